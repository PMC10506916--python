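swine_group,context,concentration_ng_ml
control,impact_site,0.715
control,normal_cortex,0.772
delayed_stimulation,impact_site,1.166
delayed_stimulation,normal_cortex,0.733
immediate_stimulation,impact_site,1.193
immediate_stimulation,normal_cortex,0.764
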