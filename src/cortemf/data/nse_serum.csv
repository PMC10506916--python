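swine_group,context,concentration_ng_ml
control,post_cci,-0.171
control,postop_day_2,-0.105
control,postop_day_7_10,-0.127
control,sacrifice_day_21,-0.319
delayed_stimulation,pre_cci,0.170
delayed_stimulation,post_cci,0.307
delayed_stimulation,postop_day_7_10,0.054
delayed_stimulation,sacrifice_day_21,0.813
immediate_stimulation,pre_cci,0.148
immediate_stimulation,post_cci,0.120
immediate_stimulation,postop_day_2,0.016
immediate_stimulation,postop_day_7_10,0.379
immediate_stimulation,sacrifice_day_21,0.203
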