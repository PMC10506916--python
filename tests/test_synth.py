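"""Generator: determinism, spectral fidelity, injury transform, scenario
evolution and artifact insertion."""

import math

import numpy as np
import pytest

from cortemf.chain import Bin
from cortemf.spectral import amplitude_spectrum, detect_peaks, extract_features
from cortemf.synth import (
    BaselineConfig,
    CircuitComponent,
    InjuryConfig,
    add_artifacts,
    apply_injury,
    default_baseline,
    default_injury,
    default_scenario,
    evolve_scenario,
    generate_signal,
    mixture_config,
)


def silent(components=(), **kw):
    return BaselineConfig(
        components=tuple(components), pink_noise_level=0.0, sensor_noise_floor=0.0, **kw
    )


def brute_force_dft_amplitude(x, k):
    """O(N) direct DFT magnitude at bin k, scaled like amplitude_spectrum."""
    n = len(x)
    w = np.exp(-2j * math.pi * k * np.arange(n) / n)
    return 2.0 * abs(np.dot(x, w)) / n


def test_empty_config_zero_noise_gives_all_zero_samples():
    rec = generate_signal(silent(), duration=1.0, sampling_rate=1000.0, seed=3)
    assert np.all(rec.samples == 0.0)
    assert len(rec.samples) == 1000


def test_single_sinusoid_matches_closed_form_dft():
    comp = CircuitComponent(2.5, 1.0, phase=0.3)
    rec = generate_signal(silent([comp]), duration=20.0, sampling_rate=1000.0, seed=0)
    spec = amplitude_spectrum(rec, smoothing_width=0.0, band=None)
    k = int(round(2.5 * 20))  # bin index on the 0.05 Hz grid
    assert np.argmax(spec.amplitudes) == k
    expected = brute_force_dft_amplitude(rec.samples, k)
    assert spec.amplitudes[k] == pytest.approx(expected, rel=1e-12)
    assert spec.amplitudes[k] == pytest.approx(1.0, abs=1e-9)


def test_default_baseline_has_printed_components_with_dominant_2p5():
    config = default_baseline()
    freqs = {c.frequency for c in config.components}
    assert {2.5, 5.5, 6.7, 7.9, 8.8, 10.0}.issubset(freqs)
    dominant = max(config.components, key=lambda c: c.amplitude)
    assert dominant.frequency == 2.5
    rec = generate_signal(config, 20.0, 5000.0, seed=1)
    peaks = detect_peaks(amplitude_spectrum(rec), band=(1.0, 12.0))
    detected = {f for f, _ in peaks}
    assert {2.5, 5.5, 6.7, 7.9, 8.8, 10.0}.issubset(detected)
    assert max(peaks, key=lambda p: p[1])[0] == 2.5


def test_determinism_bit_identical_for_fixed_seed():
    config = default_baseline()
    a = generate_signal(config, 4.0, 5000.0, seed=42)
    b = generate_signal(config, 4.0, 5000.0, seed=42)
    assert np.array_equal(a.samples, b.samples)
    c = generate_signal(config, 4.0, 5000.0, seed=43)
    assert not np.array_equal(a.samples, c.samples)


def test_component_above_nyquist_rejected():
    cfg = silent([CircuitComponent(600.0, 1.0)])
    with pytest.raises(ValueError, match="Nyquist"):
        generate_signal(cfg, 1.0, sampling_rate=1000.0, seed=0)


def test_off_target_sensors_carry_halved_components():
    cfg = silent([CircuitComponent(5.0, 2.0)])
    b319 = generate_signal(cfg, 2.0, 1000.0, seed=0, sensor_id="B319")
    bx = generate_signal(cfg, 2.0, 1000.0, seed=0, sensor_id="Bx")
    assert np.allclose(bx.samples, 0.5 * b319.samples)


def test_noiseless_multi_sinusoid_peaks_recovered_on_grid():
    """Spectral fidelity: every injected component recovered within one
    reporting-grid step, no spurious peaks above 1 % prominence."""
    freqs = [2.5, 3.4, 5.0, 7.1, 9.9]
    comps = [CircuitComponent(f, 1.0 + 0.1 * i) for i, f in enumerate(freqs)]
    rec = generate_signal(silent(comps), 20.0, 5000.0, seed=0)
    peaks = detect_peaks(
        amplitude_spectrum(rec, smoothing_width=0.0), band=(1.0, 12.0), min_prominence=0.01
    )
    assert [f for f, _ in peaks] == freqs


def test_noise_calibration_matches_configured_densities():
    """With components removed, the measured amplitude spectral density
    near 1 Hz approximates the configured white + pink level (combined in
    quadrature) within 20 % in the median over many seeds."""
    cfg = BaselineConfig(pink_noise_level=50.0, sensor_noise_floor=20.0)
    readings = []
    for seed in range(60):
        rec = generate_signal(cfg, 20.0, 1000.0, seed=seed)
        spec = amplitude_spectrum(rec, smoothing_width=0.0, band=(0.9, 1.1))
        df = spec.df
        # bin amplitude -> ASD: a sinusoid of amplitude m in a bin of
        # width df has PSD m^2 / (2 df)
        readings.append(np.median(spec.amplitudes) / math.sqrt(2.0 * df))
    measured = float(np.median(readings))
    # Rayleigh-distributed white bins: median magnitude = rms * sqrt(ln 2)
    white_rms_asd = cfg.sensor_noise_floor
    expected = math.hypot(cfg.pink_noise_level, white_rms_asd)
    assert measured == pytest.approx(expected, rel=0.2)


# -- injury ---------------------------------------------------------------


def test_identity_injury_returns_config_unchanged(baseline_config):
    injury = InjuryConfig(
        attenuation=0.0, broadening=0.0, added_components=(), plateau_span=0.0,
        plateau_level=0.0, valley_notches=(),
    )
    assert apply_injury(baseline_config, injury) == baseline_config


def test_attenuation_halves_every_component_amplitude(baseline_config):
    injury = InjuryConfig(
        attenuation=0.5, broadening=0.0, added_components=(), plateau_span=0.0,
        plateau_level=0.0, valley_notches=(),
    )
    injured = apply_injury(baseline_config, injury)
    assert len(injured.components) == len(baseline_config.components)
    for before, after in zip(baseline_config.components, injured.components):
        assert after.frequency == before.frequency
        assert after.amplitude == pytest.approx(0.5 * before.amplitude)


def test_default_injury_adds_component_and_plateau_onset_at_1p6(baseline_config):
    injured = apply_injury(baseline_config, default_injury())
    assert any(c.frequency == 1.6 for c in injured.components)
    assert injured.plateau is not None
    assert injured.plateau.onset == 1.6


def test_broadening_splits_surviving_components():
    cfg = silent([CircuitComponent(5.0, 4.0)])
    injured = apply_injury(cfg, InjuryConfig(
        attenuation=0.5, broadening=0.2, added_components=(), plateau_span=0.0,
        plateau_level=0.0, valley_notches=(),
    ))
    got = {(c.frequency, c.amplitude) for c in injured.components}
    assert got == {(4.8, 0.5), (5.0, 1.0), (5.2, 0.5)}


# -- scenario evolution ---------------------------------------------------


def test_midpoint_mixture_is_arithmetic_mean_of_amplitudes(baseline_config, injured_config):
    mixed = mixture_config(baseline_config, injured_config, weight=0.5)
    base = {c.frequency: c.amplitude for c in baseline_config.components}
    inj = {c.frequency: c.amplitude for c in injured_config.components}
    for comp in mixed.components:
        expected = 0.5 * base.get(comp.frequency, 0.0) + 0.5 * inj.get(comp.frequency, 0.0)
        assert comp.amplitude == pytest.approx(expected)


def test_weight_one_everywhere_reproduces_baseline(baseline_config, injured_config):
    scenario = default_scenario(seed=0, convergence_day=10)
    configs = {
        (plan.phase_label, plan.day_index): cfg
        for plan, cfg in evolve_scenario(scenario, baseline_config, default_injury())
    }
    late = configs[("post_stim", 20)]  # after shelf clearance at day 17
    assert late.components == baseline_config.components
    assert late.plateau is None
    assert late.valley_notches == baseline_config.valley_notches


def test_scenario_weights_monotone_and_reach_threshold_at_convergence_day():
    scenario = default_scenario(seed=0, convergence_day=10)
    post = scenario.post_stim_days()
    weights = [d.mixture_weight for d in post]
    assert all(b >= a for a, b in zip(weights, weights[1:]))
    first_above = next(d.day_index for d in post if d.mixture_weight >= 0.7)
    assert first_above == scenario.convergence_day


def test_convergence_day_outside_range_rejected():
    with pytest.raises(ValueError, match="convergence_day"):
        default_scenario(seed=0, convergence_day=30, last_post_day=21)


def test_expected_spectrum_similarity_nondecreasing_after_stimulation(
    baseline_config, injured_config
):
    """Monotone convergence of the noise-free expected spectra: the rms
    distance between each day's component structure and baseline shrinks
    as the mixture weight grows."""
    scenario = default_scenario(seed=0)
    base = {c.frequency: c.amplitude for c in baseline_config.components}
    dists = []
    for plan, cfg in evolve_scenario(scenario, baseline_config, default_injury()):
        if plan.phase_label != "post_stim":
            continue
        amps = {c.frequency: c.amplitude for c in cfg.components}
        all_freqs = set(base) | set(amps)
        d = math.sqrt(sum((amps.get(f, 0) - base.get(f, 0)) ** 2 for f in all_freqs))
        dists.append(d)
    assert all(b <= a + 1e-9 for a, b in zip(dists, dists[1:]))


# -- artifacts ------------------------------------------------------------


def test_empty_artifact_schedule_leaves_recording_unchanged(baseline_config):
    rec = generate_signal(baseline_config, 4.0, 1000.0, seed=5)
    assert add_artifacts(rec, []) is rec


def test_artifact_burst_inflates_local_rms(baseline_config):
    rec = generate_signal(baseline_config, 60.0, 1000.0, seed=5)
    noisy = add_artifacts(rec, [30.0], artifact_scale=50.0)
    fs = int(rec.sampling_rate)
    clean_rms = np.sqrt(np.mean(rec.samples[: 20 * fs] ** 2))
    burst_rms = np.sqrt(np.mean(noisy.samples[30 * fs : 31 * fs] ** 2))
    assert burst_rms > 10.0 * clean_rms


def test_artifact_guard_rejects_schedule_without_clean_bin(baseline_config):
    rec = generate_signal(baseline_config, 45.0, 1000.0, seed=5)
    with pytest.raises(ValueError, match="clean"):
        add_artifacts(rec, [10.0, 25.0, 40.0], require_clean_bin=True)
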