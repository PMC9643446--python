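"""Generator correctness: determinism, spectral shape, cohort structure and
injected effects recovered from stored ground truth."""

import numpy as np
import pytest
from scipy import signal, stats

from eegmark.synth import (
    AlphaPeak,
    CouplingSpec,
    SubjectMeta,
    SynthConfig,
    davies_harte_fgn,
    generate_cohort,
    generate_subject,
)

META = SubjectMeta("s0", "CON", 30.0, "F", 50.0, 10.0, 9.0)


def tiny_config(**kw):
    base = dict(
        seed=0,
        n_con=2,
        n_asd=2,
        duration_s=4.0,
        fs=128.0,
        n_patches=2,
        lrtc_target={},
        band_amplitudes={},
    )
    base.update(kw)
    return SynthConfig(**base)


def no_osc_config(chi, seed=0, duration_s=120.0, fs=250.0):
    return SynthConfig(
        seed=seed,
        n_patches=2,
        duration_s=duration_s,
        fs=fs,
        aperiodic_exponent={"CON": (chi, 0.0), "ASD": (chi, 0.0)},
        alpha_peak={"CON": AlphaPeak(amplitude=0.0), "ASD": AlphaPeak(amplitude=0.0)},
        band_amplitudes={},
        lrtc_target={},
    )


def test_same_seed_is_bit_identical():
    cfg = tiny_config()
    a = generate_subject(cfg, META, np.random.default_rng(42))
    b = generate_subject(cfg, META, np.random.default_rng(42))
    assert np.array_equal(a.data, b.data)
    ca = generate_cohort(cfg)
    cb = generate_cohort(cfg)
    for (ma, ra), (mb, rb) in zip(ca, cb):
        assert ma == mb
        assert np.array_equal(ra.data, rb.data)


def test_pure_powerlaw_background_has_target_slope():
    """chi=2, no oscillations: Welch PSD is log-log linear with slope ~ -2."""
    rec = generate_subject(no_osc_config(2.0), META, np.random.default_rng(1))
    f, p = signal.welch(rec.data[0], fs=rec.fs, nperseg=4096)
    m = (f >= 1.25) & (f <= 48.0)
    slope = np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)[0]
    assert abs(slope + 2.0) < 0.15


def test_alpha_peak_lands_at_configured_center():
    """10 Hz alpha oscillation: flattened Welch spectrum peaks within 0.5 Hz."""
    cfg = SynthConfig(
        seed=3,
        n_patches=4,
        duration_s=60.0,
        fs=250.0,
        alpha_peak={"CON": AlphaPeak(10.0, 2.0, 2.0), "ASD": AlphaPeak(10.0, 2.0, 2.0)},
        band_amplitudes={},
        lrtc_target={"alpha": 0.75},
    )
    rec = generate_subject(cfg, META, np.random.default_rng(3))
    f, p = signal.welch(rec.data, fs=rec.fs, nperseg=2048, axis=-1)
    p = p.mean(axis=0)
    out = ((f >= 1.25) & (f < 7.0)) | ((f > 14.0) & (f <= 48.0))
    line = np.polyfit(np.log10(f[out]), np.log10(p[out]), 1)
    alpha = (f >= 8.0) & (f <= 13.0)
    flat = np.log10(p[alpha]) - np.polyval(line, np.log10(f[alpha]))
    assert abs(f[alpha][np.argmax(flat)] - 10.0) < 0.5


def test_default_cohort_counts_follow_study_size():
    cfg = tiny_config(n_con=SynthConfig().n_con, n_asd=SynthConfig().n_asd)
    cohort = generate_cohort(cfg)
    groups = [m.group for m, _ in cohort]
    assert groups.count("CON") == 91
    assert groups.count("ASD") == 95
    ages = np.array([m.age for m, _ in cohort])
    assert ages.min() >= 18.0 and ages.max() <= 55.0


def test_null_config_groups_share_parameter_distributions():
    """d=0 everywhere: ground-truth parameters pooled over 20 seeds are
    indistinguishable between groups."""
    chis = {"CON": [], "ASD": []}
    amps = {"CON": [], "ASD": []}
    for seed in range(20):
        cfg = tiny_config(
            seed=seed,
            age_model={"CON": (35.0, 10.0), "ASD": (35.0, 10.0)},
        )
        for m, rec in generate_cohort(cfg):
            chis[m.group].append(rec.ground_truth["aperiodic_exponent"])
            amps[m.group].append(rec.ground_truth["alpha_amplitude"])
    for vals in (chis, amps):
        p = stats.ttest_ind(vals["CON"], vals["ASD"]).pvalue
        assert p > 0.01


def test_injected_age_slope_recovered_by_ols():
    slope_true = -0.01
    cfg = tiny_config(
        n_con=20, n_asd=20, seed=9, age_slopes={"aperiodic_exponent": slope_true}
    )
    cohort = generate_cohort(cfg)
    ages = np.array([m.age for m, _ in cohort])
    chis = np.array([r.ground_truth["aperiodic_exponent"] for _, r in cohort])
    res = stats.linregress(ages, chis)
    assert abs(res.slope - slope_true) < 2 * res.stderr


def test_group_effect_shifts_asd_parameter_mean():
    cfg = tiny_config(
        n_con=30, n_asd=30, seed=4, group_effect={"alpha_amplitude": 2.0},
        age_model={"CON": (35.0, 10.0), "ASD": (35.0, 10.0)},
    )
    cohort = generate_cohort(cfg)
    amps = {"CON": [], "ASD": []}
    for m, rec in cohort:
        amps[m.group].append(rec.ground_truth["alpha_amplitude"])
    sd = SynthConfig().amplitude_sd_frac * 1.0
    shift = np.mean(amps["ASD"]) - np.mean(amps["CON"])
    assert shift == pytest.approx(2.0 * sd, abs=3 * sd / np.sqrt(15))


def test_fgn_has_exact_unit_variance_structure():
    x = davies_harte_fgn(4096, 0.75, np.random.default_rng(0))
    assert x.shape == (4096,)
    assert x.std() == pytest.approx(1.0, abs=0.15)


@pytest.mark.parametrize(
    "kw",
    [
        {"lrtc_target": {"alpha": 1.5}},
        {"coupling": [CouplingSpec(0, 1, "alpha", 0.0, 1.5)]},
        {"coupling": [CouplingSpec(0, 5, "alpha", 0.0, 0.5)]},
        {"duration_s": 4.001},
        {"aperiodic_exponent": {"CON": (1.5, -0.1), "ASD": (1.5, 0.1)}},
    ],
)
def test_invalid_configs_rejected(kw):
    with pytest.raises(ValueError):
        tiny_config(**kw)


def test_metadata_matches_questionnaire_model():
    cfg = tiny_config(n_con=60, n_asd=60, seed=2)
    cohort = generate_cohort(cfg)
    aq = {"CON": [], "ASD": []}
    for m, _ in cohort:
        aq[m.group].append(m.aq)
    assert np.mean(aq["CON"]) == pytest.approx(50.97, abs=4.0)
    assert np.mean(aq["ASD"]) == pytest.approx(85.73, abs=4.0)
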