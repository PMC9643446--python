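"""Feature-table assembly, the age screen and age detrending."""

import numpy as np
import pandas as pd
import pytest

from eegmark.features import (
    FeatureTable,
    age_screen,
    assemble,
    detrend_age,
    subject_features,
)
from eegmark.prep import epoch
from eegmark.synth import SubjectMeta, generate_cohort

from conftest import SHORT_EXTRACTION, reduced_cohort_config


def _meta(i, age, group="CON"):
    return SubjectMeta(f"sub-{i:04d}", group, age, "F", 50.0, 10.0, 9.0)


def build_table(n_subjects=30, seed=0, age_fn=None):
    """Synthetic FeatureTable with a handful of columns per family."""
    rng = np.random.default_rng(seed)
    cols = []
    wide = [f"u{i:02d}" for i in range(25)]
    for fam, band_list, units in [
        ("power_abs", ["alpha", "beta"], wide),
        ("power_rel", ["alpha", "beta"], wide),
        ("tbr", ["none"], wide),
        ("dfa", ["alpha"], wide),
        ("plv", ["alpha"], wide),
    ]:
        cols += [(fam, b, u) for b in band_list for u in units]
    idx = pd.MultiIndex.from_tuples(cols, names=["family", "band", "unit"])
    ages = np.linspace(20, 50, n_subjects) + rng.normal(0, 1, n_subjects)
    values = rng.standard_normal((n_subjects, len(cols)))
    if age_fn is not None:
        values = age_fn(values, ages, idx)
    metas = [_meta(i, a) for i, a in enumerate(ages)]
    vdf = pd.DataFrame(values, index=pd.Index([m.subject_id for m in metas], name="subject_id"), columns=idx)
    mdf = pd.DataFrame(
        {"group": "CON", "age": ages, "sex": "F", "aq": 50.0, "spq_vis": 10.0, "spq_aud": 9.0},
        index=vdf.index,
    )
    return FeatureTable(values=vdf, meta=mdf)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = reduced_cohort_config(3, n_con=2, n_asd=1)
    cohort = generate_cohort(cfg)
    per = {
        m.subject_id: subject_features(epoch(rec), SHORT_EXTRACTION)
        for m, rec in cohort
    }
    return per, [m for m, _ in cohort]


class TestAssembly:
    def test_reduced_atlas_cardinalities_follow_patch_count(self, small_cohort):
        per, metas = small_cohort
        ft = assemble(per, metas, validate_counts=False)
        counts = ft.family_counts()
        # 14 patches, 5 bands: powers 14*5 each, dfa/fei (14+1)*5,
        # connectivity (66 inter + 2 intra) * 5 bands
        assert counts["power_abs"] == counts["power_rel"] == 70
        assert counts["dfa"] == counts["fei"] == 75
        assert counts["paf"] == 15 and counts["aperiodic"] == 14
        assert counts["tbr"] == 6 and counts["asymmetry"] == 30
        for m in ("coh", "imcoh", "plv", "wpli", "pec"):
            assert counts[m] == 340
        assert not ft.values.isna().any().any()

    def test_column_order_is_deterministic(self, small_cohort):
        per, metas = small_cohort
        a = assemble(per, metas, validate_counts=False)
        b = assemble(dict(reversed(per.items())), metas, validate_counts=False)
        assert a.values.columns.equals(b.values.columns)
        assert a.values.columns.is_monotonic_increasing

    def test_missing_feature_names_subject_and_column(self, small_cohort):
        per, metas = small_cohort
        broken = dict(per)
        sid = metas[1].subject_id
        broken[sid] = per[sid].drop(per[sid].index[5])
        with pytest.raises(ValueError, match=sid):
            assemble(broken, metas, validate_counts=False)

    def test_nan_feature_rejected(self, small_cohort):
        per, metas = small_cohort
        broken = dict(per)
        sid = metas[0].subject_id
        s = per[sid].copy()
        s.iloc[3] = np.nan
        broken[sid] = s
        with pytest.raises(ValueError, match="NaN"):
            assemble(broken, metas, validate_counts=False)


class TestAgeScreen:
    def test_null_features_rarely_flag_any_type(self):
        flagged = 0
        for seed in range(20):
            report = age_screen(build_table(seed=seed))
            flagged += len(report.flagged_types)
        assert flagged <= 1

    def test_perfect_trend_flags_type_at_full_percentage(self):
        def inject(values, ages, idx):
            rng = np.random.default_rng(99)
            m = idx.get_level_values("family") == "tbr"
            values[:, m] = 0.9 * ages[:, None] + 0.1 * rng.standard_normal(
                (len(ages), m.sum())
            )
            return values

        report = age_screen(build_table(age_fn=inject))
        assert report.pct_significant["tbr"] == 100.0
        assert "tbr" in report.flagged_types
        assert ("tbr", "none") in report.flagged_subgroups

    def test_exactly_linear_feature_has_unit_correlation(self):
        def inject(values, ages, idx):
            values[:, 0] = 2.0 * ages + 1.0
            return values

        report = age_screen(build_table(age_fn=inject))
        assert report.r.iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert report.p_raw.iloc[0] < 1e-12

    def test_adjusted_p_never_below_raw(self):
        report = age_screen(build_table(seed=3))
        assert (report.p_adj.to_numpy() >= report.p_raw.to_numpy() - 1e-15).all()


class TestDetrend:
    def test_exact_linear_column_becomes_constant(self):
        def inject(values, ages, idx):
            values[:, 0] = 3.0 * ages + 2.0
            return values

        ft = build_table(age_fn=inject)
        out = detrend_age(ft, [("power_abs", "alpha")])
        col = out.values.iloc[:, 0].to_numpy()
        assert np.allclose(col, col[0])

    def test_detrended_columns_have_zero_age_correlation(self):
        ft = build_table(seed=5)
        out = detrend_age(ft, [("dfa", "alpha"), ("power_abs", "alpha")])
        report = age_screen(out)
        fams = out.values.columns.get_level_values("family")
        bands = out.values.columns.get_level_values("band")
        m = ((fams == "dfa") | (fams == "power_abs")) & (bands == "alpha")
        assert np.abs(report.r.to_numpy()[m]).max() < 1e-10

    def test_idempotent(self):
        ft = build_table(seed=6)
        sub = [("plv", "alpha")]
        once = detrend_age(ft, sub)
        twice = detrend_age(once, sub)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy())

    def test_rescreen_after_detrend_clears_flags(self):
        def inject(values, ages, idx):
            rng = np.random.default_rng(1)
            m = idx.get_level_values("family") == "dfa"
            values[:, m] = ages[:, None] + 0.5 * rng.standard_normal((len(ages), m.sum()))
            return values

        ft = build_table(age_fn=inject)
        first = age_screen(ft)
        assert ("dfa", "alpha") in first.flagged_subgroups
        cleaned = detrend_age(ft, first.flagged_subgroups)
        second = age_screen(cleaned)
        assert not set(second.flagged_subgroups) & set(first.flagged_subgroups)

    def test_unflagged_columns_untouched(self):
        ft = build_table(seed=7)
        out = detrend_age(ft, [("tbr", "none")])
        fams = ft.values.columns.get_level_values("family")
        keep = fams != "tbr"
        assert np.array_equal(
            ft.values.to_numpy()[:, keep], out.values.to_numpy()[:, keep]
        )
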