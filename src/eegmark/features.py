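"""Assembly of the per-subject biomarker table and the age-effect correction.

The full battery per recording is 3443 features: 680 band powers, 6
theta/beta ratios, 30 asymmetries, 69 peak alpha frequencies, 68 aperiodic
exponents, 345 DFA exponents, 345 fEI values and 1900 region-level
connectivity values.  Columns carry (family, band, spatial unit) metadata and
are ordered deterministically; assembly is strict (a missing value for any
subject is an error, no imputation).

For statistics and FDR, families are grouped into the 12 feature *types*
(absolute and relative power count as one "power" type).  The age screen
computes each feature's Pearson correlation with age, applies BH-FDR within
type, flags types where more than 5% of features are significant, refines the
flag to (family x band) subgroups by the same rule, and the detrend step
replaces each flagged column by its whole-cohort OLS residual plus the
original column mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .atlas import RegionScheme, REGIONS
from .prep import BandSet, DEFAULT_BANDS, EpochedRecording
from .spectral import multitaper_psd, band_power, asymmetry, theta_beta_ratio, aperiodic_features
from .criticality import EnvelopeSignal, dfa_matrix, fei_matrix
from .connectivity import (
    cross_spectra,
    coherence_matrices,
    wpli_matrices,
    band_analytic,
    plv_matrix,
    pec_matrix,
    collapse_regions,
)
from .stats import fdr_bh
from .synth import SubjectMeta

NO_BAND = "none"

#: column cardinality contract for the default 68-patch configuration
EXPECTED_FAMILY_COUNTS = {
    "power_abs": 340,
    "power_rel": 340,
    "tbr": 6,
    "asymmetry": 30,
    "paf": 69,
    "aperiodic": 68,
    "dfa": 345,
    "fei": 345,
    "coh": 380,
    "imcoh": 380,
    "plv": 380,
    "wpli": 380,
    "pec": 380,
}

TOTAL_FEATURES = sum(EXPECTED_FAMILY_COUNTS.values())  # 3443

#: family -> feature type (the 12 types used for within-type FDR)
FAMILY_TO_TYPE = {
    "power_abs": "power",
    "power_rel": "power",
    "tbr": "tbr",
    "asymmetry": "asymmetry",
    "paf": "paf",
    "aperiodic": "aperiodic",
    "dfa": "dfa",
    "fei": "fei",
    "coh": "coh",
    "imcoh": "imcoh",
    "plv": "plv",
    "wpli": "wpli",
    "pec": "pec",
}

FEATURE_TYPES = tuple(dict.fromkeys(FAMILY_TO_TYPE.values()))


@dataclass
class ExtractionConfig:
    """Tunable parameters of the feature battery."""

    bands: BandSet = field(default_factory=lambda: DEFAULT_BANDS)
    half_bandwidth: float = 1.0
    dfa_fit_s: tuple = (2.0, 20.0)
    fei_window_s: float = 5.0
    edge_trim_s: float = 0.5


def subject_features(
    er: EpochedRecording, config: ExtractionConfig = None
) -> pd.Series:
    """All 3443 features of one epoched recording, indexed (family, band, unit)."""
    cfg = config or ExtractionConfig()
    bands = cfg.bands
    scheme = RegionScheme(tuple(er.patch_labels))
    labels = list(er.patch_labels)
    entries: dict[tuple[str, str, str], float] = {}

    se = multitaper_psd(er, half_bandwidth=cfg.half_bandwidth)
    abs_p, rel_p = band_power(se, bands)
    band_names = list(bands)
    for bi, b in enumerate(band_names):
        for p, lab in enumerate(labels):
            entries[("power_abs", b, lab)] = abs_p[p, bi]
            entries[("power_rel", b, lab)] = rel_p[p, bi]
    asym = asymmetry(abs_p, scheme, bands)
    for bi, b in enumerate(band_names):
        for ri, r in enumerate(REGIONS):
            entries[("asymmetry", b, r)] = asym[ri, bi]
    tbr = theta_beta_ratio(abs_p, scheme, bands)
    for ri, r in enumerate(REGIONS):
        entries[("tbr", NO_BAND, r)] = tbr[ri]
    exps, pafs, global_paf = aperiodic_features(se)
    for p, lab in enumerate(labels):
        entries[("aperiodic", NO_BAND, lab)] = exps[p]
        entries[("paf", NO_BAND, lab)] = pafs[p]
    entries[("paf", NO_BAND, "global")] = global_paf

    cs = cross_spectra(er, half_bandwidth=cfg.half_bandwidth, f_max=bands.f_max + 1.0)
    coh_im = coherence_matrices(cs, bands)
    wpli = wpli_matrices(cs, bands)
    for b in band_names:
        analytic = band_analytic(er, bands[b], edge_trim_s=cfg.edge_trim_s)
        env = EnvelopeSignal(envelope=np.abs(analytic), band=b, fs=er.fs)
        alphas = dfa_matrix(env, fit_lo_s=cfg.dfa_fit_s[0], fit_hi_s=cfg.dfa_fit_s[1])
        feis = fei_matrix(env, window_s=cfg.fei_window_s, dfa_exponents=alphas)
        for p, lab in enumerate(labels):
            entries[("dfa", b, lab)] = alphas[p]
            entries[("fei", b, lab)] = feis[p]
        entries[("dfa", b, "global")] = float(alphas.mean())
        entries[("fei", b, "global")] = float(feis.mean())
        matrices = {
            "coh": coh_im["coh"][b],
            "imcoh": coh_im["imcoh"][b],
            "wpli": wpli[b],
            "plv": plv_matrix(analytic),
            "pec": pec_matrix(analytic),
        }
        for measure, cm in matrices.items():
            values, names = collapse_regions(cm, scheme)
            for v, name in zip(values, names):
                entries[(measure, b, name)] = v

    idx = pd.MultiIndex.from_tuples(entries.keys(), names=["family", "band", "unit"])
    s = pd.Series(list(entries.values()), index=idx, dtype=float)
    return s.sort_index()


@dataclass
class FeatureTable:
    """subjects x features matrix plus per-row subject metadata.

    ``values``: DataFrame indexed by subject_id with a (family, band, unit)
    MultiIndex on the columns.  ``meta``: DataFrame indexed by subject_id with
    group, age, sex, aq, spq_vis, spq_aud.
    """

    values: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the subject index")
        if self.values.isna().any().any():
            raise ValueError("feature table contains NaN")

    @property
    def n_subjects(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def family_counts(self) -> dict[str, int]:
        return self.values.columns.get_level_values("family").value_counts().to_dict()

    def feature_types(self) -> np.ndarray:
        fams = self.values.columns.get_level_values("family")
        return np.asarray([FAMILY_TO_TYPE[f] for f in fams])

    def copy(self) -> "FeatureTable":
        return FeatureTable(values=self.values.copy(), meta=self.meta.copy())


def assemble(
    per_subject: dict[str, pd.Series],
    metas: list[SubjectMeta],
    validate_counts: bool = True,
) -> FeatureTable:
    """Stack per-subject feature Series into a FeatureTable (strict).

    Every subject must provide exactly the same feature index; with the
    default 68-patch configuration the per-family cardinalities are validated
    against the 3443-column contract.
    """
    ids = [m.subject_id for m in metas]
    if set(ids) != set(per_subject):
        raise ValueError("metadata subjects and feature subjects differ")
    ref = per_subject[ids[0]].index
    rows = []
    for sid in ids:
        s = per_subject[sid]
        if not s.index.equals(ref):
            missing = ref.difference(s.index)
            name = missing[0] if len(missing) else s.index.difference(ref)[0]
            raise ValueError(f"subject {sid}: feature mismatch at column {name}")
        if s.isna().any():
            bad = s.index[s.isna().to_numpy()][0]
            raise ValueError(f"subject {sid}: NaN feature {bad}")
        rows.append(s)
    values = pd.DataFrame(rows, index=pd.Index(ids, name="subject_id"))
    meta = pd.DataFrame(
        [
            {
                "group": m.group,
                "age": m.age,
                "sex": m.sex,
                "aq": m.aq,
                "spq_vis": m.spq_vis,
                "spq_aud": m.spq_aud,
            }
            for m in metas
        ],
        index=pd.Index(ids, name="subject_id"),
    )
    if validate_counts:
        counts = values.columns.get_level_values("family").value_counts().to_dict()
        if counts != EXPECTED_FAMILY_COUNTS:
            raise ValueError(
                f"family cardinalities {counts} violate the "
                f"{TOTAL_FEATURES}-column contract"
            )
    return FeatureTable(values=values, meta=meta)


# ---------------------------------------------------------------------------
# age screen + detrend


@dataclass
class AgeScreenReport:
    r: pd.Series
    p_raw: pd.Series
    p_adj: pd.Series
    pct_significant: dict[str, float]
    flagged_types: list[str]
    flagged_subgroups: list[tuple[str, str]]  # (family, band)
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "pct_significant": self.pct_significant,
            "flagged_types": list(self.flagged_types),
            "flagged_subgroups": [list(t) for t in self.flagged_subgroups],
        }


def _pearson_with_age(X: np.ndarray, age: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = len(age)
    a = age - age.mean()
    sa = a.std()
    if sa == 0:
        raise ValueError("constant age vector")
    Xc = X - X.mean(axis=0)
    sx = Xc.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc * a[:, None]).mean(axis=0) / (sx * sa)
    r = np.nan_to_num(np.clip(r, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * sstats.t.sf(np.abs(t), df=n - 2)
    return r, np.clip(p, 0.0, 1.0)


def age_screen(ft: FeatureTable, alpha: float = 0.05, flag_pct: float = 5.0) -> AgeScreenReport:
    """Screen every feature for a linear age effect, FDR-corrected within type."""
    if ft.n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    age = ft.meta["age"].to_numpy(dtype=float)
    X = ft.values.to_numpy(dtype=float)
    r, p = _pearson_with_age(X, age)
    cols = ft.values.columns
    types = ft.feature_types()
    p_adj = np.ones_like(p)
    for t in FEATURE_TYPES:
        m = types == t
        if m.any():
            p_adj[m] = fdr_bh(p[m])
    sig = p_adj < alpha
    pct = {
        t: 100.0 * sig[types == t].mean() if (types == t).any() else 0.0
        for t in FEATURE_TYPES
    }
    flagged_types = [t for t in FEATURE_TYPES if pct[t] > flag_pct]
    families = cols.get_level_values("family").to_numpy()
    bands = cols.get_level_values("band").to_numpy()
    flagged_subgroups = []
    for t in flagged_types:
        tmask = types == t
        for fam, band in sorted(set(zip(families[tmask], bands[tmask]))):
            sub = tmask & (families == fam) & (bands == band)
            if 100.0 * sig[sub].mean() > flag_pct:
                flagged_subgroups.append((fam, band))
    return AgeScreenReport(
        r=pd.Series(r, index=cols),
        p_raw=pd.Series(p, index=cols),
        p_adj=pd.Series(p_adj, index=cols),
        pct_significant=pct,
        flagged_types=flagged_types,
        flagged_subgroups=flagged_subgroups,
        alpha=alpha,
    )


def detrend_age(
    ft: FeatureTable, flagged_subgroups: list[tuple[str, str]]
) -> FeatureTable:
    """Remove the whole-cohort linear age trend from flagged (family, band) columns.

    Each flagged column becomes its OLS residual plus the original column mean
    (both groups pooled, per the whole-cohort correction), so detrended
    features keep their original scale.  Idempotent.
    """
    out = ft.copy()
    if not flagged_subgroups:
        return out
    age = out.meta["age"].to_numpy(dtype=float)
    a = age - age.mean()
    denom = np.sum(a**2)
    if denom == 0:
        raise ValueError("constant age vector")
    families = out.values.columns.get_level_values("family").to_numpy()
    bands = out.values.columns.get_level_values("band").to_numpy()
    mask = np.zeros(out.n_features, dtype=bool)
    for fam, band in flagged_subgroups:
        mask |= (families == fam) & (bands == band)
    X = out.values.to_numpy(dtype=float)
    sub = X[:, mask]
    mean = sub.mean(axis=0)
    slope = a @ (sub - mean) / denom
    X[:, mask] = sub - np.outer(a, slope)
    out.values.iloc[:, :] = X
    return out
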