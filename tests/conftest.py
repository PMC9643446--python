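"""Shared fixtures: desk-scale synthetic cohorts and their feature tables.

The expensive fixtures are session-scoped and lazy; only tests that request
them pay for the generation + extraction.
"""

from __future__ import annotations

import numpy as np
import pytest

from eegmark.atlas import reduced_patch_labels
from eegmark.features import ExtractionConfig, assemble, subject_features
from eegmark.prep import epoch
from eegmark.synth import SynthConfig, generate_cohort

#: extraction settings matched to the short desk-scale recordings used in
#: tests (DFA fit range and fEI window shortened accordingly)
SHORT_EXTRACTION = ExtractionConfig(dfa_fit_s=(2.0, 10.0), fei_window_s=4.0)

#: for the shortest (16-24 s) calibration recordings
TINY_EXTRACTION = ExtractionConfig(dfa_fit_s=(1.0, 4.0), fei_window_s=1.5)


def extract_table(cohort, config: ExtractionConfig = SHORT_EXTRACTION, validate=True):
    per = {
        meta.subject_id: subject_features(epoch(rec), config)
        for meta, rec in cohort
    }
    return assemble(per, [m for m, _ in cohort], validate_counts=validate)


def reduced_cohort_config(seed: int, **overrides) -> SynthConfig:
    """40-subject cohort on the 14-patch atlas subset (null unless overridden)."""
    kwargs = dict(
        seed=seed,
        n_con=20,
        n_asd=20,
        duration_s=48.0,
        fs=160.0,
        patch_subset=reduced_patch_labels(),
        age_model={"CON": (35.0, 10.0), "ASD": (35.0, 10.0)},
    )
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


@pytest.fixture(scope="session")
def null_table_68():
    """Feature table of a 40-subject null cohort on the full 68-patch atlas.

    No group effect and matched age distributions: every downstream test on
    this table probes calibration, not sensitivity.
    """
    cfg = SynthConfig(
        seed=11,
        n_con=20,
        n_asd=20,
        duration_s=24.0,
        fs=128.0,
        age_model={"CON": (35.0, 10.0), "ASD": (35.0, 10.0)},
    )
    return extract_table(generate_cohort(cfg), config=TINY_EXTRACTION)


@pytest.fixture(scope="session")
def effect_table_14():
    """120-subject cohort (14-patch subset) with a d=2 alpha-amplitude group
    effect injected into the ASD group.

    d=2 on the latent amplitude caps the achievable balanced accuracy at
    about Phi(1) = 0.84, so the cohort must be large enough that the
    cross-validation estimate measures pipeline quality rather than
    small-sample noise.
    """
    cfg = reduced_cohort_config(
        23, n_con=60, n_asd=60, group_effect={"alpha_amplitude": 2.0}
    )
    return extract_table(generate_cohort(cfg), validate=False)


@pytest.fixture(scope="session")
def toy_xy():
    """Small separable two-class problem for CV bookkeeping tests."""
    rng = np.random.default_rng(5)
    n, p = 40, 20
    y = np.repeat([0, 1], n // 2)
    X = rng.standard_normal((n, p))
    X[y == 1, :3] += 2.0
    types = np.array(["a"] * 10 + ["b"] * 10)
    return X, y, types
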