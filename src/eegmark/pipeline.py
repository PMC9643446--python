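"""End-to-end orchestration: simulate -> features -> stats -> predict.

A :class:`RunConfig` fully specifies a run (stages, seeds, module defaults);
:func:`run` executes the requested stages in order into a run directory and
writes a manifest (config hash, library versions, per-stage wall time).
Identical config + seed reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

from . import io as eio
from .features import ExtractionConfig, FeatureTable, age_screen, assemble, detrend_age, subject_features
from .prep import epoch, enforce_min_duration
from .predict import ModelGrid, predict_from_table
from .stats import group_report
from .synth import SynthConfig, generate_cohort

log = logging.getLogger("eegmark")

STAGES = ("simulate", "features", "stats", "predict")


@dataclass
class RunConfig:
    """Serializable recipe for a pipeline run."""

    stages: list = field(default_factory=lambda: list(STAGES))
    out_dir: str = "eegmark_run"
    seed: int = 0
    synth: dict = field(default_factory=dict)  # SynthConfig overrides
    epoch_len_s: float = 4.0
    min_duration_s: float = 120.0
    extraction: dict = field(default_factory=dict)  # ExtractionConfig overrides
    detrend: bool = True
    n_perm: int = 10000
    models: list = field(default_factory=lambda: ["logl1"])
    cv_target: str = "group"
    cv_repeats: int = 10
    cv_outer_k: int = 10
    cv_inner_k: int = 10
    reduced_grid: bool = True
    input_cohort: Optional[str] = None  # HDF5 path; skips the simulate stage

    def __post_init__(self) -> None:
        for s in self.stages:
            if s not in STAGES:
                raise ValueError(f"unknown stage {s!r}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _epoch_cohort(cohort, cfg: RunConfig):
    """Epoch every recording and apply the minimum-duration rule."""
    out = []
    for meta, rec in cohort:
        er = epoch(rec, epoch_len_s=cfg.epoch_len_s)
        er = enforce_min_duration(er, min_s=cfg.min_duration_s)
        if er is None:
            log.info("excluding %s: below minimum duration", meta.subject_id)
            continue
        out.append((meta, er))
    return out


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_sha256": hashlib.sha256(config.to_json().encode()).hexdigest(),
        "versions": _versions(),
        "stages": {},
        "artifacts": [],
    }
    (out / "config.json").write_text(config.to_json())

    cohort = None
    table: Optional[FeatureTable] = None

    for stage in config.stages:
        t0 = time.perf_counter()
        log.info("stage %s", stage)
        if stage == "simulate":
            synth_cfg = SynthConfig(**{"seed": config.seed, **config.synth})
            cohort = generate_cohort(synth_cfg)
            eio.save_cohort(out / "cohort.h5", cohort, synth_cfg)
            manifest["artifacts"].append("cohort.h5")
        elif stage == "features":
            if cohort is None:
                src = config.input_cohort or out / "cohort.h5"
                cohort = eio.load_cohort(src)
            epoched = _epoch_cohort(cohort, config)
            ext = ExtractionConfig(**config.extraction)
            per_subject = {}
            for i, (meta, er) in enumerate(epoched):
                per_subject[meta.subject_id] = subject_features(er, ext)
                log.info("features %d/%d (%s)", i + 1, len(epoched), meta.subject_id)
            full_atlas = all(len(er.patch_labels) == 68 for _, er in epoched)
            table = assemble(
                per_subject, [m for m, _ in epoched], validate_counts=full_atlas
            )
            screen = age_screen(table)
            (out / "age_screen.json").write_text(json.dumps(screen.to_dict(), indent=1))
            if config.detrend:
                table = detrend_age(table, screen.flagged_subgroups)
            eio.save_feature_table(out / "features.tsv", table)
            manifest["artifacts"] += ["features.tsv", "age_screen.json"]
        elif stage == "stats":
            if table is None:
                table = eio.load_feature_table(out / "features.tsv")
            report = group_report(table, n_perm=config.n_perm, seed=config.seed)
            (out / "group_stats.json").write_text(json.dumps(report.to_dict(), indent=1))
            per_feature = report.mean_diff.to_frame("mean_diff")
            per_feature["perm_p"] = report.perm_p
            per_feature["perm_p_adj"] = report.perm_p_adj
            per_feature["levene_w"] = report.levene_w
            per_feature["levene_p_adj"] = report.levene_p_adj
            per_feature.to_csv(out / "group_stats.tsv", sep="\t")
            manifest["artifacts"] += ["group_stats.json", "group_stats.tsv"]
        elif stage == "predict":
            if table is None:
                table = eio.load_feature_table(out / "features.tsv")
            grid = ModelGrid.reduced() if config.reduced_grid else ModelGrid()
            cv = predict_from_table(
                table,
                target=config.cv_target,
                models=tuple(config.models),
                grid=grid,
                repeats=config.cv_repeats,
                outer_k=config.cv_outer_k,
                inner_k=config.cv_inner_k,
                seed=config.seed,
            )
            cv.folds.to_csv(out / "cv_folds.tsv", sep="\t", index=False)
            (out / "cv_report.json").write_text(json.dumps(cv.to_dict(), indent=1))
            manifest["artifacts"] += ["cv_folds.tsv", "cv_report.json"]
        manifest["stages"][stage] = {"wall_s": round(time.perf_counter() - t0, 3)}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


def _versions() -> dict:
    import numpy, scipy, sklearn, pandas, statsmodels, h5py

    from . import __version__

    return {
        "eegmark": __version__,
        "numpy": numpy.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "pandas": pandas.__version__,
        "statsmodels": statsmodels.__version__,
        "h5py": h5py.__version__,
    }
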