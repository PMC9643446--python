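"""Persistence: HDF5 recording container, TSV metadata and feature tables.

The cohort container is one HDF5 group per subject with dataset ``data``
(patches x samples, float32) and attributes ``fs`` and ``patch_labels``;
subject metadata lives in a sidecar TSV and the generating SynthConfig (when
present) as JSON next to the container.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .features import FeatureTable
from .synth import PatchRecording, SubjectMeta, SynthConfig

META_COLUMNS = ["group", "age", "sex", "aq", "spq_vis", "spq_aud"]


def save_cohort(
    path: str | Path,
    cohort: list[tuple[SubjectMeta, PatchRecording]],
    config: Optional[SynthConfig] = None,
) -> None:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        for meta, rec in cohort:
            g = h5.create_group(meta.subject_id)
            g.create_dataset("data", data=rec.data.astype(np.float32))
            g.attrs["fs"] = rec.fs
            g.attrs["patch_labels"] = [s.encode() for s in rec.patch_labels]
            if rec.ground_truth:
                g.attrs["ground_truth"] = json.dumps(rec.ground_truth)
    meta_df = pd.DataFrame(
        [
            {
                "subject_id": m.subject_id,
                "group": m.group,
                "age": m.age,
                "sex": m.sex,
                "aq": m.aq,
                "spq_vis": m.spq_vis,
                "spq_aud": m.spq_aud,
            }
            for m, _ in cohort
        ]
    )
    meta_df.to_csv(path.with_suffix(".tsv"), sep="\t", index=False)
    if config is not None:
        path.with_suffix(".json").write_text(json.dumps(config.to_dict(), indent=1))


def load_cohort(path: str | Path) -> list[tuple[SubjectMeta, PatchRecording]]:
    path = Path(path)
    meta_df = pd.read_csv(path.with_suffix(".tsv"), sep="\t").set_index("subject_id")
    cohort = []
    with h5py.File(path, "r") as h5:
        for sid in meta_df.index:
            g = h5[sid]
            row = meta_df.loc[sid]
            meta = SubjectMeta(
                subject_id=sid,
                group=row["group"],
                age=float(row["age"]),
                sex=row["sex"],
                aq=float(row["aq"]),
                spq_vis=float(row["spq_vis"]),
                spq_aud=float(row["spq_aud"]),
            )
            truth = json.loads(g.attrs["ground_truth"]) if "ground_truth" in g.attrs else {}
            rec = PatchRecording(
                subject_id=sid,
                data=np.asarray(g["data"], dtype=np.float64),
                fs=float(g.attrs["fs"]),
                patch_labels=[
                    s.decode() if isinstance(s, bytes) else str(s)
                    for s in g.attrs["patch_labels"]
                ],
                ground_truth=truth,
            )
            cohort.append((meta, rec))
    return cohort


def save_epoched(path: str | Path, er) -> None:
    """Epoched recording in the same HDF5 container (attribute epoch_len_s)."""
    path = Path(path)
    with h5py.File(path, "w") as h5:
        g = h5.create_group(er.subject_id)
        g.create_dataset("epochs", data=er.epochs.astype(np.float32))
        g.attrs["fs"] = er.fs
        g.attrs["epoch_len_s"] = er.epoch_len_s
        g.attrs["patch_labels"] = [s.encode() for s in er.patch_labels]
        g.create_dataset("epoch_onsets", data=np.asarray(er.epoch_onsets))


def load_epoched(path: str | Path):
    from .prep import EpochedRecording

    path = Path(path)
    with h5py.File(path, "r") as h5:
        sid = next(iter(h5))
        g = h5[sid]
        return EpochedRecording(
            subject_id=sid,
            epochs=np.asarray(g["epochs"], dtype=np.float64),
            fs=float(g.attrs["fs"]),
            epoch_len_s=float(g.attrs["epoch_len_s"]),
            patch_labels=[
                s.decode() if isinstance(s, bytes) else str(s)
                for s in g.attrs["patch_labels"]
            ],
            epoch_onsets=np.asarray(g["epoch_onsets"]),
        )


def save_feature_table(path: str | Path, ft: FeatureTable) -> None:
    """TSV with three metadata header rows (family/band/unit) + sidecar meta TSV."""
    path = Path(path)
    ft.values.to_csv(path, sep="\t")
    ft.meta.to_csv(path.with_suffix(".meta.tsv"), sep="\t")


def load_feature_table(path: str | Path) -> FeatureTable:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", header=[0, 1, 2], index_col=0)
    values.index.name = "subject_id"
    values.columns.names = ["family", "band", "unit"]
    meta = pd.read_csv(path.with_suffix(".meta.tsv"), sep="\t", index_col=0)
    meta.index.name = "subject_id"
    return FeatureTable(values=values, meta=meta)
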