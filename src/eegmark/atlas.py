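"""Desikan-Killiany cortical parcellation and its lobar grouping.

The spatial units of the pipeline are the 68 cortical patches of the
Desikan-Killiany atlas (34 per hemisphere, labelled ``<name>-lh`` /
``<name>-rh``).  For region-level features the patches are grouped into six
lobar regions per hemisphere (frontal, parietal, temporal, occipital,
cingulate, insular), giving 12 region nodes of which the two insular nodes
contain a single patch each.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: 34 Desikan-Killiany parcel names (one hemisphere), alphabetical.
DK_NAMES: tuple[str, ...] = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "frontalpole",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "insula",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "paracentral",
    "parahippocampal",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
)

#: Lobar assignment of each DK parcel.
DK_REGION: dict[str, str] = {
    "bankssts": "temporal",
    "caudalanteriorcingulate": "cingulate",
    "caudalmiddlefrontal": "frontal",
    "cuneus": "occipital",
    "entorhinal": "temporal",
    "frontalpole": "frontal",
    "fusiform": "temporal",
    "inferiorparietal": "parietal",
    "inferiortemporal": "temporal",
    "insula": "insular",
    "isthmuscingulate": "cingulate",
    "lateraloccipital": "occipital",
    "lateralorbitofrontal": "frontal",
    "lingual": "occipital",
    "medialorbitofrontal": "frontal",
    "middletemporal": "temporal",
    "paracentral": "frontal",
    "parahippocampal": "temporal",
    "parsopercularis": "frontal",
    "parsorbitalis": "frontal",
    "parstriangularis": "frontal",
    "pericalcarine": "occipital",
    "postcentral": "parietal",
    "posteriorcingulate": "cingulate",
    "precentral": "frontal",
    "precuneus": "parietal",
    "rostralanteriorcingulate": "cingulate",
    "rostralmiddlefrontal": "frontal",
    "superiorfrontal": "frontal",
    "superiorparietal": "parietal",
    "superiortemporal": "temporal",
    "supramarginal": "parietal",
    "temporalpole": "temporal",
    "transversetemporal": "temporal",
}

REGIONS: tuple[str, ...] = (
    "frontal",
    "parietal",
    "temporal",
    "occipital",
    "cingulate",
    "insular",
)

HEMIS: tuple[str, str] = ("lh", "rh")


def default_patch_labels() -> list[str]:
    """The 68 patch labels: all lh parcels then all rh parcels, alphabetical."""
    return [f"{n}-{h}" for h in HEMIS for n in DK_NAMES]


#: a 14-patch homotopic subset covering all six regions (insula single-patch
#: per hemisphere, as in the full atlas); used for reduced-scale cohorts
REDUCED_SUBSET_NAMES: tuple[str, ...] = (
    "superiorfrontal",
    "caudalmiddlefrontal",
    "superiorparietal",
    "superiortemporal",
    "lateraloccipital",
    "posteriorcingulate",
    "insula",
)


def reduced_patch_labels() -> list[str]:
    return [f"{n}-{h}" for h in HEMIS for n in REDUCED_SUBSET_NAMES]


@dataclass(frozen=True)
class RegionScheme:
    """Maps each patch to a (region, hemisphere) node.

    The 12 region nodes are ordered by :data:`REGIONS` then hemisphere, which
    fixes the deterministic ordering of region-level feature names.
    """

    patch_labels: tuple[str, ...] = field(
        default_factory=lambda: tuple(default_patch_labels())
    )

    def __post_init__(self) -> None:
        for lab in self.patch_labels:
            name, _, hemi = lab.rpartition("-")
            if hemi not in HEMIS or name not in DK_REGION:
                raise ValueError(f"unrecognized patch label: {lab!r}")
        if len(set(self.patch_labels)) != len(self.patch_labels):
            raise ValueError("duplicate patch labels")

    def region_of(self, label: str) -> tuple[str, str]:
        name, _, hemi = label.rpartition("-")
        return DK_REGION[name], hemi

    @property
    def nodes(self) -> list[tuple[str, str]]:
        """The 12 (region, hemisphere) nodes in canonical order."""
        return [(r, h) for r in REGIONS for h in HEMIS]

    def node_members(self) -> dict[tuple[str, str], list[int]]:
        """Patch indices belonging to each region node."""
        members: dict[tuple[str, str], list[int]] = {n: [] for n in self.nodes}
        for i, lab in enumerate(self.patch_labels):
            members[self.region_of(lab)].append(i)
        return members

    def homotopic_pairs(self) -> list[tuple[int, int, str]]:
        """(lh_index, rh_index, region) for every homotopic parcel pair."""
        index = {lab: i for i, lab in enumerate(self.patch_labels)}
        pairs = []
        for name in sorted({lab.rpartition("-")[0] for lab in self.patch_labels}):
            lh, rh = f"{name}-lh", f"{name}-rh"
            if lh not in index or rh not in index:
                raise ValueError(f"unpaired patch: {name}")
            pairs.append((index[lh], index[rh], DK_REGION[name]))
        return pairs
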