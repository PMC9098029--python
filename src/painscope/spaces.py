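"""Parcellations and the six model-space hypotheses.

A model space is the voxel set (or list of candidate modules) a decoder may
draw on.  Three modular spaces formalize the "single coherent area" view at
different granularity (elementary regions, fine and coarse resting-state
networks); two fixed multisystem spaces (nociceptive pathways, meta-analytic
mask) span several systems; the full-brain space is unconstrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Parcellation",
    "ModelSpace",
    "build_model_spaces",
    "extract_features",
    "SPACE_IDS",
    "MODULAR_SPACES",
    "DISTRIBUTED_SPACES",
]

SPACE_IDS = ("REGION", "FRSN", "CRSN", "PATHWAYS", "META", "FULL")
MODULAR_SPACES = ("REGION", "FRSN", "CRSN")
DISTRIBUTED_SPACES = ("PATHWAYS", "META", "FULL")


@dataclass
class Parcellation:
    """Voxel→region labels with region→fRSN→cRSN maps over one mask.

    ``voxel_regions[i]`` is the integer region label of in-mask voxel *i*.
    Region labels partition the in-mask voxels; each region belongs to exactly
    one fine resting-state network (fRSN), each fRSN to one coarse network
    (cRSN).  Real atlases need not nest this way — downstream code never
    assumes nesting — but the synthetic generator produces nested ones.
    """

    geometry: "MaskGeometry"  # noqa: F821 - forward ref to datasets
    voxel_regions: np.ndarray
    region_names: dict[int, str]
    region_frsn: dict[int, str]
    frsn_crsn: dict[str, str]
    pathway_regions: set[int] = field(default_factory=set)
    meta_regions: set[int] = field(default_factory=set)
    meta_voxels: np.ndarray | None = None  # bool over mask; overrides regions

    def __post_init__(self):
        self.voxel_regions = np.asarray(self.voxel_regions, int)
        if self.voxel_regions.shape != (self.geometry.n_voxels,):
            raise ValueError("voxel_regions must have one label per in-mask voxel")
        present = set(np.unique(self.voxel_regions).tolist())
        if not present <= set(self.region_names):
            raise ValueError("voxel labels missing from region_names")
        if not set(self.region_names) <= set(self.region_frsn):
            raise ValueError("region→fRSN map must cover every region")
        if not set(self.region_frsn.values()) <= set(self.frsn_crsn):
            raise ValueError("fRSN→cRSN map must cover every fRSN")
        if not self.pathway_regions <= set(self.region_names):
            raise ValueError("pathway set contains unknown region labels")

    @property
    def region_labels(self) -> list[int]:
        return sorted(self.region_names)

    @property
    def frsn_names(self) -> list[str]:
        return sorted(set(self.region_frsn.values()))

    @property
    def crsn_names(self) -> list[str]:
        return sorted(set(self.frsn_crsn.values()))

    def region_voxels(self, label: int) -> np.ndarray:
        return np.flatnonzero(self.voxel_regions == label)

    def frsn_voxels(self, name: str) -> np.ndarray:
        members = [r for r, f in self.region_frsn.items() if f == name]
        return np.flatnonzero(np.isin(self.voxel_regions, members))

    def crsn_voxels(self, name: str) -> np.ndarray:
        frsns = [f for f, c in self.frsn_crsn.items() if c == name]
        members = [r for r, f in self.region_frsn.items() if f in frsns]
        return np.flatnonzero(np.isin(self.voxel_regions, members))

    def meta_mask(self) -> np.ndarray:
        """Boolean meta-analytic mask over the in-mask voxels."""
        if self.meta_voxels is not None:
            return np.asarray(self.meta_voxels, bool)
        return np.isin(self.voxel_regions, sorted(self.meta_regions))

    def label_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.voxel_regions, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass
class ModelSpace:
    """One hypothesis about the scope of pain representation.

    ``kind='modular'`` spaces carry a list of candidate modules (voxel index
    arrays into the mask) among which the learner selects one; ``kind='fixed'``
    spaces carry a single voxel set.
    """

    space_id: str
    kind: str  # 'modular' | 'fixed'
    modules: list[np.ndarray] | None = None
    module_names: list[str] | None = None
    voxels: np.ndarray | None = None

    def __post_init__(self):
        if self.kind == "modular":
            if not self.modules:
                raise ValueError(f"{self.space_id}: modular space needs ≥1 candidate")
            for name, m in zip(self.module_names, self.modules):
                if len(m) == 0:
                    raise ValueError(f"{self.space_id}: empty candidate {name!r}")
        elif self.kind == "fixed":
            if self.voxels is None or len(self.voxels) == 0:
                raise ValueError(f"{self.space_id}: fixed space needs a voxel set")
        else:
            raise ValueError(f"unknown space kind {self.kind!r}")

    @property
    def n_candidates(self) -> int:
        return len(self.modules) if self.kind == "modular" else 1

    def all_voxels(self) -> np.ndarray:
        if self.kind == "fixed":
            return np.asarray(self.voxels, int)
        return np.unique(np.concatenate(self.modules))


def build_model_spaces(parc: Parcellation) -> dict[str, ModelSpace]:
    """Materialize the six model spaces from a parcellation.

    REGION / FRSN / CRSN are modular (candidates = parcels at that scale);
    PATHWAYS (union of nociceptive-pathway regions), META (meta-analytic
    mask) and FULL (all in-mask voxels) are fixed.
    """
    spaces = {}
    labels = parc.region_labels
    spaces["REGION"] = ModelSpace(
        "REGION", "modular",
        modules=[parc.region_voxels(r) for r in labels],
        module_names=[parc.region_names[r] for r in labels],
    )
    spaces["FRSN"] = ModelSpace(
        "FRSN", "modular",
        modules=[parc.frsn_voxels(f) for f in parc.frsn_names],
        module_names=list(parc.frsn_names),
    )
    spaces["CRSN"] = ModelSpace(
        "CRSN", "modular",
        modules=[parc.crsn_voxels(c) for c in parc.crsn_names],
        module_names=list(parc.crsn_names),
    )
    pathway_voxels = np.flatnonzero(
        np.isin(parc.voxel_regions, sorted(parc.pathway_regions)))
    if pathway_voxels.size == 0:
        raise ValueError("pathway region set is empty")
    spaces["PATHWAYS"] = ModelSpace("PATHWAYS", "fixed", voxels=pathway_voxels)
    meta_voxels = np.flatnonzero(parc.meta_mask())
    if meta_voxels.size == 0:
        raise ValueError("meta-analytic mask is empty")
    spaces["META"] = ModelSpace("META", "fixed", voxels=meta_voxels)
    spaces["FULL"] = ModelSpace(
        "FULL", "fixed", voxels=np.arange(parc.geometry.n_voxels))
    return spaces


def extract_features(features: np.ndarray, voxel_set: np.ndarray) -> np.ndarray:
    """Column-select a voxel subset, preserving row order and stored
    voxel-index order."""
    voxel_set = np.asarray(voxel_set, int)
    if voxel_set.size and (voxel_set.min() < 0
                           or voxel_set.max() >= features.shape[1]):
        raise ValueError("voxel index outside the mask")
    return features[:, voxel_set]
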