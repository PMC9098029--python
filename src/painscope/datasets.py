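"""Core containers: mask geometry, trial records, study datasets, config.

A :class:`StudyDataset` holds one study's trial-level beta maps as a dense
``(n_trials, V)`` matrix over the in-mask voxels, together with the trial
metadata (participant, rating, experimental covariates).  Voxel indexing is
0-based over the flattened in-mask list (C order), stored with the mask so
volumes are reconstructable bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MaskGeometry",
    "TrialRecord",
    "StudyDataset",
    "AnalysisConfig",
    "MIN_TRIALS_PER_PARTICIPANT",
]

#: participants with fewer trials cannot form four rating quartiles
MIN_TRIALS_PER_PARTICIPANT = 4

#: metadata columns that are bookkeeping, not experimental factors
_RESERVED_COLUMNS = {"study_id", "participant_id", "trial_index", "rating"}


@dataclass(frozen=True)
class MaskGeometry:
    """Volume shape, affine, and the flat indices of in-mask voxels."""

    shape: tuple[int, int, int]
    affine: np.ndarray
    indices: np.ndarray  # sorted flat indices (C order) into the volume

    def __post_init__(self):
        object.__setattr__(self, "affine", np.asarray(self.affine, float))
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 1 or (idx.size > 1 and np.any(np.diff(idx) <= 0)):
            raise ValueError("mask indices must be a sorted 1-D unique array")
        object.__setattr__(self, "indices", idx)

    @property
    def n_voxels(self) -> int:
        return int(self.indices.size)

    def unmask(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a length-V vector back into a full 3-D volume."""
        values = np.asarray(values, float)
        if values.shape != (self.n_voxels,):
            raise ValueError(
                f"expected vector of length {self.n_voxels}, got {values.shape}"
            )
        vol = np.full(int(np.prod(self.shape)), fill, dtype=float)
        vol[self.indices] = values
        return vol.reshape(self.shape)

    def mask_volume(self) -> np.ndarray:
        """Boolean 3-D volume of the mask."""
        vol = np.zeros(int(np.prod(self.shape)), dtype=bool)
        vol[self.indices] = True
        return vol.reshape(self.shape)

    def matches(self, other: "MaskGeometry", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=atol)
            and self.indices.size == other.indices.size
            and bool(np.all(self.indices == other.indices))
        )


@dataclass(frozen=True)
class TrialRecord:
    """One trial: a beta-map feature vector plus its behavioral context."""

    study_id: str
    participant_id: str
    trial_index: int
    rating: float
    features: np.ndarray
    covariates: Mapping[str, float] = field(default_factory=dict)


class StudyDataset:
    """Trials × voxels for one study, grouped by participant.

    Parameters
    ----------
    study_id : str
    geometry : MaskGeometry
        Shared grid; ``features.shape[1]`` must equal ``geometry.n_voxels``.
    features : ndarray, shape (n_trials, V)
    meta : DataFrame
        One row per trial with columns ``participant_id``, ``trial_index``,
        ``rating`` and any experimental covariates (temperature, expectation,
        social, control, site, ...).  Row order is preserved everywhere.
    """

    def __init__(self, study_id: str, geometry: MaskGeometry,
                 features: np.ndarray, meta: pd.DataFrame):
        features = np.asarray(features, float)
        if features.ndim != 2:
            raise ValueError("features must be 2-D (trials × voxels)")
        if features.shape[1] != geometry.n_voxels:
            raise ValueError(
                f"features have {features.shape[1]} columns but mask has "
                f"{geometry.n_voxels} voxels"
            )
        if len(meta) != features.shape[0]:
            raise ValueError(
                f"metadata has {len(meta)} rows but images have "
                f"{features.shape[0]} volumes"
            )
        required = {"participant_id", "trial_index", "rating"}
        missing = required - set(meta.columns)
        if missing:
            raise ValueError(f"metadata missing columns: {sorted(missing)}")
        dup = meta.duplicated(subset=["participant_id", "trial_index"])
        if dup.any():
            raise ValueError("trial_index must be unique within participant")
        self.study_id = str(study_id)
        self.geometry = geometry
        self.features = features
        self.meta = meta.reset_index(drop=True).copy()
        self.meta["participant_id"] = self.meta["participant_id"].astype(str)

    # ------------------------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.features.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.features.shape[1]

    @property
    def ratings(self) -> np.ndarray:
        return self.meta["rating"].to_numpy(float)

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.meta["participant_id"]))

    @property
    def factor_schema(self) -> set[str]:
        """Experimental factors recorded for this study (absent ones omitted)."""
        return {
            c for c in self.meta.columns
            if c not in _RESERVED_COLUMNS
            and pd.api.types.is_numeric_dtype(self.meta[c])
        }

    def trials(self) -> Iterator[TrialRecord]:
        factors = sorted(self.factor_schema)
        for i, row in self.meta.iterrows():
            yield TrialRecord(
                study_id=self.study_id,
                participant_id=str(row["participant_id"]),
                trial_index=int(row["trial_index"]),
                rating=float(row["rating"]),
                features=self.features[i],
                covariates={f: float(row[f]) for f in factors},
            )

    def flagged_participants(self) -> list[str]:
        """Participants with too few trials for quartile averaging."""
        counts = self.meta["participant_id"].value_counts()
        return sorted(counts.index[counts < MIN_TRIALS_PER_PARTICIPANT])

    def copy(self, features: np.ndarray | None = None,
             meta: pd.DataFrame | None = None) -> "StudyDataset":
        return StudyDataset(
            self.study_id,
            self.geometry,
            self.features.copy() if features is None else features,
            self.meta.copy() if meta is None else meta,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"StudyDataset({self.study_id!r}, trials={self.n_trials}, "
                f"participants={len(self.participants)}, V={self.n_voxels})")


@dataclass
class AnalysisConfig:
    """Tunable knobs for every pipeline stage, serializable to YAML."""

    seed: int = 0
    cv_repeats: int = 2
    cv_folds: int = 5
    inner_folds: int = 5
    innermost_folds: int = 3  # dimension search inside module selection
    dim_opt_method: str = "grid"  # or "bayes"
    dim_opt_evals: int = 30
    dim_rel_tol: float = 0.01  # parsimony: smallest k within this rel. MSE
    n_boot_weights: int = 5008
    n_boot_mediation: int = 5000
    n_perm_coverage: int = 5000
    alpha: float = 0.05
    balance_n: int = 16  # participants sampled per study before pooling

    def __post_init__(self):
        for name in ("cv_repeats", "cv_folds", "inner_folds", "dim_opt_evals",
                     "n_boot_weights", "n_boot_mediation", "n_perm_coverage",
                     "balance_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.dim_opt_method not in ("bayes", "grid"):
            raise ValueError("dim_opt_method must be 'bayes' or 'grid'")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def concat_studies(datasets: Sequence[StudyDataset]) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack several studies into one feature matrix + metadata table."""
    if not datasets:
        raise ValueError("no datasets given")
    geo = datasets[0].geometry
    for ds in datasets[1:]:
        if not geo.matches(ds.geometry):
            raise ValueError(f"grid mismatch between studies "
                             f"{datasets[0].study_id!r} and {ds.study_id!r}")
    features = np.vstack([ds.features for ds in datasets])
    metas = []
    for ds in datasets:
        m = ds.meta.copy()
        m.insert(0, "study_id", ds.study_id)
        metas.append(m)
    meta = pd.concat(metas, ignore_index=True)
    return features, meta
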