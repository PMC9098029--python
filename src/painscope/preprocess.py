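"""Standardization and rating-quartile averaging.

Order of operations: study demeaning → per-image z-scoring → within-study
rating z-scoring → within-participant quartile collapse.  Demeaning removes
study-level offset maps; per-image z-scoring matches all trials on net
response (mean voxel value 0, SD 1) so images differ only in spatial
configuration; rating z-scoring puts heterogeneous rating scales on one
footing while preserving between-participant differences within study;
quartile averaging collapses each participant's trials to four rating-ranked
averages for computational tractability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .datasets import MIN_TRIALS_PER_PARTICIPANT, MaskGeometry, StudyDataset
from .datasets import concat_studies

__all__ = [
    "standardize_images",
    "zscore_ratings",
    "quartile_collapse",
    "preprocess",
    "standardize_maps",
    "QuartileDataset",
]

logger = logging.getLogger(__name__)

N_QUANTILES = 4  # quartiles: the minimum bin count where every bin informs
                 # a linear intensity effect


def standardize_maps(images: np.ndarray) -> np.ndarray:
    """Z-score each row (image) to mean voxel value 0 and SD 1."""
    images = np.asarray(images, float)
    mu = images.mean(axis=1, keepdims=True)
    sd = images.std(axis=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(f"zero-variance image at row {bad[0]}")
    return (images - mu) / sd


def standardize_images(datasets: Sequence[StudyDataset]) -> list[StudyDataset]:
    """Subtract each study's mean map, then z-score every trial image."""
    out = []
    for ds in datasets:
        if ds.n_trials < 1:
            raise ValueError(f"{ds.study_id}: no trials")
        demeaned = ds.features - ds.features.mean(axis=0, keepdims=True)
        sd = demeaned.std(axis=1)
        bad = np.flatnonzero(sd == 0)
        if bad.size:
            raise ValueError(
                f"{ds.study_id}: zero-variance image after demeaning at trial "
                f"row {bad[0]}"
            )
        z = (demeaned - demeaned.mean(axis=1, keepdims=True)) / sd[:, None]
        out.append(ds.copy(features=z))
    return out


def zscore_ratings(datasets: Sequence[StudyDataset]) -> list[StudyDataset]:
    """Z-score pain ratings within study (sample SD, ddof=1)."""
    out = []
    for ds in datasets:
        r = ds.ratings
        if np.unique(r).size < 2:
            raise ValueError(f"{ds.study_id}: constant ratings")
        z = (r - r.mean()) / r.std(ddof=1)
        meta = ds.meta.copy()
        meta["rating"] = z
        out.append(ds.copy(meta=meta))
    return out


@dataclass
class QuartileDataset:
    """Participant × rating-quartile averages across studies.

    ``features[i]`` is the average image of the trials in row *i*'s bin;
    ``meta`` has ``study_id``, ``participant_id``, ``quartile`` (1–4),
    ``rating`` (bin-average z-scored rating), ``n_trials`` (provenance) and
    bin-averaged covariates.  Within each participant, bin-average ratings
    are non-decreasing in quartile index.
    """

    geometry: MaskGeometry
    features: np.ndarray
    meta: pd.DataFrame
    excluded: list[tuple[str, str, str]]  # (study, participant, reason)

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def participants(self) -> list[str]:
        return list(dict.fromkeys(self.meta["participant_id"]))

    @property
    def ratings(self) -> np.ndarray:
        return self.meta["rating"].to_numpy(float)

    def rows_of(self, participants: Sequence[str]) -> np.ndarray:
        return np.flatnonzero(self.meta["participant_id"].isin(participants))

    def participant_studies(self) -> pd.Series:
        """study_id per participant (participants never span studies)."""
        return self.meta.groupby("participant_id", sort=False)["study_id"].first()

    def subset(self, participants: Sequence[str]) -> "QuartileDataset":
        rows = self.rows_of(participants)
        return QuartileDataset(self.geometry, self.features[rows],
                               self.meta.iloc[rows].reset_index(drop=True),
                               list(self.excluded))


def quartile_collapse(datasets: Sequence[StudyDataset]) -> QuartileDataset:
    """Average trials within per-participant rating quartiles.

    Trials are ranked by z-scored rating (stable sort; ties broken by trial
    order) and split into 4 equal-count bins, any remainder going to the
    lower bins.  Participants with fewer than 4 trials or all-equal ratings
    are excluded and logged, not fatal.
    """
    features, meta = concat_studies(datasets)
    geometry = datasets[0].geometry
    factor_cols = [c for c in meta.columns
                   if c not in ("study_id", "participant_id", "trial_index",
                                "rating")
                   and pd.api.types.is_numeric_dtype(meta[c])]
    rows_f, rows_m, excluded = [], [], []
    for (study, pid), grp in meta.groupby(["study_id", "participant_id"],
                                          sort=False):
        idx = grp.index.to_numpy()
        ratings = grp["rating"].to_numpy(float)
        if idx.size < MIN_TRIALS_PER_PARTICIPANT:
            excluded.append((study, pid, "fewer than 4 trials"))
            logger.warning("excluding %s/%s: fewer than 4 trials", study, pid)
            continue
        if np.unique(ratings).size < 2:
            excluded.append((study, pid, "constant ratings"))
            logger.warning("excluding %s/%s: constant ratings", study, pid)
            continue
        order = np.argsort(ratings, kind="stable")  # ties: trial order
        bins = np.array_split(order, N_QUANTILES)  # remainder → lower bins
        for q, members in enumerate(bins, start=1):
            sel = idx[members]
            rows_f.append(features[sel].mean(axis=0))
            row = {
                "study_id": study,
                "participant_id": pid,
                "quartile": q,
                "rating": float(meta.loc[sel, "rating"].mean()),
                "n_trials": int(len(sel)),
            }
            for c in factor_cols:
                vals = meta.loc[sel, c]
                row[c] = float(vals.mean()) if vals.notna().all() else np.nan
            rows_m.append(row)
    if not rows_f:
        raise ValueError("all participants excluded")
    qmeta = pd.DataFrame(rows_m)
    return QuartileDataset(geometry, np.asarray(rows_f), qmeta, excluded)


def preprocess(datasets: Sequence[StudyDataset]) -> QuartileDataset:
    """Full pipeline: demean per study, z-score images, z-score ratings,
    collapse to quartiles."""
    return quartile_collapse(zscore_ratings(standardize_images(datasets)))
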