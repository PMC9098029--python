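"""Bootstrap stability of decoder weight maps and cross-scale similarity.

Voxel weights are made interpretable by a cluster (participant-level)
bootstrap: refit the decoder on resampled participants with the dimension k
frozen at the full-data optimum, form voxelwise z = mean/SE over resamples,
and threshold at two-tailed p < α (uncorrected).  Modular-space maps from
different CV folds are conjoined as the union of their significant voxels;
maps from different scales are compared by the Pearson correlation of their
weights over the intersection of significance masks; and a region-coverage
permutation test asks whether significant voxels concentrate in a region
beyond what a random scatter over the mask would produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import stage_rng
from .pcr import fit_pcr, matrix_rank
from .preprocess import QuartileDataset
from .spaces import Parcellation, extract_features

__all__ = [
    "WeightMap",
    "bootstrap_weight_map",
    "conjoin_fold_maps",
    "spatial_similarity",
    "region_coverage_test",
]

DEFAULT_N_BOOT = 5008


@dataclass
class WeightMap:
    """Voxelwise bootstrap statistics for one trained decoder.

    All vectors span the full mask; voxels outside the decoder's space have
    weight 0 and p = 1.
    """

    descriptor: dict
    n_voxels: int
    voxels: np.ndarray      # indices the decoder used
    mean: np.ndarray        # full-mask mean bootstrap weight
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    alpha: float
    n_boot: int
    sign_conflict: np.ndarray | None = None  # set by conjunction

    @property
    def mask(self) -> np.ndarray:
        return self.p < self.alpha

    @property
    def thresholded(self) -> np.ndarray:
        w = np.where(self.mask, self.mean, 0.0)
        return w


def bootstrap_weight_map(qdata: QuartileDataset, voxels: np.ndarray,
                         k: int, n_boot: int = DEFAULT_N_BOOT,
                         seed: int = 0, alpha: float = 0.05,
                         descriptor: dict | None = None) -> WeightMap:
    """Participant-resampling bootstrap of PCR weights with k frozen.

    k is held at the full-data choice so that the map reflects weight
    variability, not hyperparameter variability.  If a resample's rank drops
    below k, the dimension is clipped to the resample rank.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    voxels = np.asarray(voxels, int)
    X = extract_features(qdata.features, voxels)
    y = qdata.ratings
    pids = qdata.meta["participant_id"].to_numpy()
    participants = list(dict.fromkeys(pids))
    if len(participants) < 2:
        raise ValueError("bootstrap needs at least 2 participants")
    rows_of = {p: np.flatnonzero(pids == p) for p in participants}
    rng = stage_rng(seed, "weight-bootstrap")
    V = voxels.size
    s1 = np.zeros(V)
    s2 = np.zeros(V)
    for _ in range(n_boot):
        draw = rng.integers(len(participants), size=len(participants))
        rows = np.concatenate([rows_of[participants[i]] for i in draw])
        Xb, yb = X[rows], y[rows]
        sv = np.linalg.svd(Xb - Xb.mean(0), compute_uv=False)
        kb = min(k, matrix_rank(sv, *Xb.shape))
        if kb < 1:
            continue
        w = fit_pcr(Xb, yb, kb).weights
        s1 += w
        s2 += w * w
    mean_v = s1 / n_boot
    var_v = np.maximum(s2 / n_boot - mean_v**2, 0.0) * n_boot / max(n_boot - 1, 1)
    se_v = np.sqrt(var_v / 1.0)  # SD of bootstrap distribution = SE of weight
    with np.errstate(divide="ignore", invalid="ignore"):
        z_v = np.where(se_v > 0, mean_v / se_v, 0.0)
    p_v = 2.0 * stats.norm.sf(np.abs(z_v))
    p_v = np.clip(p_v, np.finfo(float).tiny, 1.0)

    Vfull = qdata.features.shape[1]
    mean = np.zeros(Vfull); mean[voxels] = mean_v
    se = np.zeros(Vfull); se[voxels] = se_v
    z = np.zeros(Vfull); z[voxels] = z_v
    p = np.ones(Vfull); p[voxels] = p_v
    return WeightMap(descriptor or {}, Vfull, voxels, mean, se, z, p,
                     alpha, n_boot)


def conjoin_fold_maps(maps: list[WeightMap]) -> WeightMap:
    """Union of fold maps: significant anywhere → significant; weight = mean
    of the folds significant there.  Voxels where significant folds disagree
    in sign are flagged."""
    if not maps:
        raise ValueError("no maps to conjoin")
    V = maps[0].n_voxels
    alpha = maps[0].alpha
    for m in maps[1:]:
        if m.n_voxels != V:
            raise ValueError("grid mismatch between fold maps")
    masks = np.stack([m.mask for m in maps])
    means = np.stack([m.mean for m in maps])
    union = masks.any(axis=0)
    count = masks.sum(axis=0)
    mean = np.zeros(V)
    np.divide((means * masks).sum(axis=0), count, out=mean, where=count > 0)
    signs = np.sign(means) * masks
    conflict = (signs.max(axis=0) > 0) & (signs.min(axis=0) < 0)
    # min p across folds reproduces the union: significant in any fold
    # ⇔ min p < alpha
    p = np.stack([m.p for m in maps]).min(axis=0)
    z = np.zeros(V)
    se = np.zeros(V)
    voxels = np.unique(np.concatenate([m.voxels for m in maps]))
    out = WeightMap({"conjunction_of": len(maps)}, V, voxels, mean, se, z, p,
                    alpha, maps[0].n_boot)
    out.sign_conflict = conflict
    return out


def spatial_similarity(map_a: WeightMap, map_b: WeightMap,
                       min_voxels: int = 10,
                       n_perm: int = 0, seed: int = 0) -> dict:
    """Pearson r of weights over the intersection of significance masks.

    Returns NaN r when the intersection has fewer than ``min_voxels``.
    With ``n_perm`` > 0, a sign-agnostic permutation p-value (shuffling one
    map's weights over the intersection) is added.
    """
    if map_a.n_voxels != map_b.n_voxels:
        raise ValueError("grid mismatch")
    inter = np.flatnonzero(map_a.mask & map_b.mask)
    out = {"n_intersection": int(inter.size)}
    if inter.size < min_voxels:
        out["r"] = float("nan")
        return out
    wa, wb = map_a.mean[inter], map_b.mean[inter]
    r = float(np.corrcoef(wa, wb)[0, 1])
    out["r"] = r
    if n_perm > 0:
        rng = stage_rng(seed, "similarity-perm")
        wa_c = wa - wa.mean()
        wb_c = wb - wb.mean()
        denom = np.sqrt((wa_c @ wa_c) * (wb_c @ wb_c))
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = (wa_c @ rng.permutation(wb_c)) / denom
        out["p"] = float((1 + np.sum(np.abs(null) >= abs(r))) / (n_perm + 1))
    return out


def region_coverage_test(wmap: WeightMap, parc: Parcellation,
                         n_perm: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Permutation test of per-region coverage by significant voxels.

    The null shuffles the significance mask across all in-mask voxels;
    p = (1 + #{null coverage ≥ observed}) / (n_perm + 1), per region.
    """
    if n_perm < 999:
        raise ValueError("n_perm must be ≥ 999")
    mask = wmap.mask
    V = mask.size
    labels = parc.voxel_regions
    region_labels = parc.region_labels
    n_sig = int(mask.sum())
    label_pos = {r: i for i, r in enumerate(region_labels)}
    lab_idx = np.array([label_pos[r] for r in labels])
    sizes = np.bincount(lab_idx, minlength=len(region_labels))
    observed = np.bincount(lab_idx[mask], minlength=len(region_labels))
    rng = stage_rng(seed, "coverage-perm")
    exceed = np.zeros(len(region_labels), dtype=int)
    for _ in range(n_perm):
        perm = rng.choice(V, size=n_sig, replace=False)
        null_counts = np.bincount(lab_idx[perm], minlength=len(region_labels))
        exceed += null_counts >= observed
    p = (1 + exceed) / (n_perm + 1)
    return pd.DataFrame({
        "region": [parc.region_names[r] for r in region_labels],
        "label": region_labels,
        "n_voxels": sizes,
        "coverage": np.divide(observed, sizes, out=np.zeros(len(sizes)),
                              where=sizes > 0) * 100.0,
        "p": np.minimum(p, 1.0),
    })
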