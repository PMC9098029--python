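"""Participant-grouped, study-balanced repeated nested cross-validation.

The outer 2×5 scheme yields properly cross-validated predictions; an inner
5-fold loop chooses the PCR dimension; for modular spaces an additional
inner loop first selects the best candidate module exhaustively (each
candidate evaluated with its own innermost dimension optimization — three
levels of nesting).  Participants are never fragmented across folds, and each
fold's test set is balanced across studies to within one participant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seeds import stage_rng, stage_seed
from .datasets import AnalysisConfig
from .pcr import DimOptConfig, PCRModel, fit_pcr, optimize_dims
from .preprocess import QuartileDataset
from .spaces import ModelSpace, extract_features

__all__ = [
    "CVScheme",
    "PredictionSet",
    "build_cv_scheme",
    "grouped_folds",
    "select_module",
    "nested_cv_predict",
    "train_final",
    "balance_participants",
    "decode_all_spaces",
    "decode_studywise",
]


@dataclass
class CVScheme:
    """Per-row fold assignment for each repeat; grouping by participant,
    stratification by study."""

    repeats: int
    folds: int
    assignment: np.ndarray  # (repeats, n_rows) fold id per row

    def outer_splits(self, repeat: int):
        for f in range(self.folds):
            te = np.flatnonzero(self.assignment[repeat] == f)
            tr = np.flatnonzero(self.assignment[repeat] != f)
            yield f, tr, te


def _deal_participants(participants: pd.DataFrame, n_folds: int,
                       rng: np.random.Generator) -> dict[str, int]:
    """Shuffle participants within study, deal round-robin to folds with a
    random per-study starting fold: per-fold study counts differ by ≤ 1."""
    fold_of = {}
    for study, grp in participants.groupby("study_id", sort=False):
        pids = list(grp["participant_id"])
        rng.shuffle(pids)
        start = int(rng.integers(n_folds))
        for i, pid in enumerate(pids):
            fold_of[pid] = (i + start) % n_folds
    return fold_of


def build_cv_scheme(meta: pd.DataFrame, repeats: int, folds: int,
                    seed: int) -> CVScheme:
    """Construct the repeated participant-grouped, study-stratified scheme."""
    participants = (meta[["study_id", "participant_id"]]
                    .drop_duplicates().reset_index(drop=True))
    assignment = np.empty((repeats, len(meta)), dtype=int)
    for r in range(repeats):
        rng = stage_rng(seed, f"cv-repeat-{r}")
        fold_of = _deal_participants(participants, folds, rng)
        assignment[r] = meta["participant_id"].map(fold_of).to_numpy()
    return CVScheme(repeats, folds, assignment)


def grouped_folds(participant_ids: np.ndarray, study_ids: np.ndarray,
                  n_folds: int, rng: np.random.Generator,
                  ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Participant-grouped k-fold splits of an arbitrary row subset."""
    pids = np.asarray(participant_ids)
    sids = np.asarray(study_ids)
    uniq_p, codes = np.unique(pids, return_inverse=True)
    n_folds = min(n_folds, uniq_p.size)
    fold_of = np.empty(uniq_p.size, dtype=int)
    # study of each unique participant (participants never span studies)
    study_of = sids[np.unique(codes, return_index=True)[1]]
    for study in np.unique(study_of):
        members = np.flatnonzero(study_of == study)
        rng.shuffle(members)
        start = int(rng.integers(n_folds))
        fold_of[members] = (np.arange(members.size) + start) % n_folds
    fold = fold_of[codes]
    return [(np.flatnonzero(fold != f), np.flatnonzero(fold == f))
            for f in range(n_folds)]


@dataclass
class PredictionSet:
    """Cross-validated predictions plus the per-fold hyperparameter log."""

    space_id: str
    frame: pd.DataFrame    # row, repeat, fold, participant_id, study_id,
                           # observed, predicted
    choices: pd.DataFrame  # repeat, fold, module, k

    def averaged(self) -> pd.DataFrame:
        """Predictions averaged over repeats, one row per data row."""
        return (self.frame
                .groupby(["row", "participant_id", "study_id"], sort=False)
                .agg(observed=("observed", "first"),
                     predicted=("predicted", "mean"))
                .reset_index())


def _degenerate(X: np.ndarray) -> bool:
    return X.shape[0] < 2 or np.allclose(X, X.mean(axis=0), atol=1e-12)


def select_module(features: np.ndarray, y: np.ndarray,
                  space: ModelSpace, participant_ids: np.ndarray,
                  study_ids: np.ndarray, n_inner_folds: int,
                  opt_cfg: DimOptConfig, rng: np.random.Generator,
                  n_innermost_folds: int | None = None) -> int:
    """Exhaustively evaluate candidate modules by inner-CV MSE.

    Each candidate's inner-fold fits run their own innermost dimension
    optimization (the third nesting level); the innermost splits are shared
    across candidates.  Ties break toward fewer voxels, then label order.
    """
    inner = grouped_folds(participant_ids, study_ids, n_inner_folds, rng)
    n_innermost = n_innermost_folds or n_inner_folds
    innermost = [grouped_folds(participant_ids[tr], study_ids[tr],
                               n_innermost, rng) for tr, _ in inner]
    n_cand = space.n_candidates
    mse = np.full(n_cand, np.inf)
    for m in range(n_cand):
        Xm = extract_features(features, space.modules[m])
        if _degenerate(Xm):
            continue
        sse, count = 0.0, 0
        ok = True
        for (tr, te), inmost in zip(inner, innermost):
            Xtr = Xm[tr]
            if _degenerate(Xtr):
                ok = False
                break
            k = optimize_dims(Xtr, y[tr], inmost, opt_cfg)
            model = fit_pcr(Xtr, y[tr], k)
            pred = model.predict(Xm[te])
            sse += float(((pred - y[te]) ** 2).sum())
            count += te.size
        if ok and count:
            mse[m] = sse / count
    if not np.isfinite(mse).any():
        raise ValueError(f"{space.space_id}: all candidate modules degenerate")
    sizes = np.array([len(m) for m in space.modules])
    order = np.lexsort((np.arange(n_cand), sizes, mse))
    return int(order[0])


def _fit_on_train(features: np.ndarray, y: np.ndarray, space: ModelSpace,
                  participant_ids: np.ndarray, study_ids: np.ndarray,
                  n_inner_folds: int, opt_cfg: DimOptConfig,
                  rng: np.random.Generator,
                  n_innermost_folds: int | None = None,
                  ) -> tuple[PCRModel, int | None]:
    """Module selection (if modular) + dimension optimization + final fit."""
    if space.kind == "modular":
        m = select_module(features, y, space, participant_ids, study_ids,
                          n_inner_folds, opt_cfg, rng,
                          n_innermost_folds=n_innermost_folds)
        voxels = space.modules[m]
    else:
        m = None
        voxels = space.voxels
    Xv = extract_features(features, voxels)
    inner = grouped_folds(participant_ids, study_ids, n_inner_folds, rng)
    k = optimize_dims(Xv, y, inner, opt_cfg)
    model = fit_pcr(Xv, y, k, voxels=voxels,
                    descriptor={"space": space.space_id, "module": m})
    return model, m


def nested_cv_predict(qdata: QuartileDataset, space: ModelSpace,
                      scheme: CVScheme, seed: int,
                      config: AnalysisConfig | None = None) -> PredictionSet:
    """Run the full repeated nested CV for one model space."""
    config = config or AnalysisConfig()
    y = qdata.ratings
    pids = qdata.meta["participant_id"].to_numpy()
    studies = qdata.meta["study_id"].to_numpy()
    rows_frame, rows_choice = [], []
    for r in range(scheme.repeats):
        for f, tr, te in scheme.outer_splits(r):
            overlap = set(pids[tr]) & set(pids[te])
            assert not overlap, f"participants fragmented across folds: {overlap}"
            rng = stage_rng(seed, f"{space.space_id}-rep{r}-fold{f}")
            opt_cfg = DimOptConfig(method=config.dim_opt_method,
                                   n_evals=config.dim_opt_evals,
                                   seed=int(rng.integers(2**31)),
                                   rel_tol=config.dim_rel_tol)
            model, m = _fit_on_train(qdata.features[tr], y[tr], space,
                                     pids[tr], studies[tr],
                                     config.inner_folds, opt_cfg, rng,
                                     config.innermost_folds)
            pred = model.predict(qdata.features[te])
            rows_frame.append(pd.DataFrame({
                "row": te, "repeat": r, "fold": f,
                "participant_id": pids[te], "study_id": studies[te],
                "observed": y[te], "predicted": pred,
            }))
            module_name = (space.module_names[m]
                           if m is not None and space.module_names else m)
            rows_choice.append({"repeat": r, "fold": f,
                                "module": module_name, "k": model.k})
    return PredictionSet(space.space_id,
                         pd.concat(rows_frame, ignore_index=True),
                         pd.DataFrame(rows_choice))


def train_final(qdata: QuartileDataset, space: ModelSpace, seed: int,
                config: AnalysisConfig | None = None) -> PCRModel:
    """Fit one frozen model on all rows (module chosen by full inner CV),
    for application to holdout studies or task maps."""
    config = config or AnalysisConfig()
    rng = stage_rng(seed, f"final-{space.space_id}")
    opt_cfg = DimOptConfig(method=config.dim_opt_method,
                           n_evals=config.dim_opt_evals,
                           seed=int(rng.integers(2**31)),
                           rel_tol=config.dim_rel_tol)
    model, _ = _fit_on_train(qdata.features, qdata.ratings, space,
                             qdata.meta["participant_id"].to_numpy(),
                             qdata.meta["study_id"].to_numpy(),
                             config.inner_folds, opt_cfg, rng,
                             config.innermost_folds)
    return model


# ----------------------------------------------------------------------
# drivers


def balance_participants(qdata: QuartileDataset, n_per_study: int,
                         seed: int) -> QuartileDataset:
    """Randomly sample the same number of participants from every study
    (the smallest study's size, by default) before pooling."""
    rng = stage_rng(seed, "balance")
    keep = []
    per_participant = qdata.meta[["study_id", "participant_id"]].drop_duplicates()
    for study, grp in per_participant.groupby("study_id", sort=False):
        pids = list(grp["participant_id"])
        if len(pids) < n_per_study:
            raise ValueError(
                f"study {study!r} has {len(pids)} participants, cannot "
                f"balance to {n_per_study}"
            )
        keep.extend(rng.choice(pids, size=n_per_study, replace=False))
    return qdata.subset(keep)


def decode_all_spaces(qdata: QuartileDataset, spaces: dict[str, ModelSpace],
                      config: AnalysisConfig, seed: int,
                      balance: bool = True) -> dict[str, PredictionSet]:
    """Multistudy driver: balance participants across studies, then run the
    repeated nested CV once per model space (same folds for all spaces)."""
    if balance and qdata.meta["study_id"].nunique() > 1:
        counts = (qdata.meta[["study_id", "participant_id"]]
                  .drop_duplicates().groupby("study_id").size())
        n = min(int(counts.min()), config.balance_n)
        qdata = balance_participants(qdata, n, seed)
    scheme = build_cv_scheme(qdata.meta, config.cv_repeats, config.cv_folds,
                             stage_seed(seed, "outer-folds"))
    return {sid: nested_cv_predict(qdata, sp, scheme, seed, config)
            for sid, sp in spaces.items()}


def decode_studywise(qdata: QuartileDataset, spaces: dict[str, ModelSpace],
                     config: AnalysisConfig, seed: int,
                     ) -> dict[str, PredictionSet]:
    """Learner-generalization driver: retrain per study, pool predictions."""
    out: dict[str, list[PredictionSet]] = {sid: [] for sid in spaces}
    for study in dict.fromkeys(qdata.meta["study_id"]):
        participants = (qdata.meta.loc[qdata.meta["study_id"] == study,
                                       "participant_id"].unique())
        rows = qdata.rows_of(participants)
        sub = qdata.subset(participants)
        scheme = build_cv_scheme(sub.meta, config.cv_repeats, config.cv_folds,
                                 stage_seed(seed, f"folds-{study}"))
        for sid, sp in spaces.items():
            ps = nested_cv_predict(sub, sp, scheme,
                                   stage_seed(seed, str(study)), config)
            ps.frame["row"] = rows[ps.frame["row"].to_numpy()]
            out[sid].append(ps)
    return {
        sid: PredictionSet(
            sid,
            pd.concat([p.frame for p in parts], ignore_index=True),
            pd.concat([p.choices for p in parts], ignore_index=True),
        )
        for sid, parts in out.items()
    }
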