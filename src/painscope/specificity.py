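"""Pain specificity of frozen decoders on labeled task-contrast maps.

Frozen models are applied to per-participant task maps (standardized like
the training images), and the resulting scores are tested for pain vs
non-pain discrimination, heat vs other pain modalities, and the interaction
of model scope (distributed vs local) with pain vs non-pain.  An optimal cut
point balancing sensitivity and specificity summarizes discrimination per
model.
"""

from __future__ import annotations


import numpy as np
import pandas as pd
from scipy import stats

from .mixed import MixedModel, RandomTerm
from .pcr import PCRModel
from .preprocess import standardize_maps
from .simulate import TaskMapSet
from .spaces import DISTRIBUTED_SPACES, MODULAR_SPACES
from .inference import sidak_level

__all__ = [
    "score_task_maps",
    "specificity_contrasts",
    "per_task_tests",
    "optimal_cutpoint",
]


def score_task_maps(models: dict[str, PCRModel], task_maps: TaskMapSet,
                    standardize: bool = True) -> pd.DataFrame:
    """Score every map with every frozen model: one row per map × model."""
    X = task_maps.features
    if standardize:
        X = standardize_maps(X)
    frames = []
    for name, model in models.items():
        scores = model.predict(X)
        frame = task_maps.meta.copy()
        frame["model"] = name
        frame["score"] = scores
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def specificity_contrasts(table: pd.DataFrame) -> pd.DataFrame:
    """Planned contrasts on task scores with random participant and task
    intercepts (scores cluster by task: each task has its own evoked
    pattern, shared by its participants).

    Contrasts: pain − non-pain; heat − (mechanical + visceral)/2 within pain
    tasks; and (distributed − local model) × (pain − non-pain) interaction.
    """
    results = []
    tbl = table.copy()
    tbl["is_pain"] = (tbl["category"] == "pain").astype(float)
    pain_code = tbl["is_pain"] - tbl["is_pain"].mean()

    def _fit(sub: pd.DataFrame, columns: dict[str, np.ndarray],
             contrast: str) -> dict:
        X = np.column_stack([np.ones(len(sub))]
                            + [np.asarray(v, float) for v in columns.values()])
        terms = [RandomTerm("participant",
                            sub["participant_id"].to_numpy())]
        if sub["task"].nunique() > 1:
            terms.append(RandomTerm("task", sub["task"].to_numpy()))
        fit = MixedModel(sub["score"].to_numpy(), X, terms,
                         ["intercept"] + list(columns)).fit()
        j = 1 + list(columns).index(contrast)
        L = np.zeros(X.shape[1])
        L[j] = 1.0
        return fit.contrast_test(L)

    test = _fit(tbl, {"pain_vs_nonpain": pain_code}, "pain_vs_nonpain")
    results.append({"contrast": "pain_vs_nonpain", **test})

    pain = tbl[tbl["category"] == "pain"].copy()
    if pain["modality"].nunique() > 1:
        code = pain["modality"].map(
            {"heat": 1.0, "mechanical": -0.5, "visceral": -0.5}).to_numpy()
        code = code / float(code @ code) * len(code)  # scale-free t test
        test = _fit(pain, {"heat_vs_other": code}, "heat_vs_other")
        results.append({"contrast": "heat_vs_other_modalities", **test})

    if "model" in tbl.columns and tbl["model"].nunique() > 1:
        scope = tbl["model"].map(
            lambda m: 0.5 if m in DISTRIBUTED_SPACES
            else (-0.5 if m in MODULAR_SPACES else np.nan))
        sub = tbl[scope.notna()].copy()
        # different decoders have arbitrarily different weight scales, so
        # discrimination is compared in each model's own score units
        sub["score"] = (sub.groupby("model")["score"]
                        .transform(lambda s: (s - s.mean()) / s.std()))
        sc = scope[scope.notna()].to_numpy(float)
        pc = (sub["is_pain"] - sub["is_pain"].mean()).to_numpy()
        test = _fit(sub, {"scope": sc, "pain": pc, "scope_x_pain": sc * pc},
                    "scope_x_pain")
        results.append({"contrast": "distributed_x_pain_interaction", **test})
    return pd.DataFrame(results)


def per_task_tests(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-sample t test of mean score per task, Šidák-corrected over tasks."""
    tasks = sorted(table["task"].unique())
    level = sidak_level(alpha, len(tasks))
    rows = []
    for task in tasks:
        s = table.loc[table["task"] == task, "score"].to_numpy()
        t, p = stats.ttest_1samp(s, 0.0)
        rows.append({"task": task, "mean_score": float(s.mean()),
                     "t": float(t), "p": float(p),
                     "significant": bool(p < level)})
    out = pd.DataFrame(rows)
    out.attrs["sidak_level"] = level
    return out


def optimal_cutpoint(scores: np.ndarray, binary_labels: np.ndarray,
                     ) -> tuple[float, float, float]:
    """Threshold balancing sensitivity and specificity.

    Scans midpoints of sorted unique scores (plus outer guards), minimizing
    |sensitivity − specificity|; ties break toward maximal
    sensitivity + specificity.  Returns (threshold, sensitivity,
    specificity) with positives = scores > threshold.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(binary_labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    uniq = np.unique(scores)
    cands = (uniq[:-1] + uniq[1:]) / 2.0
    cands = np.concatenate([[uniq[0] - 1.0], cands, [uniq[-1] + 1.0]])
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best = None
    for thr in cands:
        pred = scores > thr
        sens = float((pred & labels).sum() / n_pos)
        spec = float((~pred & ~labels).sum() / n_neg)
        key = (abs(sens - spec), -(sens + spec))
        if best is None or key < best[0]:
            best = (key, thr, sens, spec)
    return best[1], best[2], best[3]
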