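"""Behavioral model of pain report: which experimental factors matter, and
how much rating variance does each explain?

Pain reports are modeled as linear main effects of the experimental factors
with participant fixed effects always retained (mean rating differences
between participants are real but are not the object of study).  Backward
stepwise selection removes the least significant factor until all remaining
factors have p < α.  The fitted model's variance is then decomposed into
per-factor wedges: the participant block is entered first and takes its R²
increment; the remaining factors' shares are the average R² increment over
all orderings (Shapley/LMG attribution), which is order-invariant,
nonnegative, and sums exactly to the model R².
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SelectedModel", "WedgeTable", "stepwise_select",
           "variance_partition"]

logger = logging.getLogger(__name__)


def _demean_within(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    df = pd.DataFrame(np.asarray(values, float))
    return (df - df.groupby(pd.Series(groups)).transform("mean")).to_numpy()


@dataclass
class SelectedModel:
    """Result of backward stepwise selection with participant fixed effects."""

    factor_names: list[str]          # retained factors
    dropped: list[str]               # eliminated factors (in drop order)
    coefficients: pd.Series
    pvalues: pd.Series
    r2: float                        # of factors + participant block
    participant_r2: float            # participant-block-only R²
    # demeaned design kept for the variance decomposition
    _F: np.ndarray = None
    _y: np.ndarray = None
    _tss: float = None


@dataclass
class WedgeTable:
    """Variance shares per component; shares sum to model R²."""

    frame: pd.DataFrame  # component, share
    model_r2: float

    @property
    def residual_share(self) -> float:
        return 1.0 - self.model_r2


def _fit_partialled(F: np.ndarray, y: np.ndarray, df_resid: int):
    """OLS of participant-demeaned y on demeaned factors; returns
    (coef, se, p, rss) with fixed-effect-corrected df."""
    coef, _, _, _ = np.linalg.lstsq(F, y, rcond=None)
    resid = y - F @ coef
    rss = float(resid @ resid)
    sigma2 = rss / max(df_resid, 1)
    cov = np.linalg.pinv(F.T @ F) * sigma2
    se = np.sqrt(np.maximum(np.diag(cov), 1e-300))
    t = coef / se
    p = 2.0 * stats.t.sf(np.abs(t), max(df_resid, 1))
    return coef, se, p, rss


def stepwise_select(outcomes: np.ndarray, factors: pd.DataFrame,
                    participant_ids: np.ndarray,
                    alpha: float = 0.05) -> SelectedModel:
    """Backward stepwise factor selection (linear main effects only).

    Participant fixed effects are absorbed by within-participant demeaning
    and never removed; residual df accounts for them.  Collinear factors are
    dropped with a warning before stepping.
    """
    y = np.asarray(outcomes, float)
    names = list(factors.columns)
    groups = np.asarray(participant_ids)
    n_participants = pd.Series(groups).nunique()
    yt = _demean_within(y[:, None], groups).ravel()
    tss = float(((y - y.mean()) ** 2).sum())
    participant_r2 = 1.0 - float(yt @ yt) / tss if tss > 0 else 0.0

    Ft = _demean_within(factors.to_numpy(float), groups)
    # collinearity guard: drop dependent columns (QR with pivoting)
    keep: list[int] = []
    for j in range(Ft.shape[1]):
        trial = Ft[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning("dropping collinear factor %r before stepping",
                           names[j])
    dropped = [names[j] for j in range(Ft.shape[1]) if j not in keep]
    names = [names[j] for j in keep]
    Ft = Ft[:, keep]

    while names:
        df_resid = len(y) - n_participants - len(names)
        _, _, p, _ = _fit_partialled(Ft, yt, df_resid)
        worst = int(np.argmax(p))
        if p[worst] < alpha:
            break
        logger.info("dropping %r (p=%.3g)", names[worst], p[worst])
        dropped.append(names[worst])
        names = names[:worst] + names[worst + 1:]
        Ft = np.delete(Ft, worst, axis=1)

    if names:
        df_resid = len(y) - n_participants - len(names)
        coef, _, p, rss = _fit_partialled(Ft, yt, df_resid)
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
    else:
        coef = np.zeros(0)
        p = np.zeros(0)
        r2 = participant_r2
    return SelectedModel(
        factor_names=names,
        dropped=dropped,
        coefficients=pd.Series(coef, index=names),
        pvalues=pd.Series(p, index=names),
        r2=r2,
        participant_r2=participant_r2,
        _F=Ft, _y=yt, _tss=tss,
    )


def _lmg_shares(X: np.ndarray, y: np.ndarray,
                tss: float | None = None) -> np.ndarray:
    """Shapley/LMG variance shares of the columns of X for y.

    Averages the R² increment of each column over all orderings; shares are
    nonnegative and sum to the full-model R².
    """
    n, q = X.shape
    if q > 14:
        raise ValueError("LMG enumeration limited to 14 predictors")
    X = X - X.mean(axis=0)
    if tss is None:
        yc = y - y.mean()
        tss = float(yc @ yc)
    else:
        yc = y
    if tss == 0:
        return np.zeros(q)

    # R²(S) = 1 − RSS(S)/tss; with an external tss the empty model's R² is
    # not 0, and the shares telescope to R²(full) − R²(∅)
    r2_cache: dict[frozenset, float] = {
        frozenset(): 1.0 - float(yc @ yc) / tss}

    def r2_of(subset: frozenset) -> float:
        if subset not in r2_cache:
            cols = sorted(subset)
            coef, _, _, _ = np.linalg.lstsq(X[:, cols], yc, rcond=None)
            resid = yc - X[:, cols] @ coef
            r2_cache[subset] = 1.0 - float(resid @ resid) / tss
        return r2_cache[subset]

    shares = np.zeros(q)
    # Shapley weights: |S|!(q−|S|−1)!/q!
    for j in range(q):
        others = [i for i in range(q) if i != j]
        for size in range(q):
            w = (math.factorial(size) * math.factorial(q - size - 1)
                 / math.factorial(q))
            for S in itertools.combinations(others, size):
                S = frozenset(S)
                shares[j] += w * (r2_of(S | {j}) - r2_of(S))
    return shares


def variance_partition(fit: SelectedModel) -> WedgeTable:
    """Wedge decomposition of the selected model's R².

    The participant block takes its own increment first; the retained
    factors split the remainder by ordering-averaged increments.
    """
    rows = [{"component": "participant", "share": fit.participant_r2}]
    if fit.factor_names:
        # increments computed on the participant-demeaned data, scaled to the
        # total (raw) rating variance so all wedges share one denominator
        shares = _lmg_shares(fit._F, fit._y, tss=fit._tss)
        for name, share in zip(fit.factor_names, shares):
            rows.append({"component": name, "share": float(share)})
    frame = pd.DataFrame(rows)
    return WedgeTable(frame, model_r2=float(frame["share"].sum()))
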