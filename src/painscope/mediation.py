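"""Within-participant mediation of experimental factors via brain scores.

The question: do a decoder's predictions carry the effect of an experimental
factor (temperature, cue, habituation) on pain report?  All variables are
first stripped of participant fixed effects (participant means subtracted),
then two least-squares path models are fitted on the pooled rows:

    path a:   mediator ~ all factors           (α per factor)
    path b/τ: outcome  ~ mediator + all factors (β; τ per factor)

The indirect effect of factor f is α_f·β; the total effect τ_f + α_f·β
equals, exactly, the factor's coefficient in the outcome-only regression on
the same rows.  Uncertainty comes from a participant-level (cluster)
bootstrap with bias-corrected percentile intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._seeds import stage_rng

__all__ = ["MediationResult", "MediationModel", "mediate", "percent_mediated"]

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 5000


def _demean_within(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Subtract group (participant) means column-wise."""
    df = pd.DataFrame(values)
    return (df - df.groupby(pd.Series(groups)).transform("mean")).to_numpy()


def _ols(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.lstsq(X, y, rcond=None)[0]


def _bc_ci(boot: np.ndarray, estimate: float, level: float = 0.95,
           ) -> tuple[float, float]:
    """Bias-corrected percentile interval (no acceleration constant)."""
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        return (math.nan, math.nan)
    prop = np.mean(boot < estimate)
    prop = min(max(prop, 1.0 / (boot.size + 1)), boot.size / (boot.size + 1))
    z0 = stats.norm.ppf(prop)
    zc = stats.norm.ppf(0.5 + level / 2.0)
    lo = stats.norm.cdf(2 * z0 - zc)
    hi = stats.norm.cdf(2 * z0 + zc)
    return (float(np.quantile(boot, lo)), float(np.quantile(boot, hi)))


@dataclass
class MediationResult:
    """Standardized paths with bias-corrected bootstrap CIs.

    ``paths`` has one row per factor: α, β (shared), τ, indirect = α·β,
    total = τ + α·β, CIs, partial r², percent mediated.  ``beta`` is the
    mediator→outcome path adjusted for all factors; ``mediator_partial_r2``
    its unique contribution.
    """

    factors: list[str]
    paths: pd.DataFrame
    beta: float
    beta_ci: tuple[float, float]
    mediator_partial_r2: float
    model_r2: float
    n_boot: int
    n_participants: int
    wedges: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> pd.DataFrame:
        out = self.paths.copy()
        out["stars"] = ["*" if (lo > 0 or hi < 0) else ""
                        for lo, hi in zip(out["indirect_lo"],
                                          out["indirect_hi"])]
        return out


class MediationModel:
    """Single-mediator, multi-factor within-participant mediation."""

    def __init__(self, factors: pd.DataFrame | np.ndarray,
                 mediator: np.ndarray, outcome: np.ndarray,
                 participant_ids: np.ndarray,
                 factor_names: list[str] | None = None):
        if isinstance(factors, pd.DataFrame):
            self.factor_names = list(factors.columns)
            F = factors.to_numpy(float)
        else:
            F = np.asarray(factors, float)
            if F.ndim == 1:
                F = F[:, None]
            self.factor_names = (factor_names
                                 or [f"factor_{j}" for j in range(F.shape[1])])
        self.participants = np.asarray(participant_ids)
        counts = pd.Series(self.participants).value_counts()
        if (counts < 2).any():
            raise ValueError("every participant needs ≥ 2 rows")
        n_p = counts.size
        if n_p < 10:
            logger.warning("only %d participants: bootstrap mediation tests "
                           "are underpowered at small samples", n_p)
        m = np.asarray(mediator, float)
        if m.std() == 0:
            raise ValueError("constant mediator")
        # remove participant fixed effects from every variable
        self.F = _demean_within(F, self.participants)
        self.m = _demean_within(m[:, None], self.participants).ravel()
        self.y = _demean_within(np.asarray(outcome, float)[:, None],
                                self.participants).ravel()
        self.n, self.q = self.F.shape
        self.n_participants = n_p

    # ------------------------------------------------------------------
    def _paths(self, F, m, y) -> tuple[np.ndarray, float, np.ndarray]:
        """(α vector, β, τ vector) by least squares on demeaned data."""
        alpha = _ols(F, m)
        Xb = np.column_stack([m, F])
        coef = _ols(Xb, y)
        return alpha, float(coef[0]), coef[1:]

    def fit(self, n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
            level: float = 0.95) -> MediationResult:
        alpha, beta, tau = self._paths(self.F, self.m, self.y)
        indirect = alpha * beta
        total = tau + indirect

        # residual df: rows minus participant fixed effects minus slopes
        df_b = self.n - self.n_participants - (self.q + 1)
        df_a = self.n - self.n_participants - self.q
        part_r2_a = self._partial_r2(self.F, self.m, df_a)
        Xb = np.column_stack([self.m, self.F])
        part_r2_b = self._partial_r2(Xb, self.y, df_b)
        resid = self.y - Xb @ _ols(Xb, self.y)
        model_r2 = 1.0 - float(resid @ resid) / float(self.y @ self.y)

        # cluster bootstrap over participants
        rng = stage_rng(seed, "mediation-bootstrap")
        uniq = list(dict.fromkeys(self.participants))
        rows_of = [np.flatnonzero(self.participants == p) for p in uniq]
        boot = np.empty((n_boot, 3 * self.q + 1))
        for b in range(n_boot):
            draw = rng.integers(len(uniq), size=len(uniq))
            rows = np.concatenate([rows_of[i] for i in draw])
            try:
                a_b, b_b, t_b = self._paths(self.F[rows], self.m[rows],
                                            self.y[rows])
            except np.linalg.LinAlgError:  # pragma: no cover
                boot[b] = np.nan
                continue
            boot[b] = np.concatenate([a_b, [b_b], t_b, a_b * b_b])

        rows = []
        for j, name in enumerate(self.factor_names):
            a_ci = _bc_ci(boot[:, j], alpha[j], level)
            t_ci = _bc_ci(boot[:, self.q + 1 + j], tau[j], level)
            i_ci = _bc_ci(boot[:, 2 * self.q + 1 + j], indirect[j], level)
            rows.append({
                "factor": name,
                "alpha": alpha[j], "alpha_lo": a_ci[0], "alpha_hi": a_ci[1],
                "tau": tau[j], "tau_lo": t_ci[0], "tau_hi": t_ci[1],
                "indirect": indirect[j],
                "indirect_lo": i_ci[0], "indirect_hi": i_ci[1],
                "total": total[j],
                "alpha_partial_r2": part_r2_a[j],
                "tau_partial_r2": part_r2_b[j + 1],
                "percent_mediated": _pct(indirect[j], tau[j]),
            })
        beta_ci = _bc_ci(boot[:, self.q], beta, level)
        wedges = self._wedge_table(model_r2)
        return MediationResult(
            factors=list(self.factor_names),
            paths=pd.DataFrame(rows),
            beta=beta, beta_ci=beta_ci,
            mediator_partial_r2=part_r2_b[0],
            model_r2=model_r2, n_boot=n_boot,
            n_participants=self.n_participants,
            wedges=wedges,
        )

    def _partial_r2(self, X: np.ndarray, y: np.ndarray, df: int) -> np.ndarray:
        """Partial r² per column: t²/(t² + df) from the joint fit."""
        coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        sigma2 = float(resid @ resid) / max(df, 1)
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 1e-300))
        t = coef / se
        return t**2 / (t**2 + max(df, 1))

    def _wedge_table(self, model_r2: float) -> pd.DataFrame:
        """Variance shares of the outcome model (mediator + factors),
        by ordering-averaged R² increments; shares sum to model R²."""
        from .behavior import _lmg_shares
        X = np.column_stack([self.m, self.F])
        names = ["mediator"] + list(self.factor_names)
        shares = _lmg_shares(X, self.y)
        return pd.DataFrame({"component": names, "share": shares,
                             "model_r2": model_r2})


def _pct(indirect: float, direct: float, tol: float = 1e-12) -> float:
    total = indirect + direct
    if abs(total) < tol:
        return math.nan
    return round(100.0 * indirect / total)


def mediate(factors, mediator_scores, outcomes, participant_ids,
            n_boot: int = DEFAULT_N_BOOT, seed: int = 0,
            factor_names: list[str] | None = None) -> MediationResult:
    """Functional entry point; see :class:`MediationModel`."""
    return MediationModel(factors, mediator_scores, outcomes,
                          participant_ids, factor_names).fit(n_boot, seed)


def percent_mediated(result: MediationResult) -> dict[str, float]:
    """Percent of each factor's total effect carried by the mediator,
    rounded to the nearest integer; missing when the total is ≈ 0."""
    return {row["factor"]: row["percent_mediated"]
            for _, row in result.paths.iterrows()}
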