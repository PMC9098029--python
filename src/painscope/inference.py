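"""Performance metrics and mixed-effects comparisons across model spaces.

Decoding accuracy is summarized per participant as the Fisher-z-transformed
Pearson correlation of cross-validated predictions with observed ratings
(predictions averaged over the two CV repeats first).  Spaces are compared
with mixed models of those z values — random participant and study
intercepts, random study slopes for the planned contrasts — using orthogonal
contrast codes, Satterthwaite degrees of freedom, and BIC-approximated Bayes
factors for the contrasts that do not reach significance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .decoding import PredictionSet
from .mixed import MixedFitResult, MixedModel, RandomTerm
from .spaces import SPACE_IDS

__all__ = [
    "fisher_z",
    "participant_performance",
    "performance_table",
    "sidak_level",
    "screen_modules",
    "planned_contrasts",
    "SpaceComparison",
    "compare_spaces",
    "bayes_factor_null",
    "calibration_check",
]

logger = logging.getLogger(__name__)

R_CLIP = 1.0 - 1e-6  # |r| = 1 with 4 points would give infinite z


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """arctanh with clipping at ±(1 − 1e−6)."""
    return np.arctanh(np.clip(r, -R_CLIP, R_CLIP))


def participant_performance(predset: PredictionSet,
                            condition: str = "multistudy") -> pd.DataFrame:
    """Within-participant prediction-outcome correlation, Fisher-z scale.

    Predictions are averaged over repeats before correlating; participants
    with fewer than 3 points or zero-variance predictions are recorded with
    missing z and logged.
    """
    rows = []
    for (pid, study), grp in (predset.averaged()
                              .groupby(["participant_id", "study_id"],
                                       sort=False)):
        n = len(grp)
        pred = grp["predicted"].to_numpy()
        obs = grp["observed"].to_numpy()
        if n < 3 or pred.std() == 0 or obs.std() == 0:
            logger.warning("participant %s: degenerate predictions (n=%d)",
                           pid, n)
            z = np.nan
        else:
            z = float(fisher_z(np.corrcoef(pred, obs)[0, 1]))
        rows.append({"participant_id": pid, "study_id": study,
                     "space": predset.space_id, "condition": condition,
                     "z": z, "n_points": n})
    return pd.DataFrame(rows)


def performance_table(predsets: dict[str, PredictionSet],
                      condition: str = "multistudy") -> pd.DataFrame:
    """One row per participant × space."""
    return pd.concat(
        [participant_performance(ps, condition) for ps in predsets.values()],
        ignore_index=True)


# ----------------------------------------------------------------------
# per-module screening


def sidak_level(alpha: float, m: int) -> float:
    """Per-test level controlling family-wise error over m tests."""
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def _obs_on_pred_fit(frame: pd.DataFrame) -> tuple[MixedFitResult, str]:
    """observed ~ predicted with random participant/study intercepts and
    slopes; ladder drops random terms on failure."""
    y = frame["observed"].to_numpy()
    x = frame["predicted"].to_numpy()
    xc = x - x.mean()
    X = np.column_stack([np.ones_like(x), xc])
    pid = frame["participant_id"].to_numpy()
    study = frame["study_id"].to_numpy()
    multi_study = len(set(study)) > 1
    ladders = []
    full = [RandomTerm("participant", pid),
            RandomTerm("participant_slope", pid, xc)]
    if multi_study:
        full += [RandomTerm("study", study), RandomTerm("study_slope", study, xc)]
    ladders.append(("full", full))
    ladders.append(("intercepts", [RandomTerm("participant", pid)]
                    + ([RandomTerm("study", study)] if multi_study else [])))
    last_exc = None
    for name, terms in ladders:
        try:
            fit = MixedModel(y, X, terms, ["intercept", "predicted"]).fit()
            if fit.converged:
                return fit, name
        except (np.linalg.LinAlgError, ValueError) as exc:  # pragma: no cover
            last_exc = exc
    raise RuntimeError(f"screening model failed to converge: {last_exc}")


def screen_modules(per_module: dict[str, PredictionSet], alpha: float = 0.05,
                   ) -> pd.DataFrame:
    """Mixed-model screening of every candidate module at one scale.

    Per module: observed ~ predicted with random participant and study
    intercepts and slopes; significance at the Šidák-adjusted level over the
    m modules of the scale; plus mean z and SEM across participants.
    """
    m = len(per_module)
    level = sidak_level(alpha, m)
    rows = []
    for name, predset in per_module.items():
        fit, ladder = _obs_on_pred_fit(predset.averaged())
        test = fit.contrast_test(np.array([0.0, 1.0]))
        perf = participant_performance(predset)
        z = perf["z"].dropna()
        rows.append({
            "module": name,
            "slope": test["estimate"], "se": test["se"],
            "t": test["t"], "df": test["df_den"], "p": test["p"],
            "significant": test["p"] < level,
            "mean_z": float(z.mean()) if len(z) else np.nan,
            "sem_z": float(z.std(ddof=1) / math.sqrt(len(z)))
            if len(z) > 1 else np.nan,
            "fallback": ladder != "full",
        })
    out = pd.DataFrame(rows)
    out.attrs["sidak_level"] = level
    out.attrs["n_modules"] = m
    return out


# ----------------------------------------------------------------------
# planned model-space comparisons


def planned_contrasts() -> dict[str, np.ndarray]:
    """Orthogonal codes over (REGION, FRSN, CRSN, PATHWAYS, META, FULL).

    C1 distributed − modular; C2 region − networks; C3 cRSN − fRSN;
    C4 meta − pathways; C5 full − multisystem.
    """
    c = {
        "C1_distributed_vs_modular": np.array([-1, -1, -1, 1, 1, 1]) / 3.0,
        "C2_region_vs_networks": np.array([1.0, -0.5, -0.5, 0, 0, 0]),
        "C3_crsn_vs_frsn": np.array([0.0, -1.0, 1.0, 0, 0, 0]),
        "C4_meta_vs_pathways": np.array([0.0, 0, 0, -1.0, 1.0, 0]),
        "C5_full_vs_multisystem": np.array([0.0, 0, 0, -0.5, -0.5, 1.0]),
    }
    return c


@dataclass
class SpaceComparison:
    """Planned-contrast results over the six model spaces."""

    contrasts: pd.DataFrame
    fit: MixedFitResult
    space_order: list[str]
    design_columns: dict[str, np.ndarray]  # per-space design row, scaled codes
    posthoc: dict = field(default_factory=dict)
    fallback: str = "full"

    def overall_test(self) -> dict:
        """Joint F test of all planned contrasts (omnibus scale effect)."""
        q = self.fit.model.p - 1  # contrast coefficients, intercept excluded
        L = np.zeros((q, self.fit.model.p))
        for i in range(q):
            L[i, i + 1] = 1.0
        return self.fit.joint_test(L)

    def summary(self) -> pd.DataFrame:
        return self.contrasts


def _space_design(spaces_per_row: np.ndarray, space_order: list[str],
                  codes: dict[str, np.ndarray]):
    """Design columns scaled so each coefficient estimates its named
    difference directly (column j = code_j / ||code_j||²)."""
    idx = pd.Categorical(spaces_per_row, categories=space_order).codes
    if (idx < 0).any():
        raise ValueError("performance table contains unknown spaces")
    cols, names, scaled = [], [], {}
    for name, code in codes.items():
        d = code / float(code @ code)
        cols.append(d[idx])
        names.append(name)
        scaled[name] = d
    X = np.column_stack([np.ones(len(spaces_per_row))] + cols)
    return X, names, scaled


def _fit_contrast_model(table: pd.DataFrame, codes: dict[str, np.ndarray],
                        space_order: list[str],
                        ) -> tuple[MixedFitResult, list[str], dict, str]:
    table = table.dropna(subset=["z"])
    X, names, scaled = _space_design(table["space"].to_numpy(), space_order,
                                     codes)
    y = table["z"].to_numpy()
    pid = table["participant_id"].to_numpy()
    study = table["study_id"].to_numpy()
    n_studies = len(set(study))
    multi_study = n_studies > 1
    terms = [RandomTerm("participant", pid)]
    ladder = "full"
    if multi_study:
        terms = terms + [RandomTerm("study", study)]
        # slope variances need more study levels than slopes to be
        # identifiable; with too few studies only intercepts are kept
        if n_studies >= len(names) + 2:
            terms = terms + [
                RandomTerm(f"study_slope:{n}", study, X[:, j + 1])
                for j, n in enumerate(names)]
        else:
            ladder = "intercepts"
            logger.info("only %d studies for %d slopes: random study "
                        "slopes omitted", n_studies, len(names))
    try:
        fit = MixedModel(y, X, terms, ["intercept"] + names).fit()
        if not fit.converged:
            raise np.linalg.LinAlgError("no convergence")
    except (np.linalg.LinAlgError, ValueError):
        ladder = "intercepts"
        logger.warning("dropping random slopes (convergence failure)")
        terms = [RandomTerm("participant", pid)]
        if multi_study:
            terms.append(RandomTerm("study", study))
        fit = MixedModel(y, X, terms, ["intercept"] + names).fit()
    return fit, names, scaled, ladder


def compare_spaces(perftable: pd.DataFrame,
                   contrast_spec: dict[str, np.ndarray] | None = None,
                   space_order: list[str] | None = None) -> SpaceComparison:
    """Planned orthogonal contrasts of decoding performance across spaces.

    Fits z ~ contrasts with random participant intercepts and random study
    intercepts and contrast slopes; each planned contrast is F-tested with
    Satterthwaite df.  The non-orthogonal FULL − REGION comparison is fitted
    separately on the two spaces involved.
    """
    space_order = space_order or [s for s in SPACE_IDS
                                  if s in set(perftable["space"])]
    codes = contrast_spec or planned_contrasts()
    fit, names, scaled, ladder = _fit_contrast_model(perftable, codes,
                                                     space_order)
    rows = []
    for j, name in enumerate(names):
        L = np.zeros(fit.model.p)
        L[j + 1] = 1.0
        test = fit.contrast_test(L)
        rows.append({"contrast": name, **test})
    contrasts = pd.DataFrame(rows)

    posthoc = {}
    if {"FULL", "REGION"} <= set(space_order):
        sub = perftable[perftable["space"].isin(["FULL", "REGION"])]
        ph_codes = {"FULL_vs_REGION": np.array([-0.5, 0.5])}
        ph_fit, _, _, _ = _fit_contrast_model(sub, ph_codes,
                                              ["REGION", "FULL"])
        L = np.array([0.0, 1.0])
        posthoc["FULL_vs_REGION"] = ph_fit.contrast_test(L)

    design_columns = {
        s: np.concatenate([[1.0], [scaled[n][space_order.index(s)]
                                   for n in names]])
        for s in space_order
    }
    return SpaceComparison(contrasts, fit, space_order, design_columns,
                           posthoc, ladder)


def bayes_factor_null(perftable: pd.DataFrame, contrast: str,
                      contrast_spec: dict[str, np.ndarray] | None = None,
                      space_order: list[str] | None = None) -> float:
    """BF01 for one planned contrast via the BIC approximation.

    Both models are refit by maximum likelihood with and without the
    contrast's fixed effect (random structure unchanged); BF01 =
    exp((BIC_with − BIC_without)/2).  BF01 > 10 is reported as a confirmed
    null.
    """
    space_order = space_order or [s for s in SPACE_IDS
                                  if s in set(perftable["space"])]
    codes = dict(contrast_spec or planned_contrasts())
    if contrast not in codes:
        raise KeyError(f"unknown contrast {contrast!r}")
    table = perftable.dropna(subset=["z"])
    y = table["z"].to_numpy()
    pid = table["participant_id"].to_numpy()
    study = table["study_id"].to_numpy()
    multi_study = len(set(study)) > 1

    def _ml_bic(drop: bool) -> float:
        use = {k: v for k, v in codes.items() if not (drop and k == contrast)}
        X, names, _ = _space_design(table["space"].to_numpy(), space_order,
                                    use)
        terms = [RandomTerm("participant", pid)]
        if multi_study:
            # slope structure follows the full model so only the fixed
            # effect differs between the two fits
            Xf, fnames, _ = _space_design(table["space"].to_numpy(),
                                          space_order, codes)
            terms = terms + [RandomTerm("study", study)] + [
                RandomTerm(f"study_slope:{n}", study, Xf[:, j + 1])
                for j, n in enumerate(fnames)]
        fit = MixedModel(y, X, terms, ["intercept"] + names).fit(reml=False)
        return fit.bic

    bic_with = _ml_bic(drop=False)
    bic_without = _ml_bic(drop=True)
    return float(math.exp((bic_with - bic_without) / 2.0))


# ----------------------------------------------------------------------
# validation calibration


def calibration_check(comparison: SpaceComparison,
                      holdout_perftable: pd.DataFrame,
                      level: float = 0.95) -> pd.DataFrame:
    """Do holdout-study mean z values fall inside the predictive intervals?

    The predictive interval for a new study's mean z in space *s* combines the
    fixed-effect uncertainty, the study intercept and relevant slope
    variances, and the sampling noise of a finite-participant study mean.
    """
    fit = comparison.fit
    vc = fit.varcomps
    sigma_p = vc.get("participant", 0.0)
    sigma_e = vc["residual"]
    sigma_study = vc.get("study", 0.0)
    slope_vars = {name.split(":", 1)[1]: v for name, v in vc.items()
                  if name.startswith("study_slope:")}
    rows = []
    holdout = holdout_perftable.dropna(subset=["z"])
    for space, x_s in comparison.design_columns.items():
        sub = holdout[holdout["space"] == space]
        if sub.empty:
            continue
        est = float(x_s @ fit.params)
        se_fixed2 = float(x_s @ fit.cov_params @ x_s)
        var_study = sigma_study + sum(
            slope_vars.get(name, 0.0) * x_s[j + 1] ** 2
            for j, name in enumerate(
                [c for c in fit.model.exog_names if c != "intercept"]))
        df = fit.satterthwaite_df(x_s)
        for study, grp in sub.groupby("study_id"):
            n_p = len(grp)
            var_mean = var_study + se_fixed2 + (sigma_p + sigma_e) / n_p
            half = stats.t.ppf(0.5 + level / 2.0, df) * math.sqrt(var_mean)
            observed = float(grp["z"].mean())
            rows.append({
                "space": space, "study_id": study, "expected": est,
                "lower": est - half, "upper": est + half,
                "observed": observed,
                "covered": bool(est - half <= observed <= est + half),
            })
    return pd.DataFrame(rows)
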