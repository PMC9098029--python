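"""Linear mixed models with independent variance components, REML/ML
estimation and Satterthwaite degrees of freedom.

The models needed here all have the form

    y = Xβ + Σ_g b_g + ε,   b_g ~ N(0, σ_g² Z_g Z_g'),   ε ~ N(0, σ² I)

where each random term *g* is a grouping factor (participant, study) paired
with a covariate (1 for a random intercept, a contrast code or predictor for
a random slope), and the components are mutually independent.  Rows are
partitioned into independent blocks (connected components of the grouping
structure), and all likelihood quantities are computed from per-block
sufficient statistics via the Woodbury identity, so one likelihood evaluation
costs O(Σ_b q_b³) with q_b the number of random-effect levels in block *b* —
independent of the number of rows.  That makes simulation-based calibration
of these models practical, and it exposes the Hessian of the restricted
likelihood in the variance parameters, which the Satterthwaite approximation
needs:

    df(c) = 2 (c' C(φ̂) c)² / (∇f' H⁻¹ ∇f),   f(φ) = c' C(φ) c

with C(φ) = (X' Σ(φ)⁻¹ X)⁻¹ and H the observed information of the REML
criterion in φ = (σ_1², ..., σ_G², σ²).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = ["RandomTerm", "MixedModel", "MixedFitResult"]

_LOG2PI = math.log(2.0 * math.pi)


@dataclass(frozen=True)
class RandomTerm:
    """One independent variance component: groups × covariate."""

    name: str
    groups: np.ndarray              # label per row
    covariate: np.ndarray | None = None  # None → random intercept


class MixedModel:
    """Variance-components mixed model fit by REML (or ML).

    Parameters
    ----------
    y : (n,) outcomes
    X : (n, p) fixed-effects design (include the intercept column yourself)
    terms : list of RandomTerm
    exog_names : optional fixed-effect names
    """

    def __init__(self, y, X, terms: list[RandomTerm],
                 exog_names: list[str] | None = None):
        self.y = np.asarray(y, float)
        self.X = np.asarray(X, float)
        if self.X.ndim == 1:
            self.X = self.X[:, None]
        self.n, self.p = self.X.shape
        if self.y.shape != (self.n,):
            raise ValueError("y/X length mismatch")
        self.terms = list(terms)
        self.exog_names = exog_names or [f"x{j}" for j in range(self.p)]
        self._build()

    # ------------------------------------------------------------------
    def _build(self):
        n = self.n
        # columns of the full random-effects design: one per (term, level)
        col_term, col_rows, col_vals = [], [], []
        level_index = 0
        cols = []
        for t_idx, term in enumerate(self.terms):
            groups = np.asarray(term.groups)
            cov = (np.ones(n) if term.covariate is None
                   else np.asarray(term.covariate, float))
            codes, _ = pd.factorize(groups, sort=True)
            n_levels = codes.max() + 1
            for lev in range(n_levels):
                rows = np.flatnonzero(codes == lev)
                cols.append((t_idx, rows, cov[rows]))
            level_index += n_levels
        self.n_cols = len(cols)
        # incidence for block detection: rows sharing any level are dependent
        if self.n_cols:
            indptr_rows = np.concatenate([c[1] for c in cols])
            indptr_cols = np.concatenate([
                np.full(len(c[1]), j) for j, c in enumerate(cols)])
            B = csr_matrix((np.ones(indptr_rows.size), (indptr_rows,
                                                        indptr_cols)),
                           shape=(n, self.n_cols))
            _, labels = connected_components((B @ B.T) > 0, directed=False)
        else:
            labels = np.arange(n)
        self._blocks = []
        for b in np.unique(labels):
            rows = np.flatnonzero(labels == b)
            inblock = [j for j, c in enumerate(cols)
                       if len(c[1]) and labels[c[1][0]] == b]
            pos = {r: i for i, r in enumerate(rows)}
            U = np.zeros((rows.size, len(inblock)))
            cterm = np.empty(len(inblock), dtype=int)
            for jj, j in enumerate(inblock):
                t_idx, rws, vals = cols[j]
                U[[pos[r] for r in rws], jj] = vals
                cterm[jj] = t_idx
            Xb, yb = self.X[rows], self.y[rows]
            self._blocks.append({
                "n": rows.size,
                "col_term": cterm,
                "G": U.T @ U,
                "UtX": U.T @ Xb,
                "Uty": U.T @ yb,
                "XtX": Xb.T @ Xb,
                "Xty": Xb.T @ yb,
                "yty": float(yb @ yb),
            })
        self.n_blocks = len(self._blocks)

    # ------------------------------------------------------------------
    def _collect(self, lam: np.ndarray):
        """Accumulate A = X'V⁻¹X, c = X'V⁻¹y, s = y'V⁻¹y, log|V| for
        V = I + Σ λ_g Z_g Z_g' (variance-ratio scale)."""
        A = np.zeros((self.p, self.p))
        c = np.zeros(self.p)
        s = 0.0
        logdet = 0.0
        for blk in self._blocks:
            d = lam[blk["col_term"]]
            if d.size:
                Dh = np.sqrt(d)
                M = np.eye(d.size) + (Dh[:, None] * blk["G"] * Dh[None, :])
                L = np.linalg.cholesky(M)
                logdet += 2.0 * float(np.log(np.diag(L)).sum())
                # W = D^½ M⁻¹ D^½
                SX = Dh[:, None] * blk["UtX"]
                Sy = Dh * blk["Uty"]
                ZX = np.linalg.solve(L, SX)
                Zy = np.linalg.solve(L, Sy)
                A += blk["XtX"] - ZX.T @ ZX
                c += blk["Xty"] - ZX.T @ Zy
                s += blk["yty"] - float(Zy @ Zy)
            else:
                A += blk["XtX"]
                c += blk["Xty"]
                s += blk["yty"]
        return A, c, s, logdet

    def _neg2_profiled(self, log_lam: np.ndarray, reml: bool) -> float:
        lam = np.exp(np.clip(log_lam, -30.0, 30.0))
        A, c, s, logdet = self._collect(lam)
        try:
            Ainv_c = np.linalg.solve(A, c)
        except np.linalg.LinAlgError:
            return 1e12
        rss = max(s - float(c @ Ainv_c), 1e-12)
        if reml:
            dfr = self.n - self.p
            sign, logdetA = np.linalg.slogdet(A)
            if sign <= 0:
                return 1e12
            return (logdet + logdetA
                    + dfr * (1.0 + _LOG2PI + math.log(rss / dfr)))
        return logdet + self.n * (1.0 + _LOG2PI + math.log(rss / self.n))

    def neg2_reml_phi(self, phi: np.ndarray) -> float:
        """REML criterion in the variance scale φ = (σ_g², ..., σ²)."""
        sigma2 = phi[-1]
        lam = phi[:-1] / sigma2
        A, c, s, logdet = self._collect(lam)
        Ainv_c = np.linalg.solve(A, c)
        rss = max(s - float(c @ Ainv_c), 1e-12)
        sign, logdetA = np.linalg.slogdet(A)
        dfr = self.n - self.p
        return (self.n * math.log(sigma2) + logdet
                + logdetA - self.p * math.log(sigma2)
                + rss / sigma2 + dfr * _LOG2PI)

    def _fixed_cov_phi(self, phi: np.ndarray, return_beta: bool = False):
        sigma2 = phi[-1]
        lam = phi[:-1] / sigma2
        A, c, _, _ = self._collect(lam)
        C = sigma2 * np.linalg.inv(A)
        if return_beta:
            return C, np.linalg.solve(A, c)
        return C

    # ------------------------------------------------------------------
    def fit(self, reml: bool = True, start: np.ndarray | None = None,
            ) -> "MixedFitResult":
        G = len(self.terms)
        if G:
            x0 = np.zeros(G) if start is None else np.log(np.maximum(start,
                                                                     1e-8))
            res = optimize.minimize(
                self._neg2_profiled, x0, args=(reml,), method="L-BFGS-B",
                bounds=[(-18.0, 18.0)] * G,
                options={"maxiter": 500, "ftol": 1e-12})
            log_lam = res.x
            converged = bool(res.success)
        else:
            log_lam = np.zeros(0)
            converged = True
        lam = np.exp(log_lam) if G else np.zeros(0)
        A, c, s, _ = self._collect(lam)
        beta = np.linalg.solve(A, c)
        rss = max(s - float(c @ beta), 1e-12)
        dfr = self.n - self.p
        sigma2 = rss / (dfr if reml else self.n)
        phi = np.concatenate([lam * sigma2, [sigma2]])
        cov_beta = sigma2 * np.linalg.inv(A)
        neg2 = self._neg2_profiled(log_lam, reml)
        return MixedFitResult(
            model=self, reml=reml, params=beta, cov_params=cov_beta,
            sigma2=sigma2, phi=phi, neg2loglike=float(neg2),
            converged=converged,
        )


@dataclass
class MixedFitResult:
    """Fixed-effect estimates, variance components and Satterthwaite tests."""

    model: MixedModel
    reml: bool
    params: np.ndarray
    cov_params: np.ndarray
    sigma2: float
    phi: np.ndarray  # (σ_g², ..., σ²)
    neg2loglike: float
    converged: bool
    _hess_inv: np.ndarray | None = field(default=None, repr=False)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params))

    @property
    def varcomps(self) -> dict[str, float]:
        out = {t.name: float(v) for t, v in zip(self.model.terms,
                                                self.phi[:-1])}
        out["residual"] = float(self.phi[-1])
        return out

    @property
    def n_params(self) -> int:
        return self.model.p + len(self.phi)

    @property
    def bic(self) -> float:
        """BIC from the (ML) deviance; refit with reml=False for model
        comparison across fixed-effect structures."""
        return self.neg2loglike + self.n_params * math.log(self.model.n)

    # ------------------------------------------------------------------
    def _phi_hess_inv(self) -> np.ndarray:
        if self._hess_inv is not None:
            return self._hess_inv
        phi = self.phi
        q = phi.size
        h = np.maximum(1e-7, 1e-4 * np.abs(phi))
        f0 = self.model.neg2_reml_phi(phi)

        def f(p):
            p = np.maximum(p, 1e-12)
            return self.model.neg2_reml_phi(p)

        H = np.zeros((q, q))
        fp = np.zeros(q)
        fm = np.zeros(q)
        for i in range(q):
            ei = np.zeros(q)
            ei[i] = h[i]
            fp[i] = f(phi + ei)
            fm[i] = f(phi - ei)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
        for i in range(q):
            for j in range(i + 1, q):
                ei = np.zeros(q); ei[i] = h[i]
                ej = np.zeros(q); ej[j] = h[j]
                fij = f(phi + ei + ej)
                H[i, j] = H[j, i] = (
                    (fij - fp[i] - fp[j] + f0) / (h[i] * h[j]))
        # H approximates the Hessian of −2ℓ_R; information = H/2
        try:
            inv = np.linalg.inv(H / 2.0)
        except np.linalg.LinAlgError:
            inv = np.linalg.pinv(H / 2.0)
        self._hess_inv = inv
        return inv

    def satterthwaite_df(self, L: np.ndarray) -> float:
        """Satterthwaite denominator df for the scalar contrast L'β."""
        L = np.asarray(L, float)
        phi = self.phi
        f0 = float(L @ self.cov_params @ L)
        h = np.maximum(1e-7, 1e-4 * np.abs(phi))
        grad = np.zeros(phi.size)
        for i in range(phi.size):
            ei = np.zeros(phi.size)
            ei[i] = h[i]
            Cp = self.model._fixed_cov_phi(np.maximum(phi + ei, 1e-12))
            Cm = self.model._fixed_cov_phi(np.maximum(phi - ei, 1e-12))
            grad[i] = (float(L @ Cp @ L) - float(L @ Cm @ L)) / (2 * h[i])
        denom = float(grad @ self._phi_hess_inv() @ grad)
        if denom <= 0 or not np.isfinite(denom):
            return float(self.model.n - self.model.p)
        df = 2.0 * f0 ** 2 / denom
        return float(np.clip(df, 1.0, self.model.n - self.model.p))

    def contrast_test(self, L: np.ndarray) -> dict:
        """t/F test of a single contrast with Satterthwaite df."""
        L = np.asarray(L, float)
        est = float(L @ self.params)
        se = math.sqrt(float(L @ self.cov_params @ L))
        df = self.satterthwaite_df(L)
        t = est / se if se > 0 else np.nan
        p = float(2.0 * stats.t.sf(abs(t), df))
        return {"estimate": est, "se": se, "t": t, "F": t * t,
                "df_num": 1.0, "df_den": df, "p": p}

    def joint_test(self, L: np.ndarray) -> dict:
        """Multi-row F test; denominator df pools per-eigenvector
        Satterthwaite dfs (harmonic combination)."""
        L = np.atleast_2d(np.asarray(L, float))
        q = L.shape[0]
        if q == 1:
            return self.contrast_test(L[0])
        M = L @ self.cov_params @ L.T
        est = L @ self.params
        F = float(est @ np.linalg.solve(M, est)) / q
        w, V = np.linalg.eigh(M)
        dfs = []
        for i in range(q):
            Li = V[:, i] @ L
            dfs.append(self.satterthwaite_df(Li))
        dfs = np.asarray(dfs)
        good = dfs > 2.0
        if good.any():
            E = float(np.sum(dfs[good] / (dfs[good] - 2.0)))
            df_den = 2.0 * E / max(E - q, 1e-6) if E > q else float(
                self.model.n - self.model.p)
        else:
            df_den = float(self.model.n - self.model.p)
        p = float(stats.f.sf(F, q, df_den))
        return {"F": F, "df_num": float(q), "df_den": df_den, "p": p,
                "estimate": [float(e) for e in est]}

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, b, se in zip(self.model.exog_names, self.params, self.bse):
            test = self.contrast_test(
                np.eye(self.model.p)[self.model.exog_names.index(name)])
            rows.append({"term": name, "estimate": b, "se": se,
                         "t": test["t"], "df": test["df_den"], "p": test["p"]})
        return pd.DataFrame(rows)
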