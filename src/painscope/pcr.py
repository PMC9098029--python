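"""Principal component regression with cross-validated dimension choice.

PCR projects the (column-centered, unscaled) training images onto their
leading principal components, regresses ratings on the first *k* component
scores by ordinary least squares, and back-projects the coefficients to a
voxel-weight vector.  *k* is a hyperparameter in ``[1, R]`` (R = rank of the
training matrix; intercept-only models, k = 0, are precluded), chosen to
minimize inner-cross-validated mean squared error either by Bayesian
optimization (Gaussian-process surrogate, expected-improvement acquisition)
or by a deterministic exhaustive grid.

Because the component scores are orthogonal, one SVD of each inner-training
split yields validation predictions for *every* k at once, so a single
evaluation of the MSE curve is cheap regardless of the search strategy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

__all__ = [
    "PCRModel",
    "DimOptConfig",
    "fit_pcr",
    "apply_model",
    "matrix_rank",
    "inner_cv_mse_curve",
    "optimize_dims",
]


def matrix_rank(s: np.ndarray, n: int, p: int) -> int:
    """Numerical rank from singular values: s > max(n, p)·eps·s₁."""
    if s.size == 0 or s[0] == 0:
        return 0
    tol = max(n, p) * np.finfo(float).eps * s[0]
    return int(np.sum(s > tol))


@dataclass
class PCRModel:
    """A trained linear decoder over one voxel set.

    Prediction for an image *x* (restricted to ``voxels``) is
    ``(x − column_means) · weights + intercept``.
    """

    weights: np.ndarray
    intercept: float
    k: int
    column_means: np.ndarray
    voxels: np.ndarray | None = None  # indices into the mask; None = all
    descriptor: dict = field(default_factory=dict)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Score images given over the full mask (or already restricted)."""
        images = np.asarray(images, float)
        if self.voxels is not None and images.shape[1] != self.weights.size:
            images = images[:, self.voxels]
        if images.shape[1] != self.weights.size:
            raise ValueError(
                f"image has {images.shape[1]} voxels, model expects "
                f"{self.weights.size}"
            )
        return (images - self.column_means) @ self.weights + self.intercept


def fit_pcr(X: np.ndarray, y: np.ndarray, k: int,
            voxels: np.ndarray | None = None,
            descriptor: dict | None = None) -> PCRModel:
    """Fit a k-component PCR model (columns centered, never scaled)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if k < 1:
        raise ValueError("intercept-only models (k = 0) are precluded")
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 training rows")
    mu = X.mean(axis=0)
    Xc = X - mu
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    r = matrix_rank(s, n, p)
    if k > r:
        raise ValueError(f"k={k} exceeds training-matrix rank {r}")
    coef = (U[:, :k].T @ y) / s[:k]  # scores are orthogonal with norms s_j
    W = Vt[:k].T @ coef
    return PCRModel(
        weights=W,
        intercept=float(y.mean()),
        k=int(k),
        column_means=mu,
        voxels=None if voxels is None else np.asarray(voxels, int),
        descriptor=descriptor or {},
    )


def apply_model(model: PCRModel, images: np.ndarray) -> np.ndarray:
    """Score standardized images with a trained model (affine in the image)."""
    return model.predict(images)


# ----------------------------------------------------------------------
# dimension optimization


@dataclass
class DimOptConfig:
    """How to search the PCR dimension: 'bayes' (default) or 'grid'.

    ``rel_tol`` applies a parsimony rule: among dimensions whose inner-CV
    MSE is within this relative tolerance of the minimum, the smallest is
    chosen (the curve is typically flat past the optimum, and extra
    components only add estimation noise).
    """

    method: str = "grid"
    n_evals: int = 30
    n_init: int = 5
    seed: int = 0
    rel_tol: float = 0.01

    def __post_init__(self):
        if self.method not in ("bayes", "grid"):
            raise ValueError("method must be 'bayes' or 'grid'")
        if self.n_evals < 2:
            raise ValueError("n_evals must be ≥ 2")


def inner_cv_mse_curve(X: np.ndarray, y: np.ndarray,
                       folds: Sequence[tuple[np.ndarray, np.ndarray]],
                       ) -> np.ndarray:
    """Pooled validation MSE for every dimension k = 1..kmax.

    kmax is the smallest training-split rank across folds, so every k in the
    curve is fittable in every fold.  One SVD per fold yields the whole curve.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    per_fold = []
    kmax = None
    for tr, te in folds:
        Xtr, ytr = X[tr], y[tr]
        mu = Xtr.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xtr - mu, full_matrices=False)
        r = matrix_rank(s, *Xtr.shape)
        if r < 1:
            raise ValueError("degenerate training split (rank 0)")
        coef = (U[:, :r].T @ ytr) / s[:r]
        A = (X[te] - mu) @ Vt[:r].T  # validation scores
        contrib = A * coef
        cum = np.cumsum(contrib, axis=1) + ytr.mean()  # preds for k=1..r
        sq = (cum - y[te][:, None]) ** 2
        per_fold.append(sq)
        kmax = r if kmax is None else min(kmax, r)
    sse = np.zeros(kmax)
    count = 0
    for sq in per_fold:
        sse += sq[:, :kmax].sum(axis=0)
        count += sq.shape[0]
    return sse / count


def _expected_improvement(mu: np.ndarray, sd: np.ndarray,
                          best: float) -> np.ndarray:
    sd = np.maximum(sd, 1e-12)
    z = (best - mu) / sd
    return sd * (z * norm.cdf(z) + norm.pdf(z))


def optimize_dims(X: np.ndarray, y: np.ndarray,
                  inner_folds: Sequence[tuple[np.ndarray, np.ndarray]],
                  opt_cfg: DimOptConfig | None = None) -> int:
    """Choose the PCR dimension minimizing inner-CV MSE.

    ``inner_folds`` must group rows by participant.  In 'grid' mode the whole
    curve is scanned; in 'bayes' mode a Gaussian-process surrogate with
    expected-improvement acquisition spends ``n_evals`` evaluations on the
    integer range.  Ties break toward smaller k.
    """
    opt_cfg = opt_cfg or DimOptConfig()
    curve = inner_cv_mse_curve(X, y, inner_folds)
    kmax = curve.size
    if kmax == 1:
        return 1
    if opt_cfg.method == "grid" or opt_cfg.n_evals >= kmax:
        best = float(curve.min())
        return int(np.flatnonzero(
            curve <= best * (1.0 + opt_cfg.rel_tol))[0]) + 1

    rng = np.random.default_rng(opt_cfg.seed)
    ks = list({1, kmax} | {
        int(k) for k in rng.choice(np.arange(2, kmax), size=min(
            max(opt_cfg.n_init - 2, 0), kmax - 2), replace=False)
    })
    observed = {k: float(curve[k - 1]) for k in ks}
    kernel = (ConstantKernel(1.0, (1e-3, 1e3))
              * RBF(length_scale=kmax / 8, length_scale_bounds=(1.0, kmax * 2))
              + WhiteKernel(1e-6, (1e-10, 1e-1)))
    cand = np.arange(1, kmax + 1)
    while len(observed) < min(opt_cfg.n_evals, kmax):
        xs = np.array(sorted(observed))[:, None].astype(float)
        ys = np.array([observed[int(k)] for k in xs.ravel()])
        scale = ys.std() or 1.0
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=False,
                                      random_state=int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gp.fit(xs, (ys - ys.mean()) / scale)
        mu, sd = gp.predict(cand[:, None].astype(float), return_std=True)
        best = (ys.min() - ys.mean()) / scale
        ei = _expected_improvement(mu, sd, best)
        ei[[k - 1 for k in observed]] = -np.inf
        k_next = int(cand[np.argmax(ei)])
        observed[k_next] = float(curve[k_next - 1])
    best_mse = min(observed.values())
    return min(k for k, v in observed.items()
               if v <= best_mse * (1.0 + opt_cfg.rel_tol))
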