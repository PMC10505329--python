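"""Gaussian mixture modelling of seed-word vectors with AIC model selection.

Seed food words are assumed to form a finite number of Gaussian clusters in
the embedding space (food groups: baked goods, produce, ...). A mixture is
fitted by EM for every combination of component count K and covariance family
(full, tied, diag, spherical), and the model with the lowest
AIC = 2·n_params − 2·log_likelihood wins.

Membership of an arbitrary word vector in a fitted component — whether the
word lies "inside the hyperellipse" of a cluster at probability level p — is
exposed in two interpretations:

``posterior``
    the component's posterior responsibility γ_k(x) is at least p;
``quantile``
    x lies inside the component's p-mass ellipsoid, i.e. the squared
    Mahalanobis distance to μ_k is at most the χ²(d) quantile at p.

Both are first-class because the two give genuinely different harvest sets;
callers must pick one explicitly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

__all__ = [
    "COV_TYPES",
    "GaussianMixtureModel",
    "CalibrationError",
    "count_params",
    "fit_gmm",
    "em_log_likelihood_trace",
    "calibrate",
    "membership",
    "membership_matrix",
]

COV_TYPES = ("full", "tied", "diag", "spherical")

#: Diagonal jitter added to covariances. High-dimensional full-covariance
#: components on a few thousand points are singular without it.
DEFAULT_REG_COVAR = 1e-6


class CalibrationError(RuntimeError):
    """Every (K, cov_type) fit in a calibration grid failed."""


def count_params(K: int, d: int, cov_type: str) -> int:
    """Free-parameter count of a K-component, d-dimensional mixture.

    (K−1) mixing weights + K·d means + covariance terms:
    full K·d(d+1)/2, tied d(d+1)/2, diag K·d, spherical K.
    """
    if K < 1 or d < 1:
        raise ValueError("K and d must be >= 1")
    if cov_type == "full":
        cov = K * d * (d + 1) // 2
    elif cov_type == "tied":
        cov = d * (d + 1) // 2
    elif cov_type == "diag":
        cov = K * d
    elif cov_type == "spherical":
        cov = K
    else:
        raise ValueError(f"unknown covariance type {cov_type!r}")
    return (K - 1) + K * d + cov


@dataclass
class GaussianMixtureModel:
    """A fitted mixture with its selection statistics.

    ``covariances`` keeps sklearn's family-dependent shape: (K, d, d) for
    full, (d, d) for tied, (K, d) for diag, (K,) for spherical.
    """

    K: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    cov_type: str
    log_likelihood: float
    aic: float
    n_params: int
    seed: int
    converged: bool
    _gm: GaussianMixture | None = None

    @property
    def d(self) -> int:
        return self.means.shape[1]

    def responsibilities(self, X: np.ndarray) -> np.ndarray:
        """Posterior probability of each component for each row of X."""
        return self._sk().predict_proba(np.atleast_2d(X))

    def mahalanobis_sq(self, X: np.ndarray) -> np.ndarray:
        """Squared Mahalanobis distance of each row to each component mean.

        Uses the fitted precision Cholesky factors: ‖(x−μ_k)ᵀ P_k‖².
        """
        X = np.atleast_2d(np.asarray(X, dtype=float))
        gm = self._sk()
        prec = gm.precisions_cholesky_
        n = X.shape[0]
        out = np.empty((n, self.K))
        for k in range(self.K):
            diff = X - self.means[k]
            if self.cov_type == "full":
                y = diff @ prec[k]
            elif self.cov_type == "tied":
                y = diff @ prec
            elif self.cov_type == "diag":
                y = diff * prec[k]
            else:  # spherical
                y = diff * prec[k]
            out[:, k] = np.einsum("ij,ij->i", y, y)
        return out

    def score_samples(self, X: np.ndarray) -> np.ndarray:
        """Per-row log density log Σ_k π_k N(x; μ_k, Σ_k)."""
        return self._sk().score_samples(np.atleast_2d(X))

    def _sk(self) -> GaussianMixture:
        if self._gm is None:
            raise RuntimeError("model has no attached estimator")
        return self._gm


def _wrap(gm: GaussianMixture, X: np.ndarray, seed: int) -> GaussianMixtureModel:
    n = X.shape[0]
    ll = float(gm.score(X) * n)
    npar = count_params(gm.n_components, X.shape[1], gm.covariance_type)
    return GaussianMixtureModel(
        K=gm.n_components,
        weights=gm.weights_,
        means=gm.means_,
        covariances=gm.covariances_,
        cov_type=gm.covariance_type,
        log_likelihood=ll,
        aic=2.0 * npar - 2.0 * ll,
        n_params=npar,
        seed=seed,
        converged=bool(gm.converged_),
        _gm=gm,
    )


def fit_gmm(
    X: np.ndarray,
    K: int,
    cov_type: str = "full",
    seed: int = 0,
    *,
    max_iter: int = 100,
    tol: float = 1e-3,
    reg_covar: float = DEFAULT_REG_COVAR,
) -> GaussianMixtureModel:
    """EM-fit a K-component mixture; deterministic given the seed.

    Initialization is k-means based; convergence is declared when the mean
    per-sample log-likelihood improves by less than ``tol``. Non-convergence
    within ``max_iter`` returns the model with ``converged=False``.
    """
    X = np.asarray(X, dtype=float)
    if cov_type not in COV_TYPES:
        raise ValueError(f"unknown covariance type {cov_type!r}")
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n samples x d features)")
    n = X.shape[0]
    if K < 1 or n <= K:
        raise ValueError(f"need n > K >= 1, got n={n}, K={K}")
    gm = GaussianMixture(
        n_components=K,
        covariance_type=cov_type,
        reg_covar=reg_covar,
        max_iter=max_iter,
        tol=tol,
        init_params="kmeans",
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        gm.fit(X)
    return _wrap(gm, X, seed)


def em_log_likelihood_trace(
    X: np.ndarray, K: int, cov_type: str, seed: int, n_steps: int = 30
) -> list[float]:
    """Total log-likelihood after each EM iteration (for monotonicity checks).

    Runs sklearn's EM one step at a time via warm starts so the trace is the
    genuine iterate sequence of a single run.
    """
    X = np.asarray(X, dtype=float)
    gm = GaussianMixture(
        n_components=K,
        covariance_type=cov_type,
        reg_covar=DEFAULT_REG_COVAR,
        max_iter=1,
        tol=0.0,
        warm_start=True,
        init_params="kmeans",
        random_state=seed,
    )
    trace: list[float] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for _ in range(n_steps):
            gm.fit(X)
            trace.append(float(gm.score(X) * X.shape[0]))
    return trace


def calibrate(
    X: np.ndarray,
    K_grid: "list[int] | range",
    cov_types: "tuple[str, ...] | list[str]" = COV_TYPES,
    seed: int = 0,
    **fit_kwargs,
) -> tuple[GaussianMixtureModel, pd.DataFrame]:
    """Grid-search (K, cov_type) and return the minimum-AIC model + AIC table.

    A two-stage coarse-then-fine search is just two calls: run a wide K grid
    with a large step, then re-run with a unit-step grid around the winner.
    The table has one row per attempted fit (columns: K, cov_type, n_params,
    log_likelihood, aic, converged) including failed fits with NaN AIC.
    """
    K_grid = list(K_grid)
    cov_types = list(cov_types)
    if not K_grid or not cov_types:
        raise ValueError("calibration grids must be non-empty")
    best: GaussianMixtureModel | None = None
    rows = []
    for K in K_grid:
        for ct in cov_types:
            try:
                m = fit_gmm(X, K, ct, seed, **fit_kwargs)
            except (ValueError, np.linalg.LinAlgError) as exc:
                rows.append(
                    {
                        "K": K,
                        "cov_type": ct,
                        "n_params": np.nan,
                        "log_likelihood": np.nan,
                        "aic": np.nan,
                        "converged": False,
                        "error": str(exc),
                    }
                )
                continue
            rows.append(
                {
                    "K": K,
                    "cov_type": ct,
                    "n_params": m.n_params,
                    "log_likelihood": m.log_likelihood,
                    "aic": m.aic,
                    "converged": m.converged,
                    "error": "",
                }
            )
            if best is None or m.aic < best.aic:
                best = m
    table = pd.DataFrame(rows)
    if best is None:
        raise CalibrationError("all fits in the calibration grid failed")
    return best, table


def membership(
    model: GaussianMixtureModel,
    x: np.ndarray,
    p: float,
    mode: str = "posterior",
) -> tuple[np.ndarray, np.ndarray]:
    """Per-component acceptance of one point at probability level ``p``.

    Returns ``(accepted, values)`` over the K components. In ``posterior``
    mode ``values`` are responsibilities and acceptance is γ_k(x) >= p; in
    ``quantile`` mode ``values`` are squared Mahalanobis distances and
    acceptance is Mahalanobis² <= χ²_d(p). A point is inside the model if
    any component accepts it.
    """
    acc, val = membership_matrix(model, np.atleast_2d(x), p, mode)
    return acc[0], val[0]


def membership_matrix(
    model: GaussianMixtureModel,
    X: np.ndarray,
    p: float,
    mode: str = "posterior",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`membership` over the rows of X (n x K outputs)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability level must be in (0, 1), got {p}")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.d:
        raise ValueError(f"dimension mismatch: x has {X.shape[1]}, model {model.d}")
    if mode == "posterior":
        values = model.responsibilities(X)
        accepted = values >= p
    elif mode == "quantile":
        values = model.mahalanobis_sq(X)
        accepted = values <= stats.chi2.ppf(p, df=model.d)
    else:
        raise ValueError(f"unknown membership mode {mode!r}")
    return accepted, values
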