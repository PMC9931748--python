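"""Sparse inverse covariance (graphical lasso) and partial correlations.

A group-level Gaussian graphical model is estimated by maximizing

    log det(T) - tr(S T) - lambda * sum_{i != j} |T_ij|

over symmetric positive-definite precision matrices T, where S is the
empirical covariance of the (standardized) group data and the L1 penalty
acts on off-diagonal entries only.  Zeros of T encode conditional
independence; the partial correlation between nodes i and j is

    P_ij = -T_ij / sqrt(T_ii * T_jj).

The penalty is selected by k-fold cross-validation maximizing held-out
Gaussian log-likelihood on a log-spaced grid with iterative refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso
from sklearn.model_selection import KFold

#: entries of the precision matrix below this magnitude are structural zeros
ZERO_TOL = 1e-10


class EstimationError(RuntimeError):
    """Graphical lasso failed to produce a valid precision matrix."""


@dataclass
class PrecisionModel:
    """Fitted group-level sparse precision matrix and derived quantities."""

    covariance_emp: np.ndarray
    precision: np.ndarray
    pcorr: np.ndarray
    penalty: float
    n_samples: int
    cv_grid: list[tuple[float, float]] | None = None
    roi_names: list[str] | None = None
    converged: bool = True

    @property
    def n_nodes(self) -> int:
        return self.precision.shape[0]

    def edge_values(self) -> np.ndarray:
        """Partial correlations of the upper triangle, row-major order."""
        iu = np.triu_indices(self.n_nodes, k=1)
        return self.pcorr[iu]


def empirical_covariance(X: np.ndarray) -> np.ndarray:
    """Biased (1/n) empirical covariance of column-centered data."""
    X = np.asarray(X, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries in data matrix")
    if X.shape[0] < 2:
        raise ValueError(f"need at least 2 samples, got {X.shape[0]}")
    Xc = X - X.mean(axis=0)
    return (Xc.T @ Xc) / X.shape[0]


def partial_correlations(precision: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix of a symmetric positive-definite precision."""
    d = np.diag(precision)
    if np.any(d <= 0):
        raise ValueError("precision matrix has non-positive diagonal entries")
    denom = np.sqrt(np.outer(d, d))
    P = -precision / denom
    np.fill_diagonal(P, 1.0)
    # structural zeros in the precision are exact zeros in P
    off = ~np.eye(P.shape[0], dtype=bool)
    P[off & (np.abs(precision) < ZERO_TOL)] = 0.0
    return P


def kkt_residual(S: np.ndarray, precision: np.ndarray, penalty: float) -> float:
    """Max violation of the stationarity conditions at a candidate solution.

    With W = T^{-1}, optimality of the off-diagonal-penalized problem
    requires W_ij - S_ij = penalty * sign(T_ij) where T_ij != 0 (i != j),
    |W_ij - S_ij| <= penalty where T_ij = 0, and W_ii = S_ii.
    """
    W = np.linalg.inv(precision)
    G = W - S
    p = S.shape[0]
    off = ~np.eye(p, dtype=bool)
    nz = off & (np.abs(precision) >= ZERO_TOL)
    z = off & ~nz
    res = np.abs(np.diag(G)).max(initial=0.0)
    if nz.any():
        res = max(res, np.abs(G[nz] - penalty * np.sign(precision[nz])).max())
    if z.any():
        res = max(res, max(0.0, np.abs(G[z]).max() - penalty))
    return float(res)


def fit_graphical_lasso(
    S: np.ndarray,
    penalty: float,
    n_samples: int = 0,
    roi_names: list[str] | None = None,
    max_iter: int = 100,
    tol: float = 1e-4,
    enet_tol: float = 1e-4,
) -> PrecisionModel:
    """Estimate a sparse precision matrix at a fixed penalty.

    At ``penalty == 0`` the solution is the plain matrix inverse (requires a
    positive-definite S).  Otherwise sklearn's coordinate-descent graphical
    lasso solver is used; entries below 1e-10 are recorded as exact zeros.
    When the solver's duality-gap criterion is not met within the iteration
    budget the last iterate is returned with ``converged=False`` (its KKT
    residual is typically still small); a solver hard failure raises
    :class:`EstimationError`.
    """
    S = np.asarray(S, dtype=np.float64)
    if penalty < 0:
        raise ValueError("penalty must be >= 0")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("covariance matrix is not symmetric")
    if penalty == 0.0:
        eigmin = np.linalg.eigvalsh(S)[0]
        if eigmin <= 0:
            raise EstimationError(
                f"unpenalized fit requires positive-definite S (min eig {eigmin:.3g})"
            )
        precision = np.linalg.inv(S)
        precision = (precision + precision.T) / 2.0
        converged = True
    else:
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                _, precision = _sk_graphical_lasso(
                    S, alpha=penalty, max_iter=max_iter, tol=tol, enet_tol=enet_tol
                )
        except (FloatingPointError, np.linalg.LinAlgError) as exc:
            raise EstimationError(f"graphical lasso failed: {exc}") from exc
        converged = not any("did not converge" in str(w.message) for w in caught)
        if not np.isfinite(precision).all():
            raise EstimationError("graphical lasso returned non-finite entries")
        precision = (precision + precision.T) / 2.0
        precision[np.abs(precision) < ZERO_TOL] = 0.0
    return PrecisionModel(
        covariance_emp=S,
        precision=precision,
        pcorr=partial_correlations(precision),
        penalty=float(penalty),
        n_samples=int(n_samples),
        roi_names=roi_names,
        converged=converged,
    )


def _loglik(S_test: np.ndarray, precision: np.ndarray) -> float:
    """Held-out Gaussian log-likelihood (up to an additive constant)."""
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        return -np.inf
    return float(logdet - np.trace(S_test @ precision))


def penalty_upper_bound(S: np.ndarray) -> float:
    """Smallest penalty at which the estimate is exactly diagonal."""
    off = ~np.eye(S.shape[0], dtype=bool)
    return float(np.abs(S[off]).max())


def select_penalty_cv(
    X: np.ndarray,
    folds: int = 3,
    n_grid: int = 10,
    n_refinements: int = 4,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> tuple[float, list[tuple[float, float]]]:
    """Choose the L1 penalty by k-fold cross-validated log-likelihood.

    The grid spans [0.01 * lam_max, lam_max] log-spaced, where lam_max is
    the largest absolute off-diagonal covariance (at which the estimate is
    exactly diagonal); each refinement round re-centers a new log-spaced
    grid on the neighbors of the current best point.  Fold assignment is
    shuffled by ``seed``, so the result is deterministic given the seed.
    """
    X = np.asarray(X, dtype=np.float64)
    n = X.shape[0]
    if n < 3 * folds:
        raise ValueError(f"need at least 3*folds={3 * folds} samples, got {n}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(kf.split(X))

    lam_max = penalty_upper_bound(empirical_covariance(X))
    lo, hi = 0.01 * lam_max, lam_max
    grid_scores: dict[float, float] = {}
    for _ in range(n_refinements):
        grid = np.logspace(np.log10(lo), np.log10(hi), n_grid)
        for lam in grid:
            lam = float(lam)
            if lam in grid_scores:
                continue
            scores = []
            for train, test in splits:
                S_tr = empirical_covariance(X[train])
                S_te = empirical_covariance(X[test])
                try:
                    model = fit_graphical_lasso(S_tr, lam, tol=tol, max_iter=max_iter)
                except EstimationError:
                    warnings.warn(
                        f"degenerate fold at penalty {lam:.4g}; scored -inf",
                        stacklevel=2,
                    )
                    scores.append(-np.inf)
                    continue
                scores.append(_loglik(S_te, model.precision))
            grid_scores[lam] = float(np.mean(scores))
        ordered = sorted(grid_scores)
        best_i = int(np.argmax([grid_scores[l] for l in ordered]))
        lo = ordered[max(best_i - 1, 0)]
        hi = ordered[min(best_i + 1, len(ordered) - 1)]
    cv_grid = sorted(grid_scores.items())
    best = max(cv_grid, key=lambda kv: kv[1])[0]
    return best, cv_grid


def fit_group_network(
    X: np.ndarray,
    penalty: float | None = None,
    folds: int = 3,
    n_grid: int = 10,
    n_refinements: int = 4,
    seed: int = 0,
    roi_names: list[str] | None = None,
    cv_tol: float = 1e-4,
    cv_max_iter: int = 100,
) -> PrecisionModel:
    """Fit the group network; CV-select the penalty when not given."""
    X = np.asarray(X, dtype=np.float64)
    cv_grid = None
    if penalty is None:
        penalty, cv_grid = select_penalty_cv(
            X,
            folds=folds,
            n_grid=n_grid,
            n_refinements=n_refinements,
            seed=seed,
            tol=cv_tol,
            max_iter=cv_max_iter,
        )
    S = empirical_covariance(X)
    model = fit_graphical_lasso(S, penalty, n_samples=X.shape[0], roi_names=roi_names)
    model.cv_grid = cv_grid
    return model
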