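"""LASSO linear regression by cyclic coordinate descent, with cross-validated
regularization.

The objective (on internally standardized predictors and centered response) is

    (1 / 2n) * ||y - b0 - X b||^2 + lambda * ||b||_1

with an unpenalized intercept.  Coordinate updates use the soft-threshold
``S(z, lambda) = sign(z) * max(|z| - lambda, 0)``; with standardized columns
the update for coordinate j is ``b_j <- S(rho_j + b_j, lambda)`` where
``rho_j`` is the current correlation of column j with the residual.

Fits run on precomputed Gram matrices so that the cross-validation and the
1000-fold stability reruns downstream stay cheap: per fold the Gram is the
full-data Gram minus the held-out block (a rank-``n_out`` downdate), and the
lambda path is solved with warm starts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["lasso_fit", "lambda_max", "lasso_path", "cv_select_lambda", "StandardizedProblem"]


def _cd_kernel_py(G: np.ndarray, c: np.ndarray, beta: np.ndarray, lam: float, tol: float, max_sweeps: int) -> None:
    """Cyclic coordinate descent on a (small) active-set sub-Gram, in place."""
    m = beta.shape[0]
    rho = c - G @ beta
    for _ in range(max_sweeps):
        delta = 0.0
        for j in range(m):
            z = rho[j] + beta[j]
            bj = (1.0 if z > 0 else -1.0) * max(abs(z) - lam, 0.0)
            d = bj - beta[j]
            if d != 0.0:
                rho -= d * G[:, j]
                beta[j] = bj
                if abs(d) > delta:
                    delta = abs(d)
        if delta < tol:
            return


try:  # pragma: no cover - exercised implicitly when numba is present
    import numba

    _cd_kernel = numba.njit(cache=False)(_cd_kernel_py)
except Exception:  # pragma: no cover
    _cd_kernel = _cd_kernel_py


@dataclass
class StandardizedProblem:
    """Sufficient statistics of a standardized LASSO problem.

    Everything the coordinate solver needs is derived from the raw Gram
    ``X'X``, the raw moment vector ``X'y`` and the first moments, so folds
    can be carved out of a full-data Gram by subtraction.
    """

    n: int
    X_std: np.ndarray  # standardized data (n x p); dropped columns zeroed
    c: np.ndarray  # standardized X' centered-y / n  (p,)
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    keep: np.ndarray  # columns with non-zero variance

    @classmethod
    def from_data(cls, X: np.ndarray, y: np.ndarray) -> "StandardizedProblem":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n = len(y)
        x_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        keep = sd > 1e-12
        if not np.all(keep):
            warnings.warn(f"dropping {np.count_nonzero(~keep)} zero-variance columns")
        sd_safe = np.where(keep, sd, 1.0)
        X_std = (X - x_mean) / sd_safe
        X_std[:, ~keep] = 0.0
        y_mean = float(y.mean())
        c = X_std.T @ (y - y_mean) / n
        return cls(n, X_std, c, x_mean, sd_safe, y_mean, keep)

    def _gram_dot(self, idx: np.ndarray, b: np.ndarray) -> np.ndarray:
        """``Gs[:, idx] @ b`` as two thin matrix-vector products."""
        v = self.X_std[:, idx] @ b
        return self.X_std.T @ v / self.n

    def _sub_gram(self, idx: np.ndarray) -> np.ndarray:
        Xi = self.X_std[:, idx]
        return np.ascontiguousarray(Xi.T @ Xi / self.n)

    @property
    def lambda_max(self) -> float:
        return float(np.max(np.abs(self.c))) if self.c.size else 0.0

    def solve(
        self,
        lam: float,
        beta0: np.ndarray | None = None,
        tol: float = 1e-7,
        max_iter: int = 10_000,
    ) -> np.ndarray:
        """Coordinate descent at one lambda (standardized scale).

        Active-set strategy: sweep all coordinates, then iterate over the
        active set until stable, then re-sweep; converged when the largest
        coefficient change in a full sweep is below ``tol``.
        """
        if lam < 0:
            raise ValueError("lambda must be non-negative")
        p = len(self.c)
        beta = np.zeros(p) if beta0 is None else beta0.copy()
        beta[~self.keep] = 0.0
        for _ in range(50):
            act = np.flatnonzero(beta)
            # vectorized KKT screen: inactive coordinates whose residual
            # correlation exceeds lambda must enter the active set
            rho = self.c - (self._gram_dot(act, beta[act]) if act.size else 0.0)
            viol = (np.abs(rho) > lam + 1e-12) & self.keep & (beta == 0.0)
            if not viol.any():
                if act.size == 0:
                    return beta
                # active set optimal w.r.t. screening; one tight polish pass
                sub = np.sort(act)
                b_a = beta[sub]
                _cd_kernel(self._sub_gram(sub), self.c[sub], b_a, lam, tol, max_iter)
                beta[:] = 0.0
                beta[sub] = b_a
                rho = self.c - self._gram_dot(sub, b_a)
                if not ((np.abs(rho) > lam + 1e-12) & self.keep & (beta == 0.0)).any():
                    return beta
                continue
            sub = np.sort(np.concatenate([act, np.flatnonzero(viol)]))
            b_a = beta[sub]
            _cd_kernel(self._sub_gram(sub), self.c[sub], b_a, lam, tol, max_iter)
            beta[:] = 0.0
            beta[sub] = b_a
        return beta

    def to_original_scale(self, beta_std: np.ndarray) -> tuple[float, np.ndarray]:
        beta = np.where(self.keep, beta_std / self.x_sd, 0.0)
        intercept = self.y_mean - float(self.x_mean @ beta)
        return intercept, beta


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest lambda at which every slope is zero (KKT bound)."""
    return StandardizedProblem.from_data(X, y).lambda_max


def lasso_fit(
    X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-7
) -> tuple[float, np.ndarray]:
    """LASSO coefficients on the original predictor scale.

    Returns ``(intercept, coefficients)``.  Zero-variance columns are dropped
    (coefficient 0) with a warning; ``lam < 0`` raises.
    """
    prob = StandardizedProblem.from_data(X, y)
    beta_std = prob.solve(lam, tol=tol)
    return prob.to_original_scale(beta_std)


def _default_path(lmax: float, n_lambdas: int = 100, min_ratio: float = 1e-3) -> np.ndarray:
    return lmax * np.logspace(0, np.log10(min_ratio), n_lambdas)


def lasso_path(
    prob: StandardizedProblem,
    lambdas: np.ndarray,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
) -> np.ndarray:
    """Warm-started solutions (standardized scale) along a decreasing path."""
    p = len(prob.c)
    out = np.zeros((len(lambdas), p))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta = prob.solve(lam, beta0=beta, tol=tol, max_iter=max_sweeps)
        out[i] = beta
    return out


def _fold_assignment(n: int, n_folds: int, fold_seed: int) -> np.ndarray:
    """Fold labels by seeded random permutation, sizes differing by <= 1."""
    rng = np.random.default_rng(fold_seed)
    labels = np.tile(np.arange(n_folds), n // n_folds + 1)[:n]
    return labels[rng.permutation(n)]


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    fold_seed: int = 0,
    n_lambdas: int = 100,
    min_ratio: float = 1e-3,
    full_problem: StandardizedProblem | None = None,
    cv_tol: float = 1e-4,
    rule: str = "min",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Pick lambda by minimum mean cross-validated MSE over a log-spaced path.

    The path runs from the full-data ``lambda_max`` down to ``lambda_max *
    min_ratio``.  Folds come from a seeded permutation.  Ties in CV MSE break
    toward the larger (more parsimonious) lambda.  Returns ``(lambda, path,
    mean CV MSE per path point)``.

    Fold fits along the path are solved at the looser ``cv_tol`` (the CV MSE
    curve is insensitive to coefficient error far below the noise scale);
    refit at the chosen lambda with the default tight tolerance.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < n_folds:
        raise ValueError("need at least as many samples as folds")
    if full_problem is None:
        full_problem = StandardizedProblem.from_data(X, y)
    path = _default_path(full_problem.lambda_max, n_lambdas, min_ratio)

    folds = _fold_assignment(n, n_folds, fold_seed)
    se = np.zeros((n_folds, len(path)))
    for f in range(n_folds):
        out = folds == f
        Xo, yo = X[out], y[out]
        prob = StandardizedProblem.from_data(X[~out], y[~out])
        # capped sweeps: deep-path fits are only needed to MSE accuracy
        betas = lasso_path(prob, path, tol=cv_tol, max_sweeps=200)
        for i in range(len(path)):
            support = np.flatnonzero(betas[i])
            b0, b = prob.to_original_scale(betas[i])
            resid = yo - (b0 + Xo[:, support] @ b[support])
            se[f, i] = float(np.mean(resid**2))
    mean_mse = se.mean(axis=0)
    best = int(np.argmin(mean_mse))  # argmin returns the first (largest-lambda) tie
    if rule == "1se":
        # largest lambda whose CV MSE is within one standard error of the minimum
        se_best = float(se[:, best].std(ddof=1) / np.sqrt(n_folds))
        best = int(np.argmax(mean_mse <= mean_mse[best] + se_best))
    elif rule != "min":
        raise ValueError("rule must be 'min' or '1se'")
    return float(path[best]), path, mean_mse
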