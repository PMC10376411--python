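"""Cross-lagged panel network estimation via node-wise LASSO regression.

Each wave-2 item is regressed on all wave-1 items (plus optional age and
gender covariates) with an L1 penalty, objective

    (1/2n) * ||y - X b||^2 + lambda * ||b||_1,

solved by cyclic coordinate descent with warm starts along a decreasing
lambda grid. The per-node penalty is chosen by seeded K-fold
cross-validation (minimum mean held-out squared error). Predictors and
outcome are z-scored on the analysis sample, so edge weights are
standardized regression coefficients: entry [i, j] of the network is
wave-1 item i predicting wave-2 item j, the diagonal holding the
autoregressive (self-prediction) coefficients. Covariate coefficients
are estimated per node but kept out of the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import linear_model
from sklearn.model_selection import KFold

from .panel import SymptomPanel

__all__ = [
    "LassoFit",
    "CLPNetwork",
    "lasso_path",
    "select_lambda_cv",
    "estimate_clpn",
    "write_network",
    "edge_list",
]

_TOL = 1e-9  # coordinate-descent tolerance (relative duality-gap scale)


@dataclass
class LassoFit:
    """One node's penalized fit: coefficients at the selected penalty."""

    coefficients: np.ndarray
    intercept: float
    lambda_: float
    cv_curve: pd.DataFrame  # columns: lambda, cv_mse, cv_se


@dataclass
class CLPNetwork:
    """Directed cross-lagged network (rows = wave-1 source, cols = wave-2 target)."""

    weights: np.ndarray
    item_labels: list[str]
    lambda_selected: np.ndarray
    covariate_coefficients: np.ndarray  # (n_covariates, p)
    covariate_labels: list[str]
    estimation_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        p = len(self.item_labels)
        if self.weights.shape != (p, p):
            raise ValueError(f"weights must be {p}x{p}")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("non-finite edge weights")

    @property
    def p(self) -> int:
        return len(self.item_labels)

    @property
    def autoregressive(self) -> np.ndarray:
        return np.diag(self.weights).copy()

    @property
    def cross_lagged(self) -> np.ndarray:
        """Off-diagonal weights, diagonal zeroed."""
        out = self.weights.copy()
        np.fill_diagonal(out, 0.0)
        return out

    def density(self) -> float:
        """Share of nonzero entries among all p*p estimable edges."""
        return float(np.count_nonzero(self.weights)) / self.weights.size


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Z-score columns; constant columns are zeroed with a warning."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"constant predictor column(s) {np.flatnonzero(const).tolist()}: coefficients fixed at 0",
            stacklevel=3,
        )
    sd_safe = np.where(const, 1.0, sd)
    Z = (X - mu) / sd_safe
    Z[:, const] = 0.0
    return Z, const


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty that zeroes every coefficient: max_j |x_j'y| / n."""
    return float(np.max(np.abs(X.T @ y)) / len(y))


def default_lambda_grid(X: np.ndarray, y: np.ndarray, n_lambda: int = 100,
                        min_ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced decreasing grid from lambda_max down to min_ratio * lambda_max."""
    lmax = lambda_max(X, y)
    if lmax <= 0:  # outcome orthogonal to every predictor
        lmax = 1e-3
    return np.geomspace(lmax, min_ratio * lmax, n_lambda)


def lasso_path(X: np.ndarray, y: np.ndarray, lambda_grid: np.ndarray) -> np.ndarray:
    """Coefficient vectors along a decreasing penalty grid.

    ``X`` is expected column-standardized and ``y`` centered (the
    convention of every caller here); solutions use cyclic coordinate
    descent with warm starts. Returns an array of shape
    ``(len(lambda_grid), n_predictors)`` in grid order.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    if len(y) <= 2:
        raise ValueError("need n > 2 rows")
    grid = np.asarray(lambda_grid, dtype=float)
    if np.any(grid < 0):
        raise ValueError("penalties must be non-negative")
    order = np.argsort(grid)[::-1]  # solver wants decreasing
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # alpha=0 convergence chatter
        _, coefs, _ = linear_model.lasso_path(
            X, y, alphas=grid[order], tol=_TOL, max_iter=100_000
        )
    out = np.empty((len(grid), X.shape[1]))
    out[order] = coefs.T
    return out


def select_lambda_cv(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 10,
    lambda_grid: np.ndarray | None = None,
    seed: int = 0,
) -> LassoFit:
    """Pick the penalty by K-fold CV (minimum mean squared error).

    Fold assignment is drawn from ``seed``; within each training fold
    the predictors and outcome are re-centered before the path solve.
    The fit is refit on the full data at the selected penalty.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if not 2 <= n_folds <= n:
        raise ValueError(f"n_folds must lie in [2, {n}]")
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y)
    grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % 2**32)
    sq_err = np.zeros((n_folds, len(grid)))
    for f, (tr, te) in enumerate(kf.split(X)):
        xm, ym = X[tr].mean(axis=0), y[tr].mean()
        coefs = lasso_path(X[tr] - xm, y[tr] - ym, grid)
        pred = (X[te] - xm) @ coefs.T + ym
        sq_err[f] = ((y[te, None] - pred) ** 2).mean(axis=0)
    cv_mse = sq_err.mean(axis=0)
    cv_se = sq_err.std(axis=0, ddof=1) / np.sqrt(n_folds)
    best = int(np.argmin(cv_mse))

    coefs_full = lasso_path(X - X.mean(axis=0), y - y.mean(), grid)
    beta = coefs_full[best]
    intercept = float(y.mean() - X.mean(axis=0) @ beta)
    curve = pd.DataFrame({"lambda": grid, "cv_mse": cv_mse, "cv_se": cv_se})
    return LassoFit(coefficients=beta, intercept=intercept, lambda_=float(grid[best]), cv_curve=curve)


def estimate_clpn(
    panel: SymptomPanel,
    include_covariates: bool = True,
    n_folds: int = 10,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
    fixed_lambda: float | None = None,
) -> CLPNetwork:
    """Estimate the directed cross-lagged panel network from a panel.

    One penalized regression per wave-2 item on all z-scored wave-1
    items (plus z-scored age and gender when ``include_covariates``),
    outcome z-scored. Each node draws its CV folds from an independent
    child of ``seed``, so single-node fits are reproducible in
    isolation. ``fixed_lambda`` skips cross-validation and fits every
    node at the given penalty (0 gives node-wise OLS).
    """
    p = panel.n_items
    if panel.n < 30:
        warnings.warn(f"n={panel.n} < 30: network estimates will be unstable", stacklevel=2)
    X_items = panel.wave1_items.to_numpy(dtype=float)
    covariate_labels = ["age", "gender"] if include_covariates else []
    blocks = [X_items]
    if include_covariates:
        blocks.append(np.column_stack([panel.age, panel.gender]))
    X_raw = np.column_stack(blocks)
    Z, _ = _standardize(X_raw)

    child_seeds = np.random.SeedSequence(seed).spawn(p)
    weights = np.zeros((p, p))
    cov_coefs = np.zeros((len(covariate_labels), p))
    lambdas = np.zeros(p)
    for j in range(p):
        y_raw = panel.wave2_items.iloc[:, j].to_numpy(dtype=float)
        sd = y_raw.std(ddof=0)
        yz = (y_raw - y_raw.mean()) / (sd if sd > 0 else 1.0)
        if fixed_lambda is not None:
            beta = lasso_path(Z, yz, np.array([fixed_lambda]))[0]
            lambdas[j] = fixed_lambda
        else:
            node_seed = int(child_seeds[j].generate_state(1)[0] % 2**31)
            fit = select_lambda_cv(Z, yz, n_folds=n_folds, lambda_grid=lambda_grid, seed=node_seed)
            beta, lambdas[j] = fit.coefficients, fit.lambda_
        weights[:, j] = beta[:p]
        if include_covariates:
            cov_coefs[:, j] = beta[p:]
    return CLPNetwork(
        weights=weights,
        item_labels=panel.item_labels,
        lambda_selected=lambdas,
        covariate_coefficients=cov_coefs,
        covariate_labels=covariate_labels,
        estimation_meta={
            "n": panel.n,
            "n_folds": n_folds,
            "seed": seed,
            "standardized": True,
            "include_covariates": include_covariates,
            "fixed_lambda": fixed_lambda,
        },
    )


def edge_list(net: CLPNetwork, include_zero: bool = False) -> pd.DataFrame:
    """Long-format edges: source, target, weight, type."""
    rows = []
    for i, src in enumerate(net.item_labels):
        for j, tgt in enumerate(net.item_labels):
            w = net.weights[i, j]
            if w != 0 or include_zero:
                rows.append(
                    {
                        "source": src,
                        "target": tgt,
                        "weight": w,
                        "type": "autoregressive" if i == j else "cross_lagged",
                    }
                )
    return pd.DataFrame(rows, columns=["source", "target", "weight", "type"])


def write_network(net: CLPNetwork, out_dir: str | Path, stem: str = "clpn") -> tuple[Path, Path]:
    """Write the dense labeled matrix and the edge list as CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mat_path = out / f"{stem}_matrix.csv"
    edge_path = out / f"{stem}_edges.csv"
    pd.DataFrame(net.weights, index=net.item_labels, columns=net.item_labels).to_csv(mat_path)
    edge_list(net).to_csv(edge_path, index=False)
    return mat_path, edge_path
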