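"""Per-wave undirected regularized partial-correlation networks.

The cross-sectional estimator is the graphical lasso over a log-spaced
penalty grid, with the extended Bayesian information criterion (EBIC)
selecting the penalty:

    EBIC = -2 * loglik + E * log(n) + 4 * gamma * E * log(p)

where E counts nonzero upper-triangle edges. The selected precision
matrix Theta is converted to partial correlations
rho_ij = -Theta_ij / sqrt(Theta_ii * Theta_jj). An unregularized
partial-correlation estimator (straight precision inversion) is also
provided; it is the cheap choice inside permutation loops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.covariance import graphical_lasso

__all__ = [
    "CrossSectionalNetwork",
    "correlation_matrix",
    "ebic_glasso",
    "partial_correlations",
    "global_strength",
    "network_correlation",
    "glasso_estimator",
    "partial_correlation_estimator",
]

_EDGE_EPS = 1e-10  # below this magnitude an edge counts as absent
_PSD_TOL = -1e-8


@dataclass
class CrossSectionalNetwork:
    """Symmetric regularized partial-correlation network for one wave."""

    partial_correlations: np.ndarray
    lambda_: float
    ebic_gamma: float
    n_used: int

    def __post_init__(self) -> None:
        P = self.partial_correlations
        if not np.allclose(P, P.T, atol=1e-10):
            raise ValueError("partial-correlation matrix must be symmetric")
        if np.any(np.abs(P) > 1 + 1e-8):
            raise ValueError("partial correlations must lie in [-1, 1]")
        if np.any(np.abs(np.diag(P)) > 1e-12):
            raise ValueError("diagonal must be zero")

    @property
    def n_edges(self) -> int:
        iu = np.triu_indices_from(self.partial_correlations, k=1)
        return int(np.sum(np.abs(self.partial_correlations[iu]) > _EDGE_EPS))


def correlation_matrix(
    items: np.ndarray | pd.DataFrame, method: str = "pearson"
) -> np.ndarray:
    """Item intercorrelations (Pearson or Spearman)."""
    X = np.asarray(items, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = np.flatnonzero(sds == 0).tolist()
        raise ValueError(f"constant item column(s) {bad}: correlation undefined")
    if method == "pearson":
        R = np.corrcoef(X, rowvar=False)
    elif method == "spearman":
        # rank-transform then Pearson; robust to the 2-column scalar case
        ranks = np.apply_along_axis(stats.rankdata, 0, X)
        R = np.corrcoef(ranks, rowvar=False)
    else:
        raise ValueError(f"unknown method '{method}'")
    np.fill_diagonal(R, 1.0)
    return (R + R.T) / 2


def _precision_to_pcor(theta: np.ndarray) -> np.ndarray:
    d = np.sqrt(np.diag(theta))
    P = -theta / np.outer(d, d)
    np.fill_diagonal(P, 0.0)
    P = np.clip((P + P.T) / 2, -1.0, 1.0)
    return P


def partial_correlations(R: np.ndarray) -> np.ndarray:
    """Unregularized partial correlations via precision-matrix inversion."""
    return _precision_to_pcor(np.linalg.pinv(R))


def ebic_glasso(
    R: np.ndarray,
    n: int,
    gamma: float = 0.5,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.01,
) -> CrossSectionalNetwork:
    """Graphical lasso with EBIC penalty selection.

    Scans a log-spaced grid from the smallest penalty that empties the
    graph down to ``lambda_min_ratio`` times it, scoring each fit with
    the EBIC at hyperparameter ``gamma`` and returning the minimizer as
    a partial-correlation network.
    """
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if np.min(np.linalg.eigvalsh(R)) < _PSD_TOL:
        raise ValueError(
            "correlation matrix is not positive semi-definite; "
            "repair it (e.g. nearest-PSD projection) before estimation"
        )
    offdiag = np.abs(R[~np.eye(p, dtype=bool)])
    lmax = float(offdiag.max()) if offdiag.size else 1.0
    if lmax <= 0:
        lmax = 1e-3
    grid = np.geomspace(lmax, lambda_min_ratio * lmax, n_lambda)

    best = None
    for lam in grid:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, theta = graphical_lasso(R, alpha=float(lam), max_iter=200)
        except (FloatingPointError, np.linalg.LinAlgError):
            continue
        P = _precision_to_pcor(theta)
        iu = np.triu_indices(p, k=1)
        E = int(np.sum(np.abs(P[iu]) > _EDGE_EPS))
        sign, logdet = np.linalg.slogdet(theta)
        if sign <= 0:
            continue
        loglik = 0.5 * n * (logdet - np.trace(R @ theta) - p * np.log(2 * np.pi))
        ebic = -2 * loglik + E * np.log(n) + 4 * gamma * E * np.log(p)
        if best is None or ebic < best[0]:
            best = (ebic, lam, P)
    if best is None:
        raise RuntimeError("graphical lasso failed on the whole penalty grid")
    _, lam, P = best
    return CrossSectionalNetwork(
        partial_correlations=P, lambda_=float(lam), ebic_gamma=gamma, n_used=n
    )


def global_strength(net: CrossSectionalNetwork | np.ndarray) -> float:
    """Sum of absolute upper-triangle edge weights."""
    W = net.partial_correlations if isinstance(net, CrossSectionalNetwork) else np.asarray(net)
    iu = np.triu_indices_from(W, k=1)
    return float(np.abs(W[iu]).sum())


def network_correlation(A: np.ndarray, B: np.ndarray, directed: bool | None = None) -> float:
    """Pearson correlation between the unique edge weights of two networks.

    Symmetric matrices are vectorized over the upper triangle; directed
    ones over all off-diagonal entries. ``directed=None`` autodetects
    from symmetry of both inputs.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("need two square matrices of identical shape")
    if directed is None:
        directed = not (np.allclose(A, A.T) and np.allclose(B, B.T))
    if directed:
        mask = ~np.eye(A.shape[0], dtype=bool)
        a, b = A[mask], B[mask]
    else:
        iu = np.triu_indices_from(A, k=1)
        a, b = A[iu], B[iu]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero-variance edge vector: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def glasso_estimator(
    gamma: float = 0.5, n_lambda: int = 100, lambda_min_ratio: float = 0.01,
    method: str = "pearson",
):
    """Items -> partial-correlation matrix, via EBIC graphical lasso."""

    def estimate(items: np.ndarray) -> np.ndarray:
        R = correlation_matrix(items, method=method)
        net = ebic_glasso(R, n=len(items), gamma=gamma, n_lambda=n_lambda,
                          lambda_min_ratio=lambda_min_ratio)
        return net.partial_correlations

    return estimate


def partial_correlation_estimator(method: str = "pearson"):
    """Items -> unregularized partial-correlation matrix (fast)."""

    def estimate(items: np.ndarray) -> np.ndarray:
        return partial_correlations(correlation_matrix(items, method=method))

    return estimate
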