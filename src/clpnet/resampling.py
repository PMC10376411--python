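"""Bootstrap stability and accuracy machinery for estimated networks.

Two resampling schemes:

* **case-dropping bootstrap** — repeatedly drop a fixed proportion of
  participants, re-estimate the network, and correlate the re-estimated
  centralities with the full-sample ones. The correlation-stability
  coefficient (CS) is the largest drop proportion at which the
  correlation stays >= 0.7 with 95% probability; CS >= 0.25 is the
  conventional bar for acceptable stability.
* **nonparametric bootstrap** — resample rows with replacement and
  collect percentile confidence intervals for every edge, plus
  CI-exclusion difference tests between pairs of edges or nodes.

All draws are reproducible from one master seed; replicate b at grid
point q uses its own child stream, so enlarging ``n_boot`` leaves
earlier replicates unchanged.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import SymptomPanel

__all__ = [
    "StabilityResult",
    "EdgeBootstrapResult",
    "case_dropping_bootstrap",
    "cs_coefficient",
    "edge_ci_bootstrap",
    "difference_tests",
]

DEFAULT_DROP_GRID = tuple(np.round(np.arange(0.05, 0.751, 0.05), 2))


@dataclass
class StabilityResult:
    """Case-dropping correlations per drop proportion and centrality index."""

    drop_proportions: np.ndarray
    correlations: dict  # index name -> (n_proportions, n_boot) array, NaN = failed
    n_boot: int
    seed: int
    n_failed: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Long format: index, drop_proportion, replicate, correlation."""
        rows = []
        for name, arr in self.correlations.items():
            for qi, q in enumerate(self.drop_proportions):
                for b in range(arr.shape[1]):
                    rows.append(
                        {"index": name, "drop_proportion": q, "replicate": b,
                         "correlation": arr[qi, b]}
                    )
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path, threshold: float = 0.7, probability: float = 0.95) -> None:
        cs = cs_coefficient(self, threshold=threshold, probability=probability)
        payload = {
            "drop_proportions": np.asarray(self.drop_proportions).tolist(),
            "cs_coefficient": cs,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "n_failed": self.n_failed,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class EdgeBootstrapResult:
    """Row-resampling bootstrap of every edge weight."""

    sample_weights: np.ndarray
    draws: np.ndarray = field(repr=False)  # (n_boot, p, p), NaN slices = failed
    ci_lower: np.ndarray = field(repr=False, default=None)
    ci_upper: np.ndarray = field(repr=False, default=None)
    bootstrap_mean: np.ndarray = field(repr=False, default=None)
    n_boot: int = 0
    seed: int = 0
    n_failed: int = 0

    def __post_init__(self) -> None:
        if self.ci_lower is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # all-NaN slices
                self.ci_lower = np.nanquantile(self.draws, 0.025, axis=0)
                self.ci_upper = np.nanquantile(self.draws, 0.975, axis=0)
                self.bootstrap_mean = np.nanmean(self.draws, axis=0)


def _as_weights(net) -> np.ndarray:
    return np.asarray(getattr(net, "weights", net), dtype=float)


def case_dropping_bootstrap(
    panel: SymptomPanel,
    estimator,
    centrality_fn,
    drop_proportions: tuple = DEFAULT_DROP_GRID,
    n_boot: int = 1000,
    seed: int = 0,
) -> StabilityResult:
    """Correlation of subsample centralities with full-sample centralities.

    ``estimator`` maps a panel to a network; ``centrality_fn`` maps a
    network to ``{index_name: vector}``. For each drop proportion q and
    replicate, ``ceil((1 - q) * n)`` rows are retained without
    replacement. Failed estimations are stored as NaN and counted.
    """
    qs = np.asarray(sorted(drop_proportions), dtype=float)
    if np.any(qs < 0) or np.any(qs >= 1):
        raise ValueError("drop proportions must lie in [0, 1)")
    full_cent = {k: np.asarray(v, dtype=float) for k, v in centrality_fn(estimator(panel)).items()}
    n = panel.n
    p = panel.n_items
    smallest = math.ceil((1 - qs.max()) * n)
    if smallest < 3 * p:
        warnings.warn(
            f"smallest retained subsample ({smallest}) < 3*p ({3 * p}); "
            "stability estimates may be erratic",
            stacklevel=2,
        )
    corrs = {k: np.full((len(qs), n_boot), np.nan) for k in full_cent}
    n_failed = 0
    for qi, q in enumerate(qs):
        keep = math.ceil((1 - q) * n)
        for b in range(n_boot):
            rng = np.random.default_rng([seed, qi, b])
            idx = rng.choice(n, size=keep, replace=False)
            try:
                cent = centrality_fn(estimator(panel.take(idx)))
            except Exception:
                n_failed += 1
                continue
            for k, v in cent.items():
                v = np.asarray(v, dtype=float)
                if np.std(v) == 0 or np.std(full_cent[k]) == 0:
                    corrs[k][qi, b] = np.nan
                else:
                    corrs[k][qi, b] = np.corrcoef(full_cent[k], v)[0, 1]
    return StabilityResult(
        drop_proportions=qs, correlations=corrs, n_boot=n_boot, seed=seed, n_failed=n_failed
    )


def cs_coefficient(
    res: StabilityResult, threshold: float = 0.7, probability: float = 0.95
) -> dict:
    """Correlation-stability coefficient per centrality index.

    The largest drop proportion in the grid whose empirical
    (1 - probability) quantile of correlations is >= threshold; 0 when
    no grid point qualifies.
    """
    out = {}
    for name, arr in res.correlations.items():
        cs = 0.0
        for qi, q in enumerate(res.drop_proportions):
            vals = arr[qi][~np.isnan(arr[qi])]
            if vals.size == 0:
                continue
            if np.quantile(vals, 1 - probability) >= threshold:
                cs = max(cs, float(q))
        out[name] = cs
    return out


def edge_ci_bootstrap(
    panel: SymptomPanel,
    estimator,
    n_boot: int = 1000,
    seed: int = 0,
) -> EdgeBootstrapResult:
    """Percentile bootstrap CIs (2.5th/97.5th) for every edge weight."""
    if panel.n < 3 * panel.n_items:
        warnings.warn(f"n={panel.n} < 3*p: bootstrap CIs may be erratic", stacklevel=2)
    W_full = _as_weights(estimator(panel))
    n = panel.n
    draws = np.full((n_boot,) + W_full.shape, np.nan)
    n_failed = 0
    for b in range(n_boot):
        rng = np.random.default_rng([seed, b])
        idx = rng.choice(n, size=n, replace=True)
        try:
            draws[b] = _as_weights(estimator(panel.take(idx)))
        except Exception:
            n_failed += 1
    return EdgeBootstrapResult(
        sample_weights=W_full, draws=draws, n_boot=n_boot, seed=seed, n_failed=n_failed
    )


def difference_tests(
    boot: EdgeBootstrapResult | np.ndarray, alpha: float = 0.05
) -> np.ndarray:
    """CI-exclusion tests between all pairs of bootstrapped quantities.

    Input is either an :class:`EdgeBootstrapResult` (its p*p edges are
    vectorized row-major) or a draws matrix of shape (n_boot, m). For
    each pair (i, j) the percentile CI of value_i - value_j at level
    ``1 - alpha`` is computed over replicates; the pair is flagged
    significant when that CI excludes zero. Returns a symmetric boolean
    m x m matrix with an all-False diagonal.
    """
    if isinstance(boot, EdgeBootstrapResult):
        draws = boot.draws.reshape(boot.draws.shape[0], -1)
    else:
        draws = np.asarray(boot, dtype=float)
    if draws.ndim != 2:
        raise ValueError("need a (n_boot, m) draws matrix")
    m = draws.shape[1]
    lo_q, hi_q = alpha / 2, 1 - alpha / 2
    sig = np.zeros((m, m), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(m):
            diffs = draws[:, i : i + 1] - draws  # (n_boot, m)
            lo = np.nanquantile(diffs, lo_q, axis=0)
            hi = np.nanquantile(diffs, hi_q, axis=0)
            sig[i] = (lo > 0) | (hi < 0)
    np.fill_diagonal(sig, False)
    return sig | sig.T  # |difference| is symmetric in (i, j)
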