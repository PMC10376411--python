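"""Permutation network comparison test (NCT) for paired two-wave data.

Compares two estimated networks on (a) global strength invariance —
S = |difference in summed absolute edge weights|; (b) structure
invariance — M = the maximum absolute edge difference; and (c) each
individual edge. The null distribution is built by randomly swapping,
per participant and independently, the wave-1 and wave-2 item vectors
(each with probability 1/2) and re-estimating both networks. Under the
null of exchangeable waves this preserves the within-person pairing.
P-values use the add-one permutation estimator
(1 + #{null >= observed}) / (1 + B), so they are never exactly zero.
An unpaired group-relabeling variant is provided for independent
samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cross_sectional import global_strength

__all__ = ["NCTResult", "nct_paired", "nct_unpaired", "edge_invariance_report"]

_MAX_RETRY_FACTOR = 10


@dataclass
class NCTResult:
    global_strength_a: float
    global_strength_b: float
    s_diff: float
    p_global: float
    m_statistic: float
    p_structure: float
    edge_p_values: np.ndarray
    n_permutations: int
    seed: int
    network_a: np.ndarray = field(repr=False, default=None)
    network_b: np.ndarray = field(repr=False, default=None)
    n_retried: int = 0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "global_strength_a": self.global_strength_a,
            "global_strength_b": self.global_strength_b,
            "s_diff": self.s_diff,
            "p_global": self.p_global,
            "m_statistic": self.m_statistic,
            "p_structure": self.p_structure,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "n_retried": self.n_retried,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _stats(W_a: np.ndarray, W_b: np.ndarray) -> tuple[float, float, np.ndarray]:
    s = abs(global_strength(W_a) - global_strength(W_b))
    diff = np.abs(W_a - W_b)
    iu = np.triu_indices_from(diff, k=1)
    return s, float(diff[iu].max()), diff


def _run_nct(items_a, items_b, estimator, n_permutations, seed, permute):
    """Shared permutation engine; `permute(rng)` yields permuted (a, b)."""
    W_a = np.asarray(estimator(items_a), dtype=float)
    W_b = np.asarray(estimator(items_b), dtype=float)
    s_obs, m_obs, diff_obs = _stats(W_a, W_b)

    rng = np.random.default_rng(seed)
    exceed_s = exceed_m = 0
    exceed_edges = np.zeros_like(diff_obs)
    retried = 0
    done = 0
    max_attempts = _MAX_RETRY_FACTOR * n_permutations
    attempts = 0
    while done < n_permutations:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"estimator failed too often inside permutations ({retried} retries)"
            )
        pa, pb = permute(rng)
        try:
            N_a = np.asarray(estimator(pa), dtype=float)
            N_b = np.asarray(estimator(pb), dtype=float)
        except Exception:
            retried += 1
            continue
        s_null, m_null, diff_null = _stats(N_a, N_b)
        exceed_s += s_null >= s_obs
        exceed_m += m_null >= m_obs
        exceed_edges += diff_null >= diff_obs
        done += 1

    B = n_permutations
    edge_p = (1.0 + exceed_edges) / (1.0 + B)
    np.fill_diagonal(edge_p, 1.0)
    edge_p = (edge_p + edge_p.T) / 2
    return NCTResult(
        global_strength_a=global_strength(W_a),
        global_strength_b=global_strength(W_b),
        s_diff=s_obs,
        p_global=(1.0 + exceed_s) / (1.0 + B),
        m_statistic=m_obs,
        p_structure=(1.0 + exceed_m) / (1.0 + B),
        edge_p_values=edge_p,
        n_permutations=B,
        seed=seed,
        network_a=W_a,
        network_b=W_b,
        n_retried=retried,
    )


def nct_paired(
    items_a: np.ndarray,
    items_b: np.ndarray,
    estimator,
    n_permutations: int = 1000,
    seed: int = 0,
) -> NCTResult:
    """Paired NCT: rows of ``items_a`` and ``items_b`` are the same people.

    ``estimator`` maps an n x p item matrix to a symmetric weight
    matrix. A failed estimation within a permutation is retried with a
    fresh swap pattern and counted in ``n_retried``.
    """
    A = np.asarray(items_a, dtype=float)
    B_items = np.asarray(items_b, dtype=float)
    if A.shape != B_items.shape:
        raise ValueError("paired conditions need identical shapes")
    if n_permutations < 20:
        raise ValueError("n_permutations < 20 gives too coarse a p-value resolution")

    def permute(rng):
        swap = rng.random(A.shape[0]) < 0.5
        pa = np.where(swap[:, None], B_items, A)
        pb = np.where(swap[:, None], A, B_items)
        return pa, pb

    return _run_nct(A, B_items, estimator, n_permutations, seed, permute)


def nct_unpaired(
    items_a: np.ndarray,
    items_b: np.ndarray,
    estimator,
    n_permutations: int = 1000,
    seed: int = 0,
) -> NCTResult:
    """Unpaired NCT: group labels are permuted across pooled rows."""
    A = np.asarray(items_a, dtype=float)
    B_items = np.asarray(items_b, dtype=float)
    if A.shape[1] != B_items.shape[1]:
        raise ValueError("conditions must share the item set")
    if n_permutations < 20:
        raise ValueError("n_permutations < 20 gives too coarse a p-value resolution")
    pooled = np.vstack([A, B_items])
    n_a = len(A)

    def permute(rng):
        idx = rng.permutation(len(pooled))
        return pooled[idx[:n_a]], pooled[idx[n_a:]]

    return _run_nct(A, B_items, estimator, n_permutations, seed, permute)


def edge_invariance_report(
    res: NCTResult, alpha: float = 0.05, holm: bool = False,
    item_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Edges whose permutation p-value falls below ``alpha``.

    Per-edge p-values are unadjusted unless ``holm`` applies the Holm
    step-down correction over all p(p-1)/2 edges. Sorted by p-value.
    """
    P = res.edge_p_values
    p = P.shape[0]
    labels = item_labels or [f"item{i + 1}" for i in range(p)]
    iu = np.triu_indices(p, k=1)
    pvals = P[iu]
    if holm:
        pvals = multipletests(pvals, method="holm")[1]
    rows = [
        {
            "node_a": labels[i],
            "node_b": labels[j],
            "p_value": pv,
            "adjusted": holm,
        }
        for i, j, pv in zip(iu[0], iu[1], pvals)
        if pv < alpha
    ]
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "p_value", "adjusted"])
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
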