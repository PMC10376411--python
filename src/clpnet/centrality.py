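"""Expected-influence centralities for directed symptom networks.

Out expected influence (OEI) of a node is the signed sum of its
outgoing cross-lagged edges — how strongly the symptom predicts the
others; in expected influence (IEI) is the signed sum of incoming
edges — how strongly it is predicted. Autoregressive (self-loop)
coefficients are excluded from both and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import CLPNetwork

__all__ = [
    "CentralityTable",
    "out_expected_influence",
    "in_expected_influence",
    "centrality_table",
    "rank_report",
]


@dataclass
class CentralityTable:
    item_labels: list[str]
    out_expected_influence: np.ndarray
    in_expected_influence: np.ndarray
    autoregressive: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.item_labels,
                "oei": self.out_expected_influence,
                "iei": self.in_expected_influence,
                "autoregressive": self.autoregressive,
            }
        )


def _cross_lagged(net: CLPNetwork | np.ndarray) -> np.ndarray:
    W = net.weights if isinstance(net, CLPNetwork) else np.asarray(net, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("need a square weight matrix")
    out = W.copy()
    np.fill_diagonal(out, 0.0)
    return out


def out_expected_influence(net: CLPNetwork | np.ndarray) -> np.ndarray:
    """OEI_i = sum over j != i of weights[i, j] (signed)."""
    return _cross_lagged(net).sum(axis=1)


def in_expected_influence(net: CLPNetwork | np.ndarray) -> np.ndarray:
    """IEI_j = sum over i != j of weights[i, j] (signed)."""
    return _cross_lagged(net).sum(axis=0)


def centrality_table(net: CLPNetwork) -> CentralityTable:
    return CentralityTable(
        item_labels=list(net.item_labels),
        out_expected_influence=out_expected_influence(net),
        in_expected_influence=in_expected_influence(net),
        autoregressive=net.autoregressive,
    )


def rank_report(tab: CentralityTable, k: int | None = None) -> dict:
    """Top-k items per index, ties broken by item order (stable sort).

    Returns ``{"oei": [(item, value), ...], "iei": [...]}`` with values
    sorted descending.
    """
    p = len(tab.item_labels)
    if k is None:
        k = p
    if k > p:
        raise ValueError(f"k={k} exceeds number of items {p}")
    report = {}
    for name, vals in (("oei", tab.out_expected_influence), ("iei", tab.in_expected_influence)):
        order = np.argsort(-np.asarray(vals), kind="stable")[:k]
        report[name] = [(tab.item_labels[i], float(vals[i])) for i in order]
    return report
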