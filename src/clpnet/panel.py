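"""Matched two-wave symptom panel container.

A :class:`SymptomPanel` holds item responses for the same participants at
two assessment waves, together with covariates (age, gender) and the
per-wave total score of a depression screener. It is the universal input
of every downstream stage (screening, descriptives, network estimation,
resampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SymptomPanel"]


@dataclass
class SymptomPanel:
    """Two-wave item-level panel with matched rows.

    Parameters
    ----------
    ids
        Unique participant keys, one per row.
    age, gender
        Covariates; age in years, gender coded 0/1.
    wave1_items, wave2_items
        Integer item responses (n x p), same columns and row order in
        both waves. Values must lie within ``item_bounds``.
    wave1_screener_total, wave2_screener_total
        Per-wave screener sum scores (e.g. PHQ-9 totals in [0, 27]).
    item_bounds, screener_bounds
        Inclusive (low, high) bounds used for validation.
    meta
        Free-form provenance: generator seed, warnings, dropped counts.
    """

    ids: np.ndarray
    age: np.ndarray
    gender: np.ndarray
    wave1_items: pd.DataFrame
    wave2_items: pd.DataFrame
    wave1_screener_total: np.ndarray
    wave2_screener_total: np.ndarray
    item_bounds: tuple[int, int] = (1, 5)
    screener_bounds: tuple[int, int] = (0, 27)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.age = np.asarray(self.age, dtype=float)
        self.gender = np.asarray(self.gender, dtype=int)
        self.wave1_screener_total = np.asarray(self.wave1_screener_total, dtype=int)
        self.wave2_screener_total = np.asarray(self.wave2_screener_total, dtype=int)
        n = len(self.ids)
        for name in ("age", "gender", "wave1_screener_total", "wave2_screener_total"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} has {len(getattr(self, name))} rows, expected {n}")
        if self.wave1_items.shape[0] != n or self.wave2_items.shape[0] != n:
            raise ValueError("item matrices must have one row per participant")
        if list(self.wave1_items.columns) != list(self.wave2_items.columns):
            raise ValueError("wave1 and wave2 item columns differ")
        if len(np.unique(self.ids)) != n:
            raise ValueError("duplicated participant keys")
        lo, hi = self.item_bounds
        for wave, items in (("wave1", self.wave1_items), ("wave2", self.wave2_items)):
            vals = items.to_numpy()
            if vals.size and (vals.min() < lo or vals.max() > hi):
                raise ValueError(f"{wave} item scores outside [{lo}, {hi}]")
        slo, shi = self.screener_bounds
        for name in ("wave1_screener_total", "wave2_screener_total"):
            tot = getattr(self, name)
            if tot.size and (tot.min() < slo or tot.max() > shi):
                raise ValueError(f"{name} outside [{slo}, {shi}]")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_items(self) -> int:
        return self.wave1_items.shape[1]

    @property
    def item_labels(self) -> list[str]:
        return list(self.wave1_items.columns)

    def take(self, indices: np.ndarray) -> "SymptomPanel":
        """Row-subset the panel (positional indices), preserving order.

        Repeated indices (bootstrap resamples) get fresh sequential ids,
        since the result is a pseudo-sample rather than a cohort subset.
        """
        idx = np.asarray(indices)
        ids = self.ids[idx]
        if len(np.unique(ids)) != len(ids):
            ids = np.arange(1, len(idx) + 1)
        return SymptomPanel(
            ids=ids,
            age=self.age[idx],
            gender=self.gender[idx],
            wave1_items=self.wave1_items.iloc[idx].reset_index(drop=True),
            wave2_items=self.wave2_items.iloc[idx].reset_index(drop=True),
            wave1_screener_total=self.wave1_screener_total[idx],
            wave2_screener_total=self.wave2_screener_total[idx],
            item_bounds=self.item_bounds,
            screener_bounds=self.screener_bounds,
            meta=dict(self.meta),
        )
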