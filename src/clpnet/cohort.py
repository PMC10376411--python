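"""Cohort assembly and descriptive statistics for two-wave panels.

Reads per-wave CSV tables, inner-joins them on a participant key,
screens on a baseline depression-screener cutoff, and produces the
descriptive / paired-test table (means, SDs, skewness, kurtosis, paired
t, mean difference with 95% CI, Cohen's dz with 95% CI) plus Cronbach's
alpha reliability.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panel import SymptomPanel

__all__ = [
    "SchemaError",
    "PanelValidationError",
    "read_panel",
    "match_waves",
    "screen",
    "descriptives_table",
    "cronbach_alpha",
]


class SchemaError(ValueError):
    """A required column is missing or the file is unreadable/empty."""


class PanelValidationError(ValueError):
    """Item or screener scores fall outside their declared bounds."""


def _item_columns(df: pd.DataFrame, prefix: str) -> list[str]:
    pat = re.compile(rf"^{re.escape(prefix)}(\d+)$")
    cols = [(int(m.group(1)), c) for c in df.columns if (m := pat.match(c))]
    return [c for _, c in sorted(cols)]


def read_panel(
    wave1_path: str | Path,
    wave2_path: str | Path,
    key: str = "id",
    item_prefix: str = "iat",
    screener_prefix: str = "phq",
    item_bounds: tuple[int, int] = (1, 5),
    screener_item_bounds: tuple[int, int] = (0, 3),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the two raw wave tables.

    Each file must carry the key column, ``age``, ``gender``, and
    consecutively numbered item columns (``iat1..iatP``) plus screener
    item columns (``phq1..phqK``). Rows with out-of-range scores raise
    :class:`PanelValidationError` naming every offending row and column.
    """
    tables = []
    for path in (wave1_path, wave2_path):
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise SchemaError(f"{path}: file is empty") from exc
        if df.empty:
            raise SchemaError(f"{path}: no data rows")
        for col in (key, "age", "gender"):
            if col not in df.columns:
                raise SchemaError(f"{path}: missing required column '{col}'")
        items = _item_columns(df, item_prefix)
        screeners = _item_columns(df, screener_prefix)
        if not items:
            raise SchemaError(f"{path}: no '{item_prefix}*' item columns found")
        if not screeners:
            raise SchemaError(f"{path}: no '{screener_prefix}*' screener columns found")
        offenders = []
        for cols, (lo, hi) in ((items, item_bounds), (screeners, screener_item_bounds)):
            block = df[cols]
            bad = (block < lo) | (block > hi) | block.isna()
            for col in cols:
                for row in df.index[bad[col]]:
                    offenders.append(f"row {row}, column {col} = {df.at[row, col]!r}")
        if offenders:
            raise PanelValidationError(
                f"{path}: {len(offenders)} out-of-range scores: " + "; ".join(offenders[:20])
            )
        tables.append(df)
    return tables[0], tables[1]


def match_waves(
    w1: pd.DataFrame,
    w2: pd.DataFrame,
    key: str = "id",
    item_prefix: str = "iat",
    screener_prefix: str = "phq",
    item_bounds: tuple[int, int] = (1, 5),
    screener_item_bounds: tuple[int, int] = (0, 3),
) -> SymptomPanel:
    """Inner-join the waves on the participant key.

    Participants present in only one wave are dropped; the counts are
    recorded in ``panel.meta['dropped_wave1'/'dropped_wave2']``. Output
    rows are sorted by key. Duplicate keys within a wave make the match
    ambiguous and raise.
    """
    for name, df in (("wave1", w1), ("wave2", w2)):
        if key not in df.columns:
            raise SchemaError(f"{name}: key column '{key}' missing")
        if df[key].duplicated().any():
            dups = df.loc[df[key].duplicated(), key].tolist()[:5]
            raise ValueError(f"{name}: duplicate keys {dups} make matching ambiguous")
    shared = np.intersect1d(w1[key].to_numpy(), w2[key].to_numpy())
    meta = {
        "dropped_wave1": int(len(w1) - len(shared)),
        "dropped_wave2": int(len(w2) - len(shared)),
    }
    if len(shared) == 0:
        meta["warning"] = "no overlapping keys between waves"
    a = w1.set_index(key).loc[shared]
    b = w2.set_index(key).loc[shared]
    items = _item_columns(w1, item_prefix)
    screeners = _item_columns(w1, screener_prefix)
    k = len(screeners)
    max_total = screener_item_bounds[1] * k
    return SymptomPanel(
        ids=shared,
        age=a["age"].to_numpy(),
        gender=a["gender"].to_numpy(),
        wave1_items=a[items].reset_index(drop=True).astype(int),
        wave2_items=b[items].reset_index(drop=True).astype(int),
        wave1_screener_total=a[screeners].sum(axis=1).to_numpy(),
        wave2_screener_total=b[screeners].sum(axis=1).to_numpy(),
        item_bounds=item_bounds,
        screener_bounds=(screener_item_bounds[0] * k, max_total),
        meta=meta,
    )


def screen(panel: SymptomPanel, cutoff: int = 8) -> tuple[SymptomPanel, float, float]:
    """Select the baseline screener-positive subgroup.

    Returns the subset with ``wave1_screener_total >= cutoff`` together
    with the per-wave prevalence of screener positivity, as percentages
    of the full panel rounded to 2 decimals.
    """
    lo, hi = panel.screener_bounds
    if not lo <= cutoff <= hi:
        raise ValueError(f"cutoff {cutoff} outside screener range [{lo}, {hi}]")
    keep = np.flatnonzero(panel.wave1_screener_total >= cutoff)
    prev1 = round(100.0 * int((panel.wave1_screener_total >= cutoff).sum()) / panel.n, 2)
    prev2 = round(100.0 * int((panel.wave2_screener_total >= cutoff).sum()) / panel.n, 2)
    subset = panel.take(keep)
    subset.meta["screen_cutoff"] = cutoff
    return subset, prev1, prev2


def descriptives_table(panel: SymptomPanel, confidence: float = 0.95) -> pd.DataFrame:
    """Per-item descriptives and wave-2-minus-wave-1 paired tests.

    For each item: sample mean and SD (n−1 denominator) per wave,
    bias-corrected skewness and excess kurtosis, paired t on the
    within-person differences (df = n − 1), the mean difference with a
    t-based CI, and Cohen's dz = t/sqrt(n) with a normal-approximation
    CI using SE = sqrt(1/n + d^2/(2n)). Items whose differences have
    zero variance get ``t_defined = False`` and NaN test columns.
    """
    n = panel.n
    if n < 3:
        raise ValueError("need at least 3 participants")
    alpha = 1 - confidence
    tcrit = stats.t.ppf(1 - alpha / 2, n - 1)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    rows = []
    for label in panel.item_labels:
        x1 = panel.wave1_items[label].to_numpy(dtype=float)
        x2 = panel.wave2_items[label].to_numpy(dtype=float)
        diff = x2 - x1
        sd_diff = diff.std(ddof=1)
        row = {
            "item": label,
            "mean_w1": x1.mean(),
            "sd_w1": x1.std(ddof=1),
            "skew_w1": stats.skew(x1, bias=False),
            "kurtosis_w1": stats.kurtosis(x1, bias=False),
            "mean_w2": x2.mean(),
            "sd_w2": x2.std(ddof=1),
            "skew_w2": stats.skew(x2, bias=False),
            "kurtosis_w2": stats.kurtosis(x2, bias=False),
            "mean_diff": diff.mean(),
            "df": n - 1,
            "t_defined": sd_diff > 0,
        }
        if sd_diff > 0:
            t, p = stats.ttest_rel(x2, x1)
            se = sd_diff / np.sqrt(n)
            d = t / np.sqrt(n)  # == diff.mean() / sd_diff
            d_se = np.sqrt(1 / n + d**2 / (2 * n))
            row.update(
                t=t,
                p=p,
                diff_ci_lower=diff.mean() - tcrit * se,
                diff_ci_upper=diff.mean() + tcrit * se,
                cohens_d=d,
                d_ci_lower=d - zcrit * d_se,
                d_ci_upper=d + zcrit * d_se,
            )
        else:
            row.update(
                t=np.nan, p=np.nan, diff_ci_lower=np.nan, diff_ci_upper=np.nan,
                cohens_d=np.nan, d_ci_lower=np.nan, d_ci_upper=np.nan,
            )
        rows.append(row)
    cols = [
        "item", "mean_w1", "sd_w1", "skew_w1", "kurtosis_w1",
        "mean_w2", "sd_w2", "skew_w2", "kurtosis_w2",
        "t", "df", "p", "mean_diff", "diff_ci_lower", "diff_ci_upper",
        "cohens_d", "d_ci_lower", "d_ci_upper", "t_defined",
    ]
    return pd.DataFrame(rows)[cols]


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha internal-consistency coefficient.

    alpha = k/(k−1) * (1 − sum of item variances / variance of the
    total score), all variances with the n−1 denominator.
    """
    X = np.asarray(items, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need an n x k matrix with k >= 2")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    k = X.shape[1]
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance; alpha undefined")
    return k / (k - 1) * (1 - X.var(axis=0, ddof=1).sum() / total_var)
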