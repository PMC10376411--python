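"""Synthetic two-wave Likert panel generator with known cross-lagged structure.

The generating model is a one-step vector autoregression on latent,
continuous symptom scores:

    X2 = X1 (B + diag(a)) + age_z * g_age + gender * g_gender + eps

where ``B`` is a sparse cross-lagged coefficient matrix (zero diagonal),
``a`` are autoregressive coefficients, and ``eps`` is isotropic Gaussian
noise. Wave-1 latents are multivariate normal with an exchangeable
correlation. Both waves are discretized to 1..L Likert categories by
fixed per-item thresholds; a correlated depression-screener total (with
its own ordinal items) defines a cutoff subgroup. The planted matrix
``B`` and the thresholds are returned as :class:`GroundTruth` so that
network-recovery can be tested without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panel import SymptomPanel

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "make_true_clpn",
    "discretize_likert",
    "generate_panel",
    "generate_tables",
    "write_panel_csvs",
]

# base magnitude range of nonzero cross-lagged weights (standardized latent scale)
_W_LO, _W_HI = 0.05, 0.15

# screener item thresholds: cumulative probabilities of the 0..3 categories,
# shifted per item by a severity offset. Calibrated so that, at the default
# screener_loading, roughly 14% of participants exceed the cutoff of 8 —
# the subgroup prevalence the generator is meant to emulate.
_SCREENER_CUMPROBS = (0.78, 0.935, 0.98)
_SCREENER_OFFSET_SPAN = 0.6


@dataclass
class GroundTruth:
    """The generator's planted parameters, for parameter-recovery tests."""

    true_cross_lagged: np.ndarray
    true_autoregressive: np.ndarray
    discretization_thresholds: dict
    seed: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_cross_lagged": self.true_cross_lagged.tolist(),
            "true_autoregressive": self.true_autoregressive.tolist(),
            "discretization_thresholds": {
                k: np.asarray(v).tolist() for k, v in self.discretization_thresholds.items()
            },
            "seed": int(self.seed),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class GeneratorConfig:
    """Parameters of the two-wave generating model.

    ``true_cross_lagged`` defaults to :func:`make_true_clpn` with one
    out-influence hub and one in-influence hub. ``covariate_effects``
    is one coefficient per covariate (age, gender), broadcast across
    items; age is z-scored before its effect is applied, gender enters
    as a 0/1 code. ``screener_loading`` is the correlation between the
    screener's latent factor and the (standardized) mean symptom latent.
    """

    n_participants: int
    n_items: int = 20
    n_screener_items: int = 9
    true_cross_lagged: np.ndarray | None = None
    autoregressive_range: tuple[float, float] = (0.15, 0.35)
    latent_wave1_correlation: float = 0.3
    noise_sd: float = 0.8
    likert_levels: int = 5
    likert_cumprobs: tuple | None = None
    screener_levels: int = 4
    screener_loading: float = 0.6
    covariate_effects: tuple[float, float] = (0.1, -0.1)
    n_extra_wave1: int = 0
    n_extra_wave2: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.likert_levels < 2:
            raise ValueError("likert_levels must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.latent_wave1_correlation < 1:
            raise ValueError("latent_wave1_correlation must lie in [0, 1)")
        if self.true_cross_lagged is not None:
            B = np.asarray(self.true_cross_lagged, dtype=float)
            if B.shape != (self.n_items, self.n_items):
                raise ValueError(
                    f"true_cross_lagged must be {self.n_items}x{self.n_items}, got {B.shape}"
                )
            self.true_cross_lagged = B


def make_true_clpn(
    p: int,
    n_hub_out: int = 1,
    n_hub_in: int = 1,
    density: float = 0.15,
    hub_scale: float = 2.0,
    seed: int = 0,
    weight_range: tuple[float, float] = (_W_LO, _W_HI),
) -> np.ndarray:
    """Build a sparse positive cross-lagged matrix with planted hubs.

    Each row receives ``round(density * (p - 1))`` nonzero off-diagonal
    entries at uniformly drawn magnitudes. The first ``n_hub_out`` rows
    and the last ``n_hub_in`` columns are hubs: their entries are pinned
    at ``hub_scale * max(weight_range)``, and hub-in columns are filled
    to twice the per-row count, so hub rows dominate every other row's
    absolute sum by construction. Diagonal is zero (autoregressive terms
    are added separately by the generator).
    """
    if p < 2:
        raise ValueError("p must be at least 2")
    if not 0 < density <= 1:
        raise ValueError("density must lie in (0, 1]")
    if density * p * (p - 1) < n_hub_out + n_hub_in:
        raise ValueError("density too low to host the requested hubs")
    if n_hub_out + n_hub_in > p:
        raise ValueError("more hubs than nodes")

    rng = np.random.default_rng(seed)
    w_lo, w_hi = weight_range
    k = max(1, round(density * (p - 1)))
    B = np.zeros((p, p))
    for i in range(p):
        others = np.array([j for j in range(p) if j != i])
        cols = rng.choice(others, size=min(k, p - 1), replace=False)
        B[i, cols] = rng.uniform(w_lo, w_hi, size=len(cols))

    hub_w = hub_scale * w_hi
    for i in range(n_hub_out):  # hub-out rows: first indices
        B[i, B[i] != 0] = hub_w
    for j in range(p - n_hub_in, p):  # hub-in columns: last indices
        have = np.flatnonzero(B[:, j])
        want = min(2 * k, p - 1)
        if len(have) < want:
            candidates = np.array([i for i in range(p) if i != j and B[i, j] == 0])
            extra = rng.choice(candidates, size=want - len(have), replace=False)
            B[extra, j] = hub_w
        B[B[:, j] != 0, j] = hub_w
    return B


def discretize_likert(latent: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Map continuous scores to ordinal categories by fixed cut points.

    ``thresholds`` has one strictly increasing row of L-1 cut points per
    item (column of ``latent``). The category is 1 plus the number of
    thresholds strictly below the latent value, so outputs lie in
    ``[1, L]``.
    """
    latent = np.atleast_2d(np.asarray(latent, dtype=float))
    thresholds = np.atleast_2d(np.asarray(thresholds, dtype=float))
    if thresholds.shape[0] != latent.shape[1]:
        raise ValueError("one threshold vector per item required")
    if thresholds.shape[1] and np.any(np.diff(thresholds, axis=1) <= 0):
        raise ValueError("thresholds must be strictly increasing per item")
    out = np.empty(latent.shape, dtype=int)
    for j in range(latent.shape[1]):
        # count of thresholds strictly below the value
        out[:, j] = 1 + np.searchsorted(thresholds[j], latent[:, j], side="left")
    return out


def _likert_thresholds(cfg: GeneratorConfig, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Per-item cut points placed at fixed quantiles of the item's marginal."""
    L = cfg.likert_levels
    if cfg.likert_cumprobs is None:
        cum = np.arange(1, L) / L  # equal-probability categories
    else:
        cum = np.asarray(cfg.likert_cumprobs, dtype=float)
        if len(cum) != L - 1 or np.any(np.diff(cum) <= 0) or cum[0] <= 0 or cum[-1] >= 1:
            raise ValueError("likert_cumprobs must be L-1 increasing values in (0, 1)")
    z = stats.norm.ppf(cum)
    return mu[:, None] + sd[:, None] * z[None, :]


def _screener_thresholds(cfg: GeneratorConfig) -> np.ndarray:
    """Severity-staggered cut points for the screener items (0..levels-1)."""
    if cfg.screener_levels == 4:
        base = stats.norm.ppf(_SCREENER_CUMPROBS)
    else:
        base = stats.norm.ppf(np.arange(1, cfg.screener_levels) / cfg.screener_levels)
    offsets = np.linspace(-_SCREENER_OFFSET_SPAN, _SCREENER_OFFSET_SPAN, cfg.n_screener_items)
    return offsets[:, None] + base[None, :]


def _screener_scores(
    symptom_latent: np.ndarray,
    lam: float,
    thresholds: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Ordinal screener item scores (n x items, values 0..levels-1)."""
    m = symptom_latent.mean(axis=1)
    m_z = (m - m.mean()) / m.std()
    f = lam * m_z + np.sqrt(max(0.0, 1 - lam**2)) * rng.standard_normal(len(m))
    # item score = number of cut points below the factor value
    return (f[:, None, None] > thresholds[None, :, :]).sum(axis=2)


def _linkage_attenuation(
    scr_thresholds: np.ndarray, item_thresholds_std: np.ndarray, R_latent: np.ndarray
) -> float:
    """Attenuation of the observed screener linkage under discretization.

    Discretizing both sides attenuates the correlation between the
    screener total and the mean symptom score below the latent factor
    correlation. Both attenuation factors have (near-)closed forms:

    * total vs factor: the total is a deterministic step function of the
      factor, so its moments are sums of normal survival functions and
      the covariance is a sum of normal densities (Stein's lemma);
    * mean item score vs mean latent: Stein linearization with slope
      ``s_j = sum_c phi(t_jc)`` per item, exact item variances, and the
      latent correlation matrix of the wave.

    Dividing the requested loading by the product undoes the attenuation.
    """
    S, phi = stats.norm.sf, stats.norm.pdf
    tau = np.asarray(scr_thresholds, dtype=float).ravel()
    var_tot = S(np.maximum.outer(tau, tau)).sum() - S(tau).sum() ** 2
    r_tf = phi(tau).sum() / np.sqrt(var_tot)

    thr = np.atleast_2d(item_thresholds_std)
    p = thr.shape[0]
    s = phi(thr).sum(axis=1)
    var_d = np.array([S(np.maximum.outer(t, t)).sum() - S(t).sum() ** 2 for t in thr])
    var_m = R_latent.sum() / p**2
    cov_md = (s[None, :] * R_latent).sum() / p**2
    var_md = ((np.outer(s, s) * R_latent).sum() - (s**2).sum() + var_d.sum()) / p**2
    r_mm = cov_md / np.sqrt(var_m * var_md)
    return r_tf * r_mm


def _wave2_latent(
    X1: np.ndarray,
    T: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    g_age, g_gender = cfg.covariate_effects
    age_z = (age - age.mean()) / age.std()
    X2 = X1 @ T
    X2 += g_age * age_z[:, None] + g_gender * gender[:, None]
    X2 += cfg.noise_sd * rng.standard_normal(X1.shape)
    return X2


def generate_tables(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate raw per-wave tables (one row per participant per wave).

    Matched participants appear in both tables with the same integer id;
    ``n_extra_wave1`` / ``n_extra_wave2`` unmatched participants are
    appended to one table only (they follow the same generating model).
    Columns: id, age, gender, item1..itemP, scr1..scrK — written out as
    iat*/phq* headers by :func:`write_panel_csvs`.
    """
    cfg = config
    p = cfg.n_items
    rng = np.random.default_rng(cfg.seed)

    B = cfg.true_cross_lagged
    if B is None:
        B = make_true_clpn(p, seed=cfg.seed)
    a = rng.uniform(*cfg.autoregressive_range, size=p)
    T = B + np.diag(a)
    radius = np.max(np.abs(np.linalg.eigvals(T)))
    if radius >= 1:
        raise ValueError(f"combined lag matrix is non-stationary (spectral radius {radius:.3f})")

    rho = cfg.latent_wave1_correlation
    Sigma = np.full((p, p), rho)
    np.fill_diagonal(Sigma, 1.0)
    L_chol = np.linalg.cholesky(Sigma)

    n_m, n_e1, n_e2 = cfg.n_participants, cfg.n_extra_wave1, cfg.n_extra_wave2
    n_all = n_m + n_e1 + n_e2
    age = rng.uniform(10, 18, size=n_all)
    gender = rng.integers(0, 2, size=n_all)
    X1 = rng.standard_normal((n_all, p)) @ L_chol.T
    X2 = _wave2_latent(X1, T, age, gender, cfg, rng)

    # theoretical marginal moments of the latents, for fixed thresholds
    g_age, g_gender = cfg.covariate_effects
    var2 = np.diag(T.T @ Sigma @ T) + g_age**2 + g_gender**2 * 0.25 + cfg.noise_sd**2
    mu2 = np.full(p, g_gender * 0.5)
    thr1 = _likert_thresholds(cfg, np.zeros(p), np.ones(p))
    thr2 = _likert_thresholds(cfg, mu2, np.sqrt(var2))
    items1 = discretize_likert(X1, thr1)
    items2 = discretize_likert(X2, thr2)

    # inflate the latent loading so the *observed* total-vs-mean-score
    # correlation lands on screener_loading despite discretization
    scr_thr = _screener_thresholds(cfg)
    cov2 = T.T @ Sigma @ T + (g_age**2 + g_gender**2 * 0.25) + cfg.noise_sd**2 * np.eye(p)
    R2 = cov2 / np.sqrt(np.outer(var2, var2))
    thr_std = _likert_thresholds(cfg, np.zeros(p), np.ones(p))
    lam1 = min(cfg.screener_loading / _linkage_attenuation(scr_thr, thr_std, Sigma), 0.999)
    lam2 = min(cfg.screener_loading / _linkage_attenuation(scr_thr, thr_std, R2), 0.999)
    scr1 = _screener_scores(X1, lam1, scr_thr, rng)
    scr2 = _screener_scores(X2, lam2, scr_thr, rng)

    ids = np.arange(1, n_all + 1)
    w1_rows = np.concatenate([np.arange(n_m), np.arange(n_m, n_m + n_e1)])
    w2_rows = np.concatenate([np.arange(n_m), np.arange(n_m + n_e1, n_all)])

    def _table(rows: np.ndarray, items: np.ndarray, scr: np.ndarray) -> pd.DataFrame:
        d = {"id": ids[rows], "age": np.round(age[rows], 2), "gender": gender[rows]}
        for j in range(p):
            d[f"item{j + 1}"] = items[rows, j]
        for j in range(scr.shape[1]):
            d[f"scr{j + 1}"] = scr[rows, j]
        return pd.DataFrame(d)

    truth = GroundTruth(
        true_cross_lagged=B,
        true_autoregressive=a,
        discretization_thresholds={"wave1": thr1, "wave2": thr2, "screener": scr_thr},
        seed=cfg.seed,
    )
    return _table(w1_rows, items1, scr1), _table(w2_rows, items2, scr2), truth


def generate_panel(config: GeneratorConfig) -> tuple[SymptomPanel, GroundTruth]:
    """Generate a matched panel (extras dropped) plus its ground truth."""
    w1, w2, truth = generate_tables(config)
    matched = np.intersect1d(w1["id"], w2["id"])
    w1 = w1.set_index("id").loc[matched]
    w2 = w2.set_index("id").loc[matched]
    p, k = config.n_items, config.n_screener_items
    item_cols = [f"item{j + 1}" for j in range(p)]
    scr_cols = [f"scr{j + 1}" for j in range(k)]
    max_total = (config.screener_levels - 1) * k
    panel = SymptomPanel(
        ids=matched,
        age=w1["age"].to_numpy(),
        gender=w1["gender"].to_numpy(),
        wave1_items=w1[item_cols].reset_index(drop=True),
        wave2_items=w2[item_cols].reset_index(drop=True),
        wave1_screener_total=w1[scr_cols].sum(axis=1).to_numpy(),
        wave2_screener_total=w2[scr_cols].sum(axis=1).to_numpy(),
        item_bounds=(1, config.likert_levels),
        screener_bounds=(0, max_total),
        meta={"seed": config.seed},
    )
    if config.n_participants < p + 5:
        panel.meta["unstable_n_warning"] = (
            f"n={config.n_participants} < p+5={p + 5}: estimation will be unstable"
        )
    return panel, truth


def write_panel_csvs(
    config: GeneratorConfig, out_dir: str | Path, item_prefix: str = "iat", screener_prefix: str = "phq"
) -> tuple[Path, Path, Path]:
    """Write wave1.csv / wave2.csv / ground_truth.json for a config.

    Headers follow the questionnaire convention: id, age, gender,
    iat1..iatP, phq1..phqK.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    w1, w2, truth = generate_tables(config)
    rename = {f"item{j + 1}": f"{item_prefix}{j + 1}" for j in range(config.n_items)}
    rename |= {f"scr{j + 1}": f"{screener_prefix}{j + 1}" for j in range(config.n_screener_items)}
    paths = (out / "wave1.csv", out / "wave2.csv", out / "ground_truth.json")
    w1.rename(columns=rename).to_csv(paths[0], index=False)
    w2.rename(columns=rename).to_csv(paths[1], index=False)
    truth.to_json(paths[2])
    return paths
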