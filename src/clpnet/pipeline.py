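"""End-to-end orchestration: data -> screen -> describe -> estimate ->
compare -> resample -> sensitivity, from a single config.

One master seed fans out to named child streams (generation, estimation
CV folds, NCT permutations, stability bootstrap, edge bootstrap), so any
stage can be re-run in isolation and reproduce its numbers exactly. The
summary JSON echoes the full config and seed and is sufficient to re-run
the pipeline identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import centrality as cent
from . import cohort, comparison, cross_sectional, estimation, resampling, synthetic
from .panel import SymptomPanel

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

log = logging.getLogger("clpnet")

ALL_STAGES = ("simulate", "describe", "estimate", "compare", "stability", "sensitivity")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Exactly one of ``input_paths`` (dict with wave1/wave2 CSV paths) or
    ``generator`` (keyword arguments of
    :class:`~clpnet.synthetic.GeneratorConfig`, minus the seed) must be
    given.
    """

    out_dir: str = "clpn_out"
    seed: int = 0
    input_paths: dict | None = None
    generator: dict | None = None
    key: str = "id"
    item_prefix: str = "iat"
    screener_prefix: str = "phq"
    screener_cutoff: int = 8
    estimation: dict = field(default_factory=dict)  # n_folds, include_covariates, fixed_lambda
    nct: dict = field(default_factory=dict)  # n_permutations, estimator, gamma, n_lambda
    resampling: dict = field(default_factory=dict)  # drop_proportions, n_boot_stability, n_boot_edges
    sensitivity: dict = field(default_factory=dict)  # enabled
    plots: bool = False

    def __post_init__(self) -> None:
        if (self.input_paths is None) == (self.generator is None):
            raise ValueError("exactly one of input_paths / generator must be set")
        if not 0 <= self.screener_cutoff <= 27:
            raise ValueError(f"screener_cutoff {self.screener_cutoff} outside [0, 27]")
        for section, keys in (
            ("estimation", {"n_folds", "include_covariates", "fixed_lambda", "n_lambda"}),
            ("nct", {"n_permutations", "estimator", "gamma", "n_lambda", "lambda_min_ratio"}),
            ("resampling", {"drop_proportions", "n_boot_stability", "n_boot_edges",
                            "cs_threshold", "cs_probability"}),
            ("sensitivity", {"enabled", "gamma", "n_lambda"}),
        ):
            unknown = set(getattr(self, section)) - keys
            if unknown:
                raise ValueError(f"unknown {section} option(s): {sorted(unknown)}")
        for name in ("n_folds", "n_permutations", "n_boot_stability", "n_boot_edges", "n_lambda"):
            for section in (self.estimation, self.nct, self.resampling):
                v = section.get(name)
                if v is not None and v <= 0:
                    raise ValueError(f"{name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage_seeds(master: int) -> dict:
    names = ("generation", "estimation", "nct", "stability", "edges")
    children = np.random.SeedSequence(master).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % 2**31) for n, c in zip(names, children)}


def _clpn_estimator(config: PipelineConfig, seed: int):
    opts = config.estimation

    def estimate(panel: SymptomPanel) -> estimation.CLPNetwork:
        return estimation.estimate_clpn(
            panel,
            include_covariates=opts.get("include_covariates", True),
            n_folds=opts.get("n_folds", 10),
            seed=seed,
            fixed_lambda=opts.get("fixed_lambda"),
        )

    return estimate


def _xsec_estimator(opts: dict):
    kind = opts.get("estimator", "glasso")
    if kind == "glasso":
        return cross_sectional.glasso_estimator(
            gamma=opts.get("gamma", 0.5),
            n_lambda=opts.get("n_lambda", 100),
            lambda_min_ratio=opts.get("lambda_min_ratio", 0.01),
        )
    if kind == "pcor":
        return cross_sectional.partial_correlation_estimator()
    raise ValueError(f"unknown cross-sectional estimator '{kind}'")


def _centrality_fn(net: estimation.CLPNetwork) -> dict:
    return {
        "oei": cent.out_expected_influence(net),
        "iei": cent.in_expected_influence(net),
    }


def run_pipeline(config: PipelineConfig, stages: tuple = ALL_STAGES) -> dict:
    """Run the requested stages; returns a summary dict (also written as JSON).

    Earlier stages a later one depends on (data loading, matching,
    screening) are always computed; only the requested stages write
    their artifacts.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    summary: dict = {"config": config.to_dict(), "stage_seeds": seeds, "artifacts": {}}

    def record(name: str, path: Path) -> None:
        summary["artifacts"][name] = str(path)
        log.info("wrote %s", path)

    # --- data ------------------------------------------------------------
    if config.generator is not None:
        gen_cfg = synthetic.GeneratorConfig(seed=seeds["generation"], **config.generator)
        data_dir = out / "data"
        w1_path, w2_path, truth_path = synthetic.write_panel_csvs(
            gen_cfg, data_dir, item_prefix=config.item_prefix,
            screener_prefix=config.screener_prefix,
        )
        if "simulate" in stages:
            record("wave1", w1_path)
            record("wave2", w2_path)
            record("ground_truth", truth_path)
        likert_hi = gen_cfg.likert_levels
        scr_hi = gen_cfg.screener_levels - 1
    else:
        w1_path = config.input_paths["wave1"]
        w2_path = config.input_paths["wave2"]
        likert_hi, scr_hi = 5, 3

    w1, w2 = cohort.read_panel(
        w1_path, w2_path, key=config.key, item_prefix=config.item_prefix,
        screener_prefix=config.screener_prefix, item_bounds=(1, likert_hi),
        screener_item_bounds=(0, scr_hi),
    )
    panel = cohort.match_waves(
        w1, w2, key=config.key, item_prefix=config.item_prefix,
        screener_prefix=config.screener_prefix, item_bounds=(1, likert_hi),
        screener_item_bounds=(0, scr_hi),
    )
    log.info("matched panel: n=%d (dropped %d / %d)", panel.n,
             panel.meta["dropped_wave1"], panel.meta["dropped_wave2"])

    screened, prev1, prev2 = cohort.screen(panel, cutoff=config.screener_cutoff)
    log.info("screened subgroup: n=%d (prevalence %.2f%% / %.2f%%)", screened.n, prev1, prev2)
    summary["n_matched"] = panel.n
    summary["n_screened"] = screened.n
    summary["prevalence_wave1"] = prev1
    summary["prevalence_wave2"] = prev2

    # --- describe --------------------------------------------------------
    if "describe" in stages:
        screening = {
            "cutoff": config.screener_cutoff,
            "n_matched": panel.n,
            "n_screened": screened.n,
            "dropped_wave1": panel.meta["dropped_wave1"],
            "dropped_wave2": panel.meta["dropped_wave2"],
            "prevalence_wave1": prev1,
            "prevalence_wave2": prev2,
            "cronbach_alpha_wave1": cohort.cronbach_alpha(screened.wave1_items),
            "cronbach_alpha_wave2": cohort.cronbach_alpha(screened.wave2_items),
        }
        path = out / "screening.json"
        path.write_text(json.dumps(screening, indent=1))
        record("screening", path)
        desc = cohort.descriptives_table(screened)
        path = out / "descriptives.csv"
        desc.to_csv(path, index=False, float_format="%.6g")
        record("descriptives", path)

    # --- estimate --------------------------------------------------------
    net = None
    if {"estimate", "stability"} & set(stages):
        net = _clpn_estimator(config, seeds["estimation"])(screened)
    if "estimate" in stages:
        mat_path, edge_path = estimation.write_network(net, out)
        record("clpn_matrix", mat_path)
        record("clpn_edges", edge_path)
        tab = cent.centrality_table(net)
        path = out / "centrality.csv"
        tab.to_frame().to_csv(path, index=False, float_format="%.6g")
        record("centrality", path)
        path = out / "centrality_top.json"
        path.write_text(json.dumps(cent.rank_report(tab, k=min(5, net.p)), indent=1))
        record("centrality_top", path)
        summary["clpn_density"] = net.density()
        summary["clpn_n_nonzero"] = int(np.count_nonzero(net.weights))

    # --- compare (NCT on per-wave cross-sectional networks) --------------
    if "compare" in stages:
        xsec = _xsec_estimator(config.nct)
        res = comparison.nct_paired(
            screened.wave1_items.to_numpy(float),
            screened.wave2_items.to_numpy(float),
            xsec,
            n_permutations=config.nct.get("n_permutations", 1000),
            seed=seeds["nct"],
        )
        path = out / "nct.json"
        res.to_json(path)
        record("nct", path)
        path = out / "nct_edge_p.csv"
        pd.DataFrame(res.edge_p_values, index=screened.item_labels,
                     columns=screened.item_labels).to_csv(path)
        record("nct_edge_p", path)
        summary["nct"] = {
            "global_strength_wave1": res.global_strength_a,
            "global_strength_wave2": res.global_strength_b,
            "s_diff": res.s_diff, "p_global": res.p_global,
            "m_statistic": res.m_statistic, "p_structure": res.p_structure,
        }

    # --- stability / accuracy --------------------------------------------
    if "stability" in stages:
        opts = config.resampling
        estimator = _clpn_estimator(config, seeds["estimation"])
        stab = resampling.case_dropping_bootstrap(
            screened, estimator, _centrality_fn,
            drop_proportions=tuple(opts.get("drop_proportions", resampling.DEFAULT_DROP_GRID)),
            n_boot=opts.get("n_boot_stability", 1000),
            seed=seeds["stability"],
        )
        path = out / "stability.json"
        stab.to_json(path, threshold=opts.get("cs_threshold", 0.7),
                     probability=opts.get("cs_probability", 0.95))
        record("stability", path)
        path = out / "stability.csv"
        stab.to_frame().to_csv(path, index=False, float_format="%.6g")
        record("stability_long", path)
        summary["cs_coefficient"] = resampling.cs_coefficient(
            stab, threshold=opts.get("cs_threshold", 0.7),
            probability=opts.get("cs_probability", 0.95))

        boot = resampling.edge_ci_bootstrap(
            screened, estimator,
            n_boot=opts.get("n_boot_edges", 1000),
            seed=seeds["edges"],
        )
        labels = screened.item_labels
        rows = [
            {"source": labels[i], "target": labels[j],
             "weight": boot.sample_weights[i, j],
             "boot_mean": boot.bootstrap_mean[i, j],
             "ci_lower": boot.ci_lower[i, j], "ci_upper": boot.ci_upper[i, j]}
            for i in range(len(labels)) for j in range(len(labels))
        ]
        path = out / "edge_ci.csv"
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
        record("edge_ci", path)

        sig = resampling.difference_tests(boot)
        path = out / "edge_difference_significant.csv"
        edge_names = [f"{labels[i]}->{labels[j]}"
                      for i in range(len(labels)) for j in range(len(labels))]
        pd.DataFrame(sig, index=edge_names, columns=edge_names).to_csv(path)
        record("edge_differences", path)

        if config.plots:
            _write_plots(out, net, stab, labels)

    # --- sensitivity ------------------------------------------------------
    if "sensitivity" in stages and config.sensitivity.get("enabled", True):
        sens = _sensitivity(config, w1, w2, panel, screened)
        if sens is not None:
            path = out / "sensitivity.json"
            path.write_text(json.dumps(sens, indent=1))
            record("sensitivity", path)
            summary["sensitivity"] = sens

    path = out / "summary.json"
    path.write_text(json.dumps(summary, indent=1, default=str))
    log.info("wrote %s", path)
    return summary


def _sensitivity(config: PipelineConfig, w1, w2, panel, screened) -> dict | None:
    """Correlate the analysis sample's per-wave networks with networks
    built from the rows each wave loses in matching (or, absent any
    unmatched rows, from the full matched panel)."""
    opts = config.sensitivity
    xsec = cross_sectional.glasso_estimator(
        gamma=opts.get("gamma", 0.5), n_lambda=opts.get("n_lambda", 100))
    pcor = cross_sectional.partial_correlation_estimator()
    items = cohort._item_columns(w1, config.item_prefix)
    out: dict = {}
    for wave, raw in (("wave1", w1), ("wave2", w2)):
        matched_items = panel.wave1_items if wave == "wave1" else panel.wave2_items
        unmatched = raw[~raw[config.key].isin(panel.ids)]
        if len(unmatched) >= 3 * len(items):
            used, other = matched_items, unmatched[items].to_numpy(float)
            basis = "matched panel vs unmatched rows"
        else:
            used = screened.wave1_items if wave == "wave1" else screened.wave2_items
            other = matched_items.to_numpy(float)
            basis = "screened subgroup vs full matched panel"
        used_arr = used.to_numpy(float)
        try:
            r = cross_sectional.network_correlation(
                xsec(used_arr), xsec(other), directed=False)
            est_name = "ebic_glasso"
        except ValueError:
            # regularized networks can be empty when partial correlations
            # are uniformly weak; fall back to the saturated estimator
            r = cross_sectional.network_correlation(
                pcor(used_arr), pcor(other), directed=False)
            est_name = "partial_correlations"
        out[f"{wave}_correlation"] = r
        out[f"{wave}_comparison_basis"] = basis
        out[f"{wave}_estimator"] = est_name
    return out


def _write_plots(out: Path, net, stab, labels: list) -> None:
    """Optional static figures: weight heatmap, centrality bars, stability curves."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 6))
    vmax = np.abs(net.weights).max() or 1.0
    im = ax.imshow(net.weights, cmap="RdYlGn", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(len(labels)), labels, rotation=90, fontsize=6)
    ax.set_yticks(range(len(labels)), labels, fontsize=6)
    ax.set_xlabel("wave-2 target")
    ax.set_ylabel("wave-1 source")
    fig.colorbar(im, label="edge weight")
    fig.tight_layout()
    fig.savefig(out / "network_heatmap.png", dpi=150)
    plt.close(fig)

    tab = cent.centrality_table(net).to_frame()
    fig, axes = plt.subplots(1, 2, figsize=(8, 5), sharey=True)
    for ax, col in zip(axes, ("oei", "iei")):
        ax.barh(tab["item"], tab[col])
        ax.set_title(col.upper())
        ax.tick_params(labelsize=6)
    fig.tight_layout()
    fig.savefig(out / "centrality.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, arr in stab.correlations.items():
        med = np.nanmedian(arr, axis=1)
        ax.plot(1 - stab.drop_proportions, med, marker="o", label=name.upper())
    ax.axhline(0.7, ls="--", color="grey")
    ax.set_xlabel("proportion of cases retained")
    ax.set_ylabel("correlation with full-sample centrality")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out / "stability.png", dpi=150)
    plt.close(fig)
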