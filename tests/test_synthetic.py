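"""Generator correctness: planted structure, discretization, linkage."""

import numpy as np
import pytest
from scipy import stats

from clpnet.synthetic import (
    GeneratorConfig,
    discretize_likert,
    generate_panel,
    generate_tables,
    make_true_clpn,
)


class TestMakeTrueClpn:
    def test_full_density_fills_every_offdiagonal(self):
        B = make_true_clpn(p=3, n_hub_out=0, n_hub_in=0, density=1.0, hub_scale=1.0, seed=1)
        assert np.all(np.diag(B) == 0)
        off = B[~np.eye(3, dtype=bool)]
        assert np.all(off != 0) and off.size == 6

    def test_hub_row_dominates_row_sums(self):
        B = make_true_clpn(p=20, n_hub_out=1, n_hub_in=1, seed=3)
        row_sums = np.abs(B).sum(axis=1)
        assert row_sums[0] == row_sums.max()
        col_sums = np.abs(B).sum(axis=0)
        assert col_sums[-1] == col_sums.max()

    def test_seed_determinism(self):
        a = make_true_clpn(p=20, density=0.1, seed=7)
        b = make_true_clpn(p=20, density=0.1, seed=7)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize(
        "kwargs",
        [dict(p=1), dict(p=5, density=0.0), dict(p=5, density=1.2),
         dict(p=5, density=0.05, n_hub_out=2, n_hub_in=2)],
    )
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(ValueError):
            make_true_clpn(**kwargs)


class TestDiscretize:
    def test_floor_and_interior_categories(self):
        thr = np.array([[-0.5, 0.5]])
        assert discretize_likert(np.array([[-50.0]]), thr)[0, 0] == 1
        assert discretize_likert(np.array([[0.0]]), thr)[0, 0] == 2
        assert discretize_likert(np.array([[50.0]]), thr)[0, 0] == 3

    def test_non_monotone_thresholds_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            discretize_likert(np.zeros((2, 1)), np.array([[0.5, -0.5]]))

    def test_category_frequencies_match_normal_gaps(self):
        # multinomial cell probabilities are the Phi-gaps of the cut points
        rng = np.random.default_rng(0)
        thr = np.array([[-1.0, -0.2, 0.4, 1.3]])
        x = rng.standard_normal((100_000, 1))
        cats = discretize_likert(x, thr)[:, 0]
        edges = np.concatenate([[-np.inf], thr[0], [np.inf]])
        expected = np.diff(stats.norm.cdf(edges))
        observed = np.bincount(cats, minlength=6)[1:] / len(cats)
        assert np.abs(observed - expected).max() < 0.01

    def test_symmetric_thresholds_give_symmetric_marginals(self):
        rng = np.random.default_rng(1)
        thr = np.array([[-0.9, -0.3, 0.3, 0.9]])
        cats = discretize_likert(rng.standard_normal((100_000, 1)), thr)[:, 0]
        counts = np.bincount(cats, minlength=6)[1:]
        edges = np.concatenate([[-np.inf], thr[0], [np.inf]])
        expected = np.diff(stats.norm.cdf(edges)) * counts.sum()
        assert stats.chisquare(counts, expected).pvalue > 0.01


class TestGeneratePanel:
    def test_null_model_has_no_cross_wave_correlation(self):
        cfg = GeneratorConfig(
            n_participants=5000, n_items=6, seed=2,
            true_cross_lagged=np.zeros((6, 6)),
            autoregressive_range=(0.0, 1e-9),
            latent_wave1_correlation=0.0,
            covariate_effects=(0.0, 0.0),
        )
        panel, _ = generate_panel(cfg)
        X1 = panel.wave1_items.to_numpy(float)
        X2 = panel.wave2_items.to_numpy(float)
        cross = np.corrcoef(X1.T, X2.T)[:6, 6:]
        assert np.abs(cross).max() < 0.05

    def test_single_planted_edge_recovered_by_ols(self):
        B = np.zeros((4, 4))
        B[0, 1] = 0.5
        cfg = GeneratorConfig(
            n_participants=5000, n_items=4, seed=3, true_cross_lagged=B,
            autoregressive_range=(0.0, 1e-9), covariate_effects=(0.0, 0.0),
        )
        panel, _ = generate_panel(cfg)
        X = panel.wave1_items.to_numpy(float)
        X = np.column_stack([np.ones(len(X)), (X - X.mean(0)) / X.std(0)])
        y = panel.wave2_items.iloc[:, 1].to_numpy(float)
        coef = np.linalg.lstsq(X, y, rcond=None)[0][1:]
        assert coef[0] > 0
        assert coef[0] == np.abs(coef).max()

    def test_byte_identical_regeneration(self):
        cfg = GeneratorConfig(n_participants=200, seed=5, n_extra_wave1=30)
        w1a, w2a, ta = generate_tables(cfg)
        w1b, w2b, tb = generate_tables(cfg)
        assert w1a.equals(w1b) and w2a.equals(w2b)
        np.testing.assert_array_equal(ta.true_cross_lagged, tb.true_cross_lagged)

    def test_nonstationary_lag_matrix_rejected(self):
        B = np.full((4, 4), 0.5)
        np.fill_diagonal(B, 0.0)
        cfg = GeneratorConfig(n_participants=100, n_items=4, seed=0,
                              true_cross_lagged=B, autoregressive_range=(0.9, 0.95))
        with pytest.raises(ValueError, match="non-stationary"):
            generate_panel(cfg)

    def test_tiny_sample_flags_warning(self):
        panel, _ = generate_panel(GeneratorConfig(n_participants=20, seed=0))
        assert "unstable_n_warning" in panel.meta

    def test_screener_linkage_matches_loading(self):
        cfg = GeneratorConfig(n_participants=10_000, seed=9)
        panel, _ = generate_panel(cfg)
        r = np.corrcoef(panel.wave1_screener_total, panel.wave1_items.mean(axis=1))[0, 1]
        assert abs(r - cfg.screener_loading) < 0.05

    def test_unmatched_extras_land_in_one_wave_only(self):
        cfg = GeneratorConfig(n_participants=100, n_extra_wave1=40, n_extra_wave2=25, seed=4)
        w1, w2, _ = generate_tables(cfg)
        assert len(w1) == 140 and len(w2) == 125
        shared = np.intersect1d(w1["id"], w2["id"])
        assert len(shared) == 100

    def test_thresholds_strictly_increasing(self):
        _, truth = generate_panel(GeneratorConfig(n_participants=50, seed=1))
        for key in ("wave1", "wave2"):
            thr = truth.discretization_thresholds[key]
            assert np.all(np.diff(thr, axis=1) > 0)
            assert thr.shape[1] == 4  # likert_levels - 1
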