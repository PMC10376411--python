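"""Cohort IO, matching, screening and descriptive statistics."""

import numpy as np
import pandas as pd
import pingouin
import pytest

from clpnet import cohort
from clpnet.cohort import (
    PanelValidationError,
    SchemaError,
    cronbach_alpha,
    descriptives_table,
    match_waves,
    read_panel,
    screen,
)
from clpnet.synthetic import GeneratorConfig, write_panel_csvs

from conftest import make_panel


def _wave_frame(ids, p=2, k=1, value=3, scr=1):
    d = {"id": ids, "age": 14, "gender": 0}
    for j in range(p):
        d[f"iat{j + 1}"] = value
    for j in range(k):
        d[f"phq{j + 1}"] = scr
    return pd.DataFrame(d)


class TestReadPanel:
    def test_roundtrip_from_generator(self, tmp_path):
        cfg = GeneratorConfig(n_participants=60, seed=1)
        p1, p2, _ = write_panel_csvs(cfg, tmp_path)
        w1, w2 = read_panel(p1, p2)
        assert len(w1) == 60 and len(w2) == 60
        assert "iat20" in w1.columns and "phq9" in w1.columns

    def test_out_of_range_score_names_offender(self, tmp_path):
        cfg = GeneratorConfig(n_participants=10, seed=1)
        p1, p2, _ = write_panel_csvs(cfg, tmp_path)
        df = pd.read_csv(p1)
        df.loc[4, "iat3"] = 7
        df.to_csv(p1, index=False)
        with pytest.raises(PanelValidationError, match=r"row 4, column iat3"):
            read_panel(p1, p2)

    def test_empty_file_is_schema_error(self, tmp_path):
        empty = tmp_path / "w1.csv"
        empty.write_text("")
        with pytest.raises(SchemaError):
            read_panel(empty, empty)

    def test_missing_column_is_schema_error(self, tmp_path):
        cfg = GeneratorConfig(n_participants=10, seed=1)
        p1, p2, _ = write_panel_csvs(cfg, tmp_path)
        df = pd.read_csv(p1).drop(columns=["age"])
        df.to_csv(p1, index=False)
        with pytest.raises(SchemaError, match="age"):
            read_panel(p1, p2)


class TestMatchWaves:
    def test_inner_join_counts_dropped(self):
        panel = match_waves(_wave_frame([1, 2, 3]), _wave_frame([2, 3, 4]))
        assert panel.n == 2
        assert panel.meta["dropped_wave1"] == 1
        assert panel.meta["dropped_wave2"] == 1
        np.testing.assert_array_equal(panel.ids, [2, 3])

    def test_disjoint_keys_give_empty_panel_with_warning(self):
        panel = match_waves(_wave_frame([1, 2]), _wave_frame([3, 4]))
        assert panel.n == 0
        assert "warning" in panel.meta

    def test_duplicate_keys_are_ambiguous(self):
        with pytest.raises(ValueError, match="ambiguous"):
            match_waves(_wave_frame([1, 1, 2]), _wave_frame([1, 2]))

    def test_large_overlap_fixture_matches_planted_count(self):
        # 10,104 wave-1 rows and 8,390 wave-2 rows sharing 2,415 keys
        cfg = GeneratorConfig(
            n_participants=2415, n_extra_wave1=10104 - 2415,
            n_extra_wave2=8390 - 2415, seed=11,
        )
        from clpnet.synthetic import generate_tables

        w1, w2, _ = generate_tables(cfg)
        rename = {f"item{j + 1}": f"iat{j + 1}" for j in range(20)}
        rename |= {f"scr{j + 1}": f"phq{j + 1}" for j in range(9)}
        panel = match_waves(w1.rename(columns=rename), w2.rename(columns=rename))
        assert panel.n == 2415
        assert panel.meta["dropped_wave1"] == 7689
        assert panel.meta["dropped_wave2"] == 5975


class TestScreen:
    def test_cutoff_zero_keeps_everyone(self):
        panel = make_panel(np.ones((10, 2)), np.ones((10, 2)))
        subset, prev1, prev2 = screen(panel, cutoff=0)
        assert subset.n == 10 and prev1 == 100.0 and prev2 == 100.0

    def test_cutoff_out_of_range_rejected(self):
        panel = make_panel(np.ones((5, 2)), np.ones((5, 2)))
        with pytest.raises(ValueError, match="cutoff"):
            screen(panel, cutoff=28)

    def test_subset_size_non_increasing_in_cutoff(self):
        rng = np.random.default_rng(0)
        scr = rng.integers(0, 28, size=200)
        panel = make_panel(np.ones((200, 2)), np.ones((200, 2)), scr1=scr, scr2=scr)
        sizes = [screen(panel, c)[0].n for c in (0, 4, 8, 12, 20)]
        assert sizes == sorted(sizes, reverse=True)

    def test_prevalence_invariant_to_row_order(self):
        rng = np.random.default_rng(1)
        scr = rng.integers(0, 28, size=100)
        panel = make_panel(np.ones((100, 2)), np.ones((100, 2)), scr1=scr, scr2=scr)
        perm = panel.take(rng.permutation(100))
        assert screen(panel, 8)[1:] == screen(perm, 8)[1:]


class TestDescriptives:
    def test_effect_size_identity_and_oracle(self, small_panel):
        panel, _ = small_panel
        tab = descriptives_table(panel)
        n = panel.n
        # dz * sqrt(n) reproduces t exactly (paired-design identity)
        np.testing.assert_allclose(tab["cohens_d"] * np.sqrt(n), tab["t"], rtol=1e-12)
        assert (tab["df"] == n - 1).all()
        assert (tab["diff_ci_lower"] <= tab["mean_diff"]).all()
        assert (tab["mean_diff"] <= tab["diff_ci_upper"]).all()
        # independent oracle for one item
        lbl = panel.item_labels[0]
        res = pingouin.ttest(
            panel.wave2_items[lbl], panel.wave1_items[lbl], paired=True
        )
        row = tab.iloc[0]
        np.testing.assert_allclose(row["t"], res["T"].iloc[0], rtol=1e-9)
        np.testing.assert_allclose(row["p"], res["p_val"].iloc[0], rtol=1e-9)

    def test_identical_waves_flag_undefined_t(self):
        X = np.tile([1, 2, 3, 4, 5], (4, 1)).T
        tab = descriptives_table(make_panel(X, X))
        assert (~tab["t_defined"]).all()
        assert (tab["mean_diff"] == 0).all()
        assert tab["t"].isna().all()

    def test_row_permutation_invariance(self, small_panel):
        panel, _ = small_panel
        perm = panel.take(np.random.default_rng(3).permutation(panel.n))
        a = descriptives_table(panel).drop(columns="item")
        b = descriptives_table(perm).drop(columns="item")
        pd.testing.assert_frame_equal(a, b, atol=1e-12)


class TestCronbachAlpha:
    def test_parallel_duplicates_give_one(self):
        x = np.random.default_rng(0).normal(size=100)
        assert cronbach_alpha(np.column_stack([x, x, x])) == pytest.approx(1.0)

    def test_independent_columns_give_zero(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(100_000, 2))
        assert abs(cronbach_alpha(X)) < 0.05

    def test_matches_closed_form_from_known_covariance(self):
        rng = np.random.default_rng(2)
        S = np.array([[1.0, 0.5, 0.4], [0.5, 1.0, 0.6], [0.4, 0.6, 1.0]])
        X = rng.multivariate_normal(np.zeros(3), S, size=10_000)
        k = 3
        alpha_true = k / (k - 1) * (1 - np.trace(S) / S.sum())
        assert cronbach_alpha(X) == pytest.approx(alpha_true, abs=0.01)

    def test_matches_pingouin(self, small_panel):
        panel, _ = small_panel
        ours = cronbach_alpha(panel.wave1_items)
        theirs = pingouin.cronbach_alpha(panel.wave1_items)[0]
        assert ours == pytest.approx(theirs, abs=1e-9)

    def test_zero_variance_total_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            cronbach_alpha(np.ones((10, 3)))
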