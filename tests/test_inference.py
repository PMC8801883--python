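"""RCBD ANOVA, marginal means and Tukey comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kernelset import fit_rcbd, marginal_means, tukey_hsd


def rcbd_table(rng, hybrids=2, treatments=2, blocks=3, hyb_eff=None,
               trt_eff=None, noise=0.0):
    hyb_eff = hyb_eff or {}
    trt_eff = trt_eff or {}
    rows = []
    for h in range(hybrids):
        for t in range(treatments):
            for b in range(blocks):
                y = (10.0 + hyb_eff.get(h, 0.0) + trt_eff.get(t, 0.0)
                     + 0.5 * b + noise * rng.standard_normal())
                rows.append({"hybrid": f"H{h}", "treatment": f"T{t}",
                             "block": b + 1, "y": y})
    return pd.DataFrame(rows)


class TestFitRcbd:
    def test_constant_response_gives_zero_effects(self, rng):
        df = rcbd_table(rng)
        df["y"] = 7.0
        res = fit_rcbd(df, "y", ["hybrid", "treatment"], nest_block_in=None)
        effects = res.terms[res.terms["source"] != "Residual"]
        assert np.allclose(effects["sum_sq"], 0.0, atol=1e-18)
        assert np.allclose(effects["F"], 0.0)

    def test_balanced_two_way_matches_hand_decomposition(self, rng):
        """Known additive effects, no noise: sums of squares must equal
        the closed-form two-way ANOVA formulas."""
        hyb_eff, trt_eff = {0: 0.0, 1: 4.0}, {0: 0.0, 1: -2.0}
        df = rcbd_table(rng, hyb_eff=hyb_eff, trt_eff=trt_eff)
        res = fit_rcbd(df, "y", ["hybrid", "treatment"], nest_block_in=None)
        t = res.terms.set_index("source")

        grand = df["y"].mean()
        ss_h = sum(len(g) * (g["y"].mean() - grand) ** 2
                   for _, g in df.groupby("hybrid"))
        ss_t = sum(len(g) * (g["y"].mean() - grand) ** 2
                   for _, g in df.groupby("treatment"))
        ss_b = sum(len(g) * (g["y"].mean() - grand) ** 2
                   for _, g in df.groupby("block"))
        assert t.loc["C(hybrid)", "sum_sq"] == pytest.approx(ss_h, abs=1e-8)
        assert t.loc["C(treatment)", "sum_sq"] == pytest.approx(ss_t, abs=1e-8)
        assert t.loc["C(block)", "sum_sq"] == pytest.approx(ss_b, abs=1e-8)
        assert t.loc["Residual", "sum_sq"] == pytest.approx(0.0, abs=1e-8)

    def test_balanced_ss_conservation(self, rng):
        df = rcbd_table(rng, hybrids=3, treatments=4, noise=1.0,
                        hyb_eff={1: 2.0}, trt_eff={2: -1.0})
        res = fit_rcbd(df, "y", ["hybrid", "treatment"],
                       interactions=[("hybrid", "treatment")],
                       nest_block_in=None)
        total = ((df["y"] - df["y"].mean()) ** 2).sum()
        assert res.terms["sum_sq"].sum() == pytest.approx(total, abs=1e-8)

    def test_aliased_terms_named(self, rng):
        df = rcbd_table(rng, noise=1.0)
        df["dup"] = df["treatment"]
        with pytest.raises(ValueError, match="aliased"):
            fit_rcbd(df, "y", ["treatment", "dup"], nest_block_in=None)

    def test_missing_column_rejected(self, rng):
        df = rcbd_table(rng)
        with pytest.raises(ValueError):
            fit_rcbd(df, "nope", ["hybrid"], nest_block_in=None)


class TestPower:
    def test_injected_interaction_detected(self):
        """A full-contrast hybrid x shading interaction (sensitivities 0
        vs 1) is detected at alpha = 0.05 in at least 80% of seeds."""
        import warnings
        from kernelset import (REFERENCE_HYBRIDS, default_shading_config,
                               simulate_shading_experiment)
        genos = [("H1", REFERENCE_HYBRIDS["H1"], 0.0),
                 ("H2", REFERENCE_HYBRIDS["H2"], 0.0),
                 ("H3", REFERENCE_HYBRIDS["H3"], 1.0),
                 ("H4", REFERENCE_HYBRIDS["H4"], 1.0)]
        sig, n_seeds = 0, 25
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for seed in range(n_seeds):
                sim = simulate_shading_experiment(
                    default_shading_config(seed=seed, genotypes=genos))
                res = fit_rcbd(sim.plots, "yield_mg_ha",
                               ["env", "hybrid", "treatment"],
                               interactions=[("hybrid", "treatment")])
                p = res.terms.set_index("source").loc[
                    "C(hybrid):C(treatment)", "p"]
                sig += p < 0.05
        assert sig >= 0.8 * n_seeds


class TestMarginalMeans:
    def test_balanced_equals_cell_means(self, rng):
        df = rcbd_table(rng, hybrids=3, treatments=2, noise=1.0,
                        hyb_eff={1: 3.0})
        res = fit_rcbd(df, "y", ["hybrid", "treatment"], nest_block_in=None)
        mm = marginal_means(res, "hybrid").set_index("hybrid")["mean"]
        cell = df.groupby("hybrid")["y"].mean()
        np.testing.assert_allclose(mm[cell.index], cell, atol=1e-10)

    def test_unbalanced_matches_reference_grid_oracle(self, rng):
        df = rcbd_table(rng, hybrids=2, treatments=3, noise=1.0,
                        trt_eff={1: 2.0})
        df = df.drop(index=df.index[:2]).reset_index(drop=True)  # unbalance
        res = fit_rcbd(df, "y", ["hybrid", "treatment"], nest_block_in=None)
        mm = marginal_means(res, "treatment").set_index("treatment")["mean"]
        # oracle: explicit prediction averaging over the full factor grid
        import itertools
        for trt in df["treatment"].unique():
            grid = pd.DataFrame(
                [{"hybrid": h, "block": b, "treatment": trt}
                 for h, b in itertools.product(df["hybrid"].unique(),
                                               df["block"].unique())])
            oracle = res.model.predict(grid).mean()
            assert mm[trt] == pytest.approx(oracle, abs=1e-10)

    def test_unknown_factor_rejected(self, rng):
        res = fit_rcbd(rcbd_table(rng, noise=1.0), "y", ["hybrid"],
                       nest_block_in=None)
        with pytest.raises(ValueError):
            marginal_means(res, "treatment")

    def test_empty_cell_warns(self, rng):
        df = rcbd_table(rng, hybrids=2, treatments=2, noise=1.0)
        df = df[~((df["hybrid"] == "H1") & (df["treatment"] == "T1"))]
        res = fit_rcbd(df, "y", ["hybrid", "treatment"], nest_block_in=None)
        with pytest.warns(UserWarning, match="unobserved"):
            marginal_means(res, "hybrid")


class TestTukey:
    def test_identical_groups(self, rng):
        df = rcbd_table(rng, hybrids=1, treatments=2, blocks=6, noise=1.0)
        df.loc[df["treatment"] == "T1", "y"] = \
            df.loc[df["treatment"] == "T0", "y"].to_numpy()
        res = fit_rcbd(df, "y", ["treatment"], nest_block_in=None)
        pairs, _ = tukey_hsd(res, "treatment")
        assert pairs["difference"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert pairs["p_adj"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_two_groups_equal_pooled_t_test(self, rng):
        """For k = 2 the studentized range is t*sqrt(2), so the Tukey
        adjusted p must equal the pooled two-sample p from the model MSE."""
        df = rcbd_table(rng, hybrids=1, treatments=2, blocks=8, noise=1.5,
                        trt_eff={1: 1.2})
        res = fit_rcbd(df, "y", ["treatment"], block=None, nest_block_in=None)
        pairs, _ = tukey_hsd(res, "treatment")
        a = df.loc[df["treatment"] == "T0", "y"]
        b = df.loc[df["treatment"] == "T1", "y"]
        t_p = stats.ttest_ind(a, b).pvalue
        assert pairs["p_adj"].iloc[0] == pytest.approx(t_p, rel=1e-6)
        assert pairs["q"].iloc[0] == pytest.approx(
            abs(stats.ttest_ind(a, b).statistic) * np.sqrt(2), rel=1e-6)

    def test_hsd_matches_published_studentized_range(self, rng):
        """Balanced k = 4, residual df = 20: HSD = q(0.05, 4, 20) *
        sqrt(MSE/n) with q = 3.958 from published tables."""
        rows = [{"treatment": f"T{t}", "y": 10 + t + rng.standard_normal()}
                for t in range(4) for _ in range(6)]
        df = pd.DataFrame(rows)
        res = fit_rcbd(df, "y", ["treatment"], block=None, nest_block_in=None)
        assert res.residual_df == 20
        _, hsd = tukey_hsd(res, "treatment")
        assert hsd == pytest.approx(3.958 * np.sqrt(res.mse / 6.0), rel=1e-3)

    def test_adjusted_p_never_below_unadjusted(self, rng):
        df = rcbd_table(rng, hybrids=1, treatments=4, blocks=5, noise=1.0,
                        trt_eff={1: 0.8, 2: -0.5})
        res = fit_rcbd(df, "y", ["treatment"], nest_block_in=None)
        pairs, _ = tukey_hsd(res, "treatment")
        for row in pairs.itertuples():
            t_unadj = 2 * stats.t.sf(row.q / np.sqrt(2), res.residual_df)
            assert row.p_adj >= t_unadj - 1e-12

    def test_single_level_rejected(self, rng):
        df = rcbd_table(rng, hybrids=1, treatments=1, noise=1.0)
        with pytest.raises(ValueError, match="2 levels"):
            fit_rcbd(df, "y", ["treatment"], nest_block_in=None)
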