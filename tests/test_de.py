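"""DE engine: size factors, dispersions, Wald tests vs brute-force likelihood, BH."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import twostep_rnaseq as tr
from twostep_rnaseq.de import (
    NBDifferentialExpression,
    bh_adjust,
    de_genes,
    estimate_dispersions,
    filter_low,
    qq_calibration,
    size_factors,
    wald_test,
)


class TestSizeFactors:
    def test_identical_samples(self):
        c = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        sf = size_factors(c)
        assert np.allclose(sf, 1.0)

    def test_exact_doubling(self):
        c = pd.DataFrame({"a": [10, 20, 5, 7], "b": [20, 40, 10, 14]})
        sf = size_factors(c)
        # median of ratios with geometric mean rescaled to 1: (1/sqrt2, sqrt2)
        assert sf["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf["b"] == pytest.approx(np.sqrt(2))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        c = pd.DataFrame(rng.poisson(50, (30, 4)), columns=list("abcd"))
        sf1 = size_factors(c)
        sf2 = size_factors(c.sample(frac=1, random_state=1))
        pd.testing.assert_series_equal(sf1, sf2)

    def test_no_common_transcript_falls_back_with_warning(self):
        c = pd.DataFrame({"a": [10, 0], "b": [0, 10]})
        with pytest.warns(UserWarning):
            sf = size_factors(c)
        assert (sf > 0).all()


class TestFilterLow:
    def test_strict_threshold(self):
        c = pd.DataFrame(
            {"a": [0, 2, 10, 11, 50], "b": [0, 3, 10, 10, 50]},
            index=list("vwxyz"),
        )
        kept = filter_low(c, 20)
        # totals (0, 5, 20, 21, 100): strictly greater than 20 keeps 2
        assert list(kept.index) == ["y", "z"]

    def test_zero_threshold_drops_only_allzero(self):
        c = pd.DataFrame({"a": [0, 1], "b": [0, 0]}, index=["u", "v"])
        assert list(filter_low(c, 0).index) == ["v"]


class TestDispersions:
    @staticmethod
    def _design(n_per=3):
        cols = [f"c{i}" for i in range(n_per)] + [f"t{i}" for i in range(n_per)]
        cond = pd.Series(["ctrl"] * n_per + ["trt"] * n_per, index=cols)
        return cols, cond

    def test_poisson_counts_get_tiny_dispersion(self):
        rng = np.random.default_rng(1)
        cols, cond = self._design(4)
        mu = rng.uniform(200, 2000, 1500)
        c = pd.DataFrame(rng.poisson(mu[:, None], (1500, 8)), columns=cols)
        sf = size_factors(c)
        dm = estimate_dispersions(c, cond, sf)
        assert dm.final.median() <= 0.01

    def test_nb_alpha_point_two_recovered(self):
        rng = np.random.default_rng(2)
        cols, cond = self._design(6)
        mu = rng.uniform(100, 3000, 2000)
        alpha = 0.2
        lam = rng.gamma(1 / alpha, alpha * mu[:, None], (2000, 12))
        c = pd.DataFrame(rng.poisson(lam), columns=cols)
        dm = estimate_dispersions(c, cond, size_factors(c))
        assert 0.1 <= dm.raw.median() <= 0.3
        assert 0.1 <= dm.final.median() <= 0.3

    def test_zero_variance_clipped_to_floor(self):
        cols, cond = self._design(3)
        c = pd.DataFrame([[7, 7, 7, 9, 9, 9]], columns=cols)
        # single gene with zero within-condition variance: raw estimate hits the floor
        dm = estimate_dispersions(c, cond, pd.Series(1.0, index=cols))
        assert dm.final.iloc[0] <= 1e-6

    def test_single_replicate_condition_skipped(self):
        cols = ["c0", "c1", "t0"]
        cond = pd.Series(["ctrl", "ctrl", "trt"], index=cols)
        c = pd.DataFrame(np.random.default_rng(3).poisson(100, (50, 3)), columns=cols)
        with pytest.warns(UserWarning, match="single replicate"):
            dm = estimate_dispersions(c, cond, pd.Series(1.0, index=cols))
        assert (dm.final > 0).all()


def nb_profile_loglik_lfc(y, x, sf, alpha, lfc_grid):
    """Brute-force oracle: profile log-likelihood over b0 on a log2fc grid."""
    best = -np.inf
    best_lfc = 0.0
    for lfc in lfc_grid:
        b1 = lfc * np.log(2)
        # inner 1-d maximization over b0 by dense scan + refinement
        m = np.log(max(np.mean(y / (sf * np.exp(b1 * x))), 1e-8))
        b0s = np.linspace(m - 1.5, m + 1.5, 121)
        mu = sf[None, :] * np.exp(b0s[:, None] + b1 * x[None, :])
        ll = (y[None, :] * np.log(mu) - (y[None, :] + 1 / alpha) * np.log1p(alpha * mu)).sum(axis=1)
        k = np.argmax(ll)
        lo, hi = b0s[max(k - 1, 0)], b0s[min(k + 1, len(b0s) - 1)]
        b0s = np.linspace(lo, hi, 101)
        mu = sf[None, :] * np.exp(b0s[:, None] + b1 * x[None, :])
        ll = (y[None, :] * np.log(mu) - (y[None, :] + 1 / alpha) * np.log1p(alpha * mu)).sum(axis=1)
        cur = ll.max()
        if cur > best:
            best = cur
            best_lfc = lfc
    return best_lfc


class TestWaldTest:
    def test_identical_groups_are_null(self, toy_design):
        c = pd.DataFrame(
            [[10, 12, 11, 10, 12, 11]], columns=toy_design.index, index=["T1"]
        )
        sf = pd.Series(1.0, index=toy_design.index)
        res = wald_test(c, toy_design, sf, pd.Series({"T1": 0.1}), ("treated", "control"), min_total_reads=0)
        assert res.loc["T1", "log2FoldChange"] == pytest.approx(0.0, abs=1e-6)
        assert res.loc["T1", "pvalue"] == pytest.approx(1.0, abs=1e-6)

    def test_fourfold_change_recovered(self, toy_counts, toy_design):
        sf = pd.Series(1.0, index=toy_design.index)
        disp = pd.Series(1e-8, index=toy_counts.index)
        res = wald_test(toy_counts, toy_design, sf, disp, ("treated", "control"))
        assert res.loc["TA", "log2FoldChange"] == pytest.approx(2.0, abs=0.01)
        assert res.loc["TA", "pvalue"] < 1e-6

    def test_label_swap_antisymmetry(self, toy_counts, toy_design):
        sf = pd.Series(1.0, index=toy_design.index)
        disp = pd.Series(0.05, index=toy_counts.index)
        fwd = wald_test(toy_counts, toy_design, sf, disp, ("treated", "control"))
        swapped = toy_design.copy()
        swapped["condition"] = swapped["condition"].map({"treated": "control", "control": "treated"})
        rev = wald_test(toy_counts, swapped, sf, disp, ("treated", "control"))
        assert np.allclose(fwd["log2FoldChange"], -rev["log2FoldChange"], atol=1e-6)
        assert np.allclose(fwd["pvalue"], rev["pvalue"], atol=1e-6)

    def test_untested_transcripts_have_missing_p(self, toy_design):
        c = pd.DataFrame(
            [[1, 0, 1, 0, 1, 0], [50, 40, 60, 45, 55, 50]],
            columns=toy_design.index,
            index=["low", "high"],
        )
        sf = pd.Series(1.0, index=toy_design.index)
        disp = pd.Series(0.1, index=c.index)
        res = wald_test(c, toy_design, sf, disp, ("treated", "control"), min_total_reads=20)
        assert not res.loc["low", "tested"]
        assert np.isnan(res.loc["low", "pvalue"]) and np.isnan(res.loc["low", "padj"])
        assert res.loc["high", "tested"]

    def test_mle_matches_profile_likelihood_grid(self):
        # oracle equivalence on a simulated panel: <= 0.01 discrepancy on >= 99%
        cfg = tr.SimConfig(n_genes=200, seed=13, baseline_log_sd=1.0)
        ann = tr.simulate_annotation(cfg)
        truth = tr.make_truth(cfg, ann)
        counts = tr.simulate_counts(cfg, truth, 1e6, ann)
        design = tr.make_design(cfg)
        sf = size_factors(counts)
        disp = truth.dispersion
        res = wald_test(counts, design, sf, disp, ("treatment", "control"))
        tested = res.index[res["tested"] & res["converged"]]
        x = np.array([0.0] * 3 + [1.0] * 3)
        cols = list(design.index[design["condition"] == "control"]) + list(
            design.index[design["condition"] == "treatment"]
        )
        sf_vec = sf[cols].to_numpy()
        hits = 0
        for t in tested:
            est = res.loc[t, "log2FoldChange"]
            grid = np.arange(est - 0.05, est + 0.05, 0.001)
            oracle = nb_profile_loglik_lfc(
                counts.loc[t, cols].to_numpy(float), x, sf_vec, max(disp[t], 1e-8), grid
            )
            hits += abs(oracle - est) <= 0.01
        assert hits / len(tested) >= 0.99


class TestBHAdjust:
    def test_worked_example(self):
        q = bh_adjust([0.01, 0.02, 0.04, 0.5])
        assert np.allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_nan_excluded_from_m(self):
        q = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(q[1])
        assert np.allclose(q[[0, 2]], bh_adjust([0.01, 0.02]))

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_step_up_brute_force(self, ps):
        q = bh_adjust(ps)
        # independent step-up oracle
        p = np.asarray(ps)
        m = len(p)
        order = np.argsort(p, kind="mergesort")
        expected = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * m / rank)
            expected[i] = running
        assert np.allclose(q, expected)
        # monotone non-decreasing in p-rank
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDeGenes:
    @staticmethod
    def _results(rows):
        df = pd.DataFrame(
            rows, columns=["gene_id", "log2FoldChange", "padj"]
        )
        df["tested"] = True
        df.index = [f"tx{i}" for i in range(len(df))]
        return df

    def test_empty_results(self):
        res = self._results([])
        assert len(de_genes(res, fdr=0.1)) == 0

    def test_any_transcript_rule(self):
        res = self._results([["g1", 1.2, 0.05], ["g1", 0.8, 0.5]])
        out = de_genes(res, fdr=0.1)
        assert list(out.index) == ["g1"]
        assert out.loc["g1", "direction_best"] == "up"

    def test_conflicting_signs_counted_both_ways(self):
        res = self._results(
            [["g1", 1.0, 0.01], ["g1", -2.0, 0.05], ["g2", -1.0, 0.02], ["g3", 1.0, 0.9]]
        )
        out = de_genes(res, fdr=0.1)
        assert set(out.index) == {"g1", "g2"}
        assert bool(out.loc["g1", "up_any"]) and bool(out.loc["g1", "down_any"])
        assert bool(out.loc["g1", "conflict"])
        assert out.loc["g1", "direction_best"] == "up"  # most significant transcript
        assert out.loc["g2", "direction_best"] == "down"
        n_up = int(out["up_any"].sum())
        n_down = int(out["down_any"].sum())
        assert (n_up, n_down) == (1, 2)


class TestQQCalibration:
    def test_perfectly_uniform_grid(self):
        m = 500
        p = (np.arange(1, m + 1) - 0.5) / m
        qq = qq_calibration(p)
        assert qq.ks_stat < 0.01
        assert not qq.flagged
        assert np.allclose(qq.table["expected"], qq.table["observed"], atol=1e-9)

    def test_pathological_pvalues_flagged(self):
        qq = qq_calibration(np.full(100, 1e-10))
        assert qq.flagged
        assert qq.ks_stat > 0.9

    def test_too_few_pvalues_rejected(self):
        with pytest.raises(ValueError):
            qq_calibration([0.5] * 9)


class TestEstimatorBehavior:
    def test_fit_exposes_sklearn_surface(self, small_experiment):
        counts, design, ann, truth = small_experiment
        model = NBDifferentialExpression(fdr=0.1)
        assert model.get_params()["fdr"] == 0.1
        model.set_params(fdr=0.05)
        model.fit(counts, design, ann)
        assert hasattr(model, "results_") and "treatment" in model.results_
        assert (model.size_factors_ > 0).all()
        res = model.results_["treatment"]
        ok = res["padj"].notna()
        assert (res.loc[ok, "padj"] >= res.loc[ok, "pvalue"] - 1e-12).all()

    def test_effect_estimates_track_truth(self, small_experiment):
        counts, design, ann, truth = small_experiment
        model = NBDifferentialExpression().fit(counts, design, ann)
        res = model.results_["treatment"]
        ok = res["tested"] & res["log2FoldChange"].notna()
        slope = np.polyfit(truth.log2fc["treatment"][ok], res["log2FoldChange"][ok], 1)[0]
        assert 0.8 <= slope <= 1.2

    def test_null_contrast_calls_nothing(self):
        hits = []
        for seed in range(5):
            cfg = tr.SimConfig(
                n_genes=1000, frac_de=0.0, seed=100 + seed,
                groups=(tr.GroupSpec("ctrlA", 3, None), tr.GroupSpec("ctrlB", 3, "ctrlA")),
            )
            ann = tr.simulate_annotation(cfg)
            truth = tr.make_truth(cfg, ann)
            counts = tr.simulate_counts(cfg, truth, 2e6, ann)
            m = NBDifferentialExpression().fit(counts, tr.make_design(cfg), ann)
            hits.append(len(tr.de_gene_set(m.results_["ctrlB"], 0.1)))
        assert np.median(hits) == 0

    def test_power_grows_with_depth(self):
        cfg = tr.SimConfig(n_genes=1500, seed=42)
        ann = tr.simulate_annotation(cfg)
        truth = tr.make_truth(cfg, ann)
        design = tr.make_design(cfg)
        rng = np.random.default_rng(5)
        rates = tr.simulate_library_rates(cfg, truth, ann, rng=rng)
        n_de = []
        for depth in [1e6, 5e6, 25e6]:
            counts = tr.counts_from_rates(rates, depth, rng=rng)
            m = NBDifferentialExpression().fit(counts, design, ann)
            n_de.append(len(tr.de_gene_set(m.results_["treatment"], 0.1)))
        assert n_de[0] <= n_de[1] <= n_de[2]
        assert n_de[2] > 0
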