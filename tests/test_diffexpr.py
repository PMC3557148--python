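"""Linear models, array weights, moderated statistics, BH, evaluation."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stqc import StqcError
import stqc.batch_adjust as ba
import stqc.diffexpr as dx
from conftest import Bundle, make_config, clean_overrides


def _design(cond, arrays):
    return pd.DataFrame({"intercept": 1.0, "condition_tumour": cond}, index=arrays)


class TestFitLm:
    def test_noise_free_coefficients_exact(self):
        arrays = [f"a{i}" for i in range(6)]
        cond = np.array([0.0, 1.0] * 3)
        delta = np.array([1.5, -2.0, 0.0])
        expr = pd.DataFrame(
            5.0 + np.outer(delta, cond), index=["g1", "g2", "g3"], columns=arrays
        )
        fit = dx.fit_lm(expr, _design(cond, arrays))
        np.testing.assert_allclose(fit.coef["condition_tumour"], delta, atol=1e-12)
        np.testing.assert_allclose(fit.s2, 0.0, atol=1e-20)

    def test_unit_weights_equal_ols(self):
        rng = np.random.default_rng(0)
        arrays = [f"a{i}" for i in range(10)]
        cond = np.tile([0.0, 1.0], 5)
        expr = pd.DataFrame(rng.normal(0, 1, (50, 10)), columns=arrays)
        X = _design(cond, arrays)
        f1 = dx.fit_lm(expr, X)
        f2 = dx.fit_lm(expr, X, weights=pd.Series(1.0, index=arrays))
        pd.testing.assert_frame_equal(f1.coef, f2.coef)
        pd.testing.assert_series_equal(f1.s2, f2.s2)

    def test_weighted_fit_matches_hand_solved_normal_equations(self):
        # 4 arrays, intercept + covariate, weights alternating 4 and 1
        arrays = list("abcd")
        x = np.array([0.0, 0.0, 1.0, 1.0])
        w = np.array([4.0, 1.0, 4.0, 1.0])
        y = np.array([[1.0, 2.0, 4.0, 8.0]])
        expr = pd.DataFrame(y, index=["g"], columns=arrays)
        fit = dx.fit_lm(expr, _design(x, arrays), weights=pd.Series(w, index=arrays))
        X = np.column_stack([np.ones(4), x])
        beta_hand = np.linalg.solve(X.T @ np.diag(w) @ X, X.T @ np.diag(w) @ y[0])
        np.testing.assert_allclose(
            fit.coef.loc["g"].to_numpy(), beta_hand, atol=1e-12
        )
        resid = y[0] - X @ beta_hand
        np.testing.assert_allclose(fit.s2["g"], (w * resid**2).sum() / 2, atol=1e-12)

    def test_rank_deficient_design_names_term(self):
        arrays = [f"a{i}" for i in range(6)]
        X = _design(np.ones(6), arrays)  # condition column == intercept
        expr = pd.DataFrame(np.random.default_rng(0).normal(0, 1, (20, 6)), columns=arrays)
        with pytest.raises(StqcError, match="rank deficient"):
            dx.fit_lm(expr, X)


class TestArrayWeights:
    def test_homoscedastic_weights_near_one(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            arrays = [f"a{i}" for i in range(12)]
            cond = np.tile([0.0, 1.0], 6)
            expr = pd.DataFrame(rng.normal(0, 1, (2000, 12)), columns=arrays)
            w = dx.estimate_array_weights(expr, _design(cond, arrays))
            assert w.min() > 0.8 and w.max() < 1.25
            assert np.prod(w) == pytest.approx(1.0, abs=1e-6)

    def test_noisy_array_downweighted_fourfold(self):
        devs = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            arrays = [f"a{i}" for i in range(12)]
            cond = np.tile([0.0, 1.0], 6)
            noise = rng.normal(0, 1, (3000, 12))
            noise[:, 0] *= 2.0  # 4x error variance
            expr = pd.DataFrame(noise, columns=arrays)
            w = dx.estimate_array_weights(expr, _design(cond, arrays))
            rest = np.exp(np.mean(np.log(w.iloc[1:])))
            devs.append(w.iloc[0] / rest)
        assert np.mean(devs) == pytest.approx(0.25, rel=0.30)

    def test_flagged_arrays_get_smallest_weights(self, degraded_bundle):
        b = degraded_bundle
        expr = b.batch_corrected()
        w = dx.estimate_array_weights(expr, dx.base_design(b.meta))
        flagged = b.report.table["flagged"]
        assert flagged.sum() >= 2
        assert w[flagged].max() < np.median(w[~flagged])
        q = b.truth.arrays["q"]
        degraded = (q > 0).to_numpy()
        rho = stats.spearmanr(w[degraded], -q[degraded]).statistic
        assert rho > 0.7


class TestEbayes:
    def test_equal_variances_collapse_to_pooled_t(self):
        arrays = [f"a{i}" for i in range(8)]
        cond = np.tile([0.0, 1.0], 4)
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(0, 1, (30, 8)), columns=arrays)
        fit = dx.fit_lm(expr, _design(cond, arrays))
        fit.s2[:] = 0.7  # identical residual variances
        res = dx.ebayes_moderate(fit)
        v = float(fit.cov_unscaled.loc["condition_tumour", "condition_tumour"])
        expected_t = fit.coef["condition_tumour"] / np.sqrt(0.7 * v)
        np.testing.assert_allclose(res["t"], expected_t, rtol=1e-9)

    def test_zero_prior_df_is_ordinary_t(self):
        rng = np.random.default_rng(1)
        arrays = [f"a{i}" for i in range(10)]
        cond = np.tile([0.0, 1.0], 5)
        g1 = rng.normal(0, 1, (200, 5))
        g2 = rng.normal(0, 1, (200, 5))
        expr = pd.DataFrame(np.empty((200, 10)), columns=arrays)
        expr.iloc[:, cond == 0] = g1
        expr.iloc[:, cond == 1] = g2
        fit = dx.fit_lm(expr, _design(cond, arrays))
        res = dx.ebayes_moderate(fit, prior_df=0)
        # independently coded two-sample pooled t-test
        t_ref, p_ref = stats.ttest_ind(g2, g1, axis=1, equal_var=True)
        np.testing.assert_allclose(res["t"], t_ref, rtol=1e-9)
        np.testing.assert_allclose(res["p"], p_ref, rtol=1e-9)

    def test_large_sample_moderated_close_to_ordinary(self):
        # with many arrays the shrinkage weight d0/(d0+d) vanishes and the
        # moderated t approaches the ordinary t gene by gene
        rng = np.random.default_rng(2)
        n = 100
        arrays = [f"a{i}" for i in range(n)]
        cond = np.tile([0.0, 1.0], n // 2)
        sigma = np.exp(rng.normal(0, 1.2, (500, 1)))  # strong heterogeneity
        expr = pd.DataFrame(rng.normal(0, sigma, (500, n)), columns=arrays)
        fit = dx.fit_lm(expr, _design(cond, arrays))
        mod = dx.ebayes_moderate(fit)
        ord_ = dx.ebayes_moderate(fit, prior_df=0)
        dev = np.abs((mod["t"] / ord_["t"]).to_numpy() - 1)
        # agreement within 1% for the typical gene; only genes with
        # extreme variances retain visible shrinkage at n = 100
        assert np.percentile(dev, 75) < 0.01
        assert np.percentile(dev, 90) < 0.05

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(3)
        arrays = [f"a{i}" for i in range(16)]
        cond = np.tile([0.0, 1.0], 8)
        expr = pd.DataFrame(rng.normal(0, 1, (2000, 16)), columns=arrays)
        res = dx.ebayes_moderate(dx.fit_lm(expr, _design(cond, arrays)))
        assert stats.kstest(res["p"], "uniform").statistic < 0.05

    def test_matches_limma_ebayes(self, tmp_path):
        """Independent oracle: limma's eBayes on the same matrix."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(42)
        arrays = [f"a{i:02d}" for i in range(12)]
        cond = np.tile([0.0, 1.0], 6)
        expr = pd.DataFrame(
            rng.normal(7, 1, (150, 12)) + np.outer(rng.normal(0, 0.5, 150), cond),
            index=[f"g{i}" for i in range(150)],
            columns=arrays,
        )
        fit = dx.fit_lm(expr, _design(cond, arrays))
        res = dx.ebayes_moderate(fit)
        expr.to_csv(tmp_path / "expr.tsv", sep="\t")
        pd.DataFrame({"cond": cond}, index=arrays).to_csv(tmp_path / "meta.tsv", sep="\t")
        script = tmp_path / "limma.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f'e <- as.matrix(read.delim("{tmp_path}/expr.tsv", row.names=1))\n'
            f'm <- read.delim("{tmp_path}/meta.tsv", row.names=1)\n'
            "fit <- eBayes(lmFit(e, model.matrix(~m$cond)))\n"
            "out <- data.frame(t=fit$t[,2], p=fit$p.value[,2], d0=fit$df.prior)\n"
            f'write.table(out, "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)\n'
        )
        r = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, timeout=300
        )
        if r.returncode != 0:
            pytest.skip(f"R limma unavailable: {r.stderr[-200:]}")
        theirs = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        np.testing.assert_allclose(res["t"], theirs["t"], rtol=1e-8)
        np.testing.assert_allclose(res["p"], theirs["p"], rtol=1e-8)

    def test_all_zero_variances_rejected(self):
        arrays = [f"a{i}" for i in range(6)]
        cond = np.tile([0.0, 1.0], 3)
        expr = pd.DataFrame(
            5.0 + np.outer(np.arange(20.0), cond), columns=arrays
        )
        fit = dx.fit_lm(expr, _design(cond, arrays))
        with pytest.raises(StqcError, match="zero"):
            dx.ebayes_moderate(fit)


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(dx.bh_adjust([0.01]), [0.01])

    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            dx.bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_adjusted_at_least_raw_and_order_equivariant(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0, 1, 100)
        adj = dx.bh_adjust(p)
        assert (adj >= p - 1e-15).all()
        perm = rng.permutation(100)
        np.testing.assert_allclose(dx.bh_adjust(p[perm]), adj[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(StqcError):
            dx.bh_adjust([0.5, 1.2])
        with pytest.raises(StqcError):
            dx.bh_adjust([-0.1])


class TestOverlapCounts:
    def test_identical_lists(self):
        out = dx.overlap_counts({"x": {"A"}, "y": {"A"}})
        both = out[(out["x"]) & (out["y"])]["count"].iloc[0]
        only = out[(out["x"]) ^ (out["y"])]["count"]
        assert both == 1 and (only == 0).all()

    def test_three_sets_match_brute_force_enumeration(self):
        sets = {"s1": {"A", "B"}, "s2": {"B", "C"}, "s3": {"C", "D"}}
        out = dx.overlap_counts(sets).set_index(["s1", "s2", "s3"])["count"]
        universe = set.union(*sets.values())
        for pattern in itertools.product([True, False], repeat=3):
            if not any(pattern):
                continue
            expected = sum(
                1
                for el in universe
                if all((el in sets[n]) == m for n, m in zip(sets, pattern))
            )
            assert out.loc[pattern] == expected
        assert out.sum() == len(universe)

    def test_disjoint_lists(self):
        out = dx.overlap_counts({"x": {"A"}, "y": {"B"}})
        assert out[(out["x"]) & (out["y"])]["count"].iloc[0] == 0


class TestHcluster:
    def test_identical_arrays_merge_at_zero(self):
        expr = pd.DataFrame(
            {"a1": [1.0, 2.0, 3.0], "a2": [1.0, 2.0, 3.0], "a3": [9.0, 1.0, 4.0]}
        )
        Z = dx.hcluster(expr, distance="euclidean")
        assert Z[0, 2] == pytest.approx(0.0)

    def test_average_linkage_heights_match_hand_computation(self):
        # 1-D points 0, 1, 4, 10: merges at 1, 3.5, 25/3
        expr = pd.DataFrame([[0.0, 1.0, 4.0, 10.0]], columns=list("abcd"))
        expr = pd.concat([expr, expr * 0 + 1])  # second constant row, no effect
        Z = dx.hcluster(expr, distance="euclidean")
        np.testing.assert_allclose(sorted(Z[:, 2]), [1.0, 3.5, 25.0 / 3])

    def test_constant_array_rejected_under_pearson(self):
        expr = pd.DataFrame({"a1": [1.0, 1.0, 1.0], "a2": [1.0, 2.0, 3.0]})
        with pytest.raises(StqcError, match="constant"):
            dx.hcluster(expr, distance="one_minus_pearson")


class TestStrategies:
    def test_clean_cohort_strategies_agree(self, clean_bundle):
        """With no degradation or batch effects, all five strategies call
        essentially the same clusters differentially expressed."""
        b = clean_bundle
        sv = ba.estimate_sv(b.expr, dx.base_design(b.meta), 0, config=b.cfg).sv_matrix
        calls = {}
        for s in dx.STRATEGIES:
            res = dx.run_strategy(s, b.expr, b.report, b.meta, b.cfg, sv=sv)
            calls[s] = set(res.index[res["adj_p"] <= 0.05])
        for s1, s2 in itertools.combinations(calls, 2):
            jac = len(calls[s1] & calls[s2]) / len(calls[s1] | calls[s2])
            assert jac > 0.9, (s1, s2, jac)

    def test_degraded_cohort_bookkeeping(self, degraded_bundle):
        b = degraded_bundle
        expr = b.batch_corrected()
        n_flagged = int(b.report.table["flagged"].sum())
        assert n_flagged >= 2
        sv = ba.estimate_sv(expr, dx.base_design(b.meta), 2, seed=0, config=b.cfg).sv_matrix
        for s in dx.STRATEGIES:
            res = dx.run_strategy(s, expr, b.report, b.meta, b.cfg, sv=sv)
            assert len(res) == expr.shape[0]
            assert (res["adj_p"] >= res["p"] - 1e-15).all()

    def test_compensating_strategies_match_exclusion_sensitivity(self, degraded_bundle):
        """Retaining flagged arrays with compensation detects at least as
        many true effects as dropping them, at matched empirical FDR."""
        b = degraded_bundle
        expr = b.batch_corrected()
        de = b.truth.clusters["de_flag"]
        sv = ba.estimate_sv(expr, dx.base_design(b.meta), 2, seed=0, config=b.cfg).sv_matrix

        def sens_at_fdr(res, f=0.05):
            order = np.argsort(res["p"].to_numpy())
            is_de = de.reindex(res.index).to_numpy()[order]
            fp, tp = np.cumsum(~is_de), np.cumsum(is_de)
            k = np.arange(1, len(order) + 1)
            ok = np.flatnonzero(fp / k <= f)
            return tp[ok[-1]] / is_de.sum() if len(ok) else 0.0

        sens = {
            s: sens_at_fdr(dx.run_strategy(s, expr, b.report, b.meta, b.cfg, sv=sv))
            for s in dx.STRATEGIES
        }
        for s in ("weights", "combat", "covariate", "sva"):
            assert sens[s] >= sens["exclude"] - 0.02

    def test_sensitivity_above_080_with_default_effects(self, degraded_bundle):
        b = degraded_bundle
        expr = b.batch_corrected()
        res = dx.run_strategy("covariate", expr, b.report, b.meta, b.cfg)
        de = b.truth.clusters["de_flag"]
        called = res["adj_p"] <= 0.05
        assert (called & de).sum() / de.sum() >= 0.8

    def test_exclude_with_too_few_arrays_rejected(self, degraded_bundle):
        b = degraded_bundle
        # flag everything except two arrays
        tbl = b.report.table.copy()
        tbl["flagged"] = True
        tbl.loc[tbl.index[:2], "flagged"] = False
        tbl[["cv_pass", "pm_bg_pass", "gnuse_pass"]] = ~tbl[["flagged"] * 3].to_numpy()
        import stqc.qc_metrics as qm

        rep = qm.report_from_calls(tbl[["cv_pass", "pm_bg_pass", "gnuse_pass"]])
        with pytest.raises(StqcError, match="< 3 arrays"):
            dx.run_strategy("exclude", b.expr, rep, b.meta, b.cfg)

    def test_unknown_strategy_rejected(self, clean_bundle):
        b = clean_bundle
        with pytest.raises(StqcError, match="unknown strategy"):
            dx.run_strategy("bogus", b.expr, b.report, b.meta, b.cfg)
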