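import shutil
import subprocess

import numpy as np
import pytest
from scipy import stats

from batchlens.io_formats import BatchDesign, ExpressionMatrix
from batchlens.linear_models import (
    ConfoundingError,
    EBayesParams,
    adjust_pvalues,
    build_design,
    count_degs,
    estimate_ebayes,
    fit_genewise,
    moderated_f,
    moderated_t,
)


def _two_group(rng, n_probes, n_samples, noise_sd=1.0, mean=8.0):
    samples = [f"s{i}" for i in range(n_samples)]
    cls = {s: ("case" if i < n_samples // 2 else "control") for i, s in enumerate(samples)}
    y = mean + rng.normal(0, noise_sd, size=(n_probes, n_samples))
    matrix = ExpressionMatrix([f"p{i}" for i in range(n_probes)], samples, y)
    design = build_design(samples, class_labels=cls)
    return matrix, design, cls


class TestBuildDesign:
    def test_batch_only_coding(self):
        bd = BatchDesign("F", {f"s{i}": ("a" if i < 3 else "b") for i in range(6)})
        d = build_design(bd.sample_ids, bd)
        assert d.term_names == ["Intercept", "F[b]"]
        assert d.rank == 2

    def test_batch_plus_class_coding(self):
        bd = BatchDesign("F", {f"s{i}": ("a" if i < 6 else "b") for i in range(12)})
        cls = {f"s{i}": ("case" if i % 2 == 0 else "control") for i in range(12)}
        d = build_design(bd.sample_ids, bd, class_labels=cls)
        assert d.term_names == ["Intercept", "F[b]", "class[case]"]

    def test_class_aliased_with_batch_rejected(self):
        bd = BatchDesign("F", {f"s{i}": ("a" if i < 3 else "b") for i in range(6)})
        cls = {f"s{i}": ("case" if i < 3 else "control") for i in range(6)}
        with pytest.raises(ConfoundingError, match="F"):
            build_design(bd.sample_ids, bd, class_labels=cls)

    def test_collinear_blocking_dropped_with_warning(self):
        bd = BatchDesign("F", {f"s{i}": ("a" if i < 3 else "b") for i in range(6)})
        blocking = {"copy": {f"s{i}": ("x" if i < 3 else "y") for i in range(6)}}
        with pytest.warns(UserWarning, match="collinear"):
            d = build_design(bd.sample_ids, bd, blocking_terms=blocking)
        assert d.dropped_terms == ["copy[y]"]


class TestGenewiseFit:
    def test_exact_fit_gives_zero_variance(self):
        samples = [f"s{i}" for i in range(6)]
        cls = {s: ("case" if i < 3 else "control") for i, s in enumerate(samples)}
        design = build_design(samples, class_labels=cls)
        y = np.array([[5.0, 5.0, 5.0, 2.0, 2.0, 2.0]])
        m = ExpressionMatrix(["p0"], samples, y)
        fit = fit_genewise(m, design)
        assert fit.sigma2[0] == pytest.approx(0.0, abs=1e-18)
        assert fit.coefficients[0, 1] == pytest.approx(3.0)

    def test_two_group_coefficient_is_group_mean_difference(self):
        rng = np.random.default_rng(3)
        m, design, cls = _two_group(rng, 5, 10)
        fit = fit_genewise(m, design)
        case = [i for i, s in enumerate(m.sample_ids) if cls[s] == "case"]
        ctrl = [i for i, s in enumerate(m.sample_ids) if cls[s] == "control"]
        expected = m.values[:, case].mean(axis=1) - m.values[:, ctrl].mean(axis=1)
        np.testing.assert_allclose(fit.coefficients[:, 1], expected, atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        """OLS coefficients agree with an independent pseudo-inverse solve."""
        rng = np.random.default_rng(4)
        bd = BatchDesign("F", {f"s{i}": f"b{i % 3}" for i in range(12)})
        design = build_design(bd.sample_ids, bd)
        m = ExpressionMatrix([f"p{i}" for i in range(20)], bd.sample_ids,
                             rng.normal(8, 1, size=(20, 12)))
        fit = fit_genewise(m, design)
        x = design.matrix
        for g in range(20):
            beta = np.linalg.solve(x.T @ x, x.T @ m.values[g])
            np.testing.assert_allclose(fit.coefficients[g], beta, atol=1e-9)

    def test_saturated_design_rejected(self):
        samples = ["s0", "s1"]
        cls = {"s0": "case", "s1": "control"}
        design = build_design(samples, class_labels=cls)
        m = ExpressionMatrix(["p0"], samples, np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            fit_genewise(m, design)


class TestEstimateEbayes:
    def test_identical_variances_give_infinite_prior(self):
        samples = [f"s{i}" for i in range(6)]
        cls = {s: ("case" if i < 3 else "control") for i, s in enumerate(samples)}
        design = build_design(samples, class_labels=cls)
        base = np.array([1.0, 2.0, 4.0, 1.0, 2.0, 4.0])
        y = np.vstack([base + off for off in (0.0, 1.0, 2.0)])
        m = ExpressionMatrix(["p0", "p1", "p2"], samples, y)
        fit = fit_genewise(m, design)
        assert np.ptp(fit.sigma2) == pytest.approx(0.0, abs=1e-12)
        eb = estimate_ebayes(fit)
        assert np.isinf(eb.d0)
        assert eb.s0_sq == pytest.approx(fit.sigma2[0])

    def test_parameter_recovery_from_simulated_hierarchy(self):
        """Variances drawn from s0^2 * d0 / chi2_d0 with d0=4, s0^2=0.04:
        the moment estimator recovers d0 in [3, 5] and s0^2 within 10%."""
        rng = np.random.default_rng(9)
        G, d0_true, s0_true, n = 5000, 4.0, 0.04, 8
        true_var = s0_true * d0_true / rng.chisquare(d0_true, G)
        samples = [f"s{i}" for i in range(n)]
        cls = {s: ("case" if i < n // 2 else "control") for i, s in enumerate(samples)}
        y = rng.normal(0, 1, size=(G, n)) * np.sqrt(true_var)[:, None] + 8
        m = ExpressionMatrix([f"p{i}" for i in range(G)], samples, y)
        fit = fit_genewise(m, build_design(samples, class_labels=cls))
        eb = estimate_ebayes(fit)
        assert 3.0 <= eb.d0 <= 5.0
        assert eb.s0_sq == pytest.approx(s0_true, rel=0.10)

    def test_extreme_dispersion_gives_small_finite_prior_df(self):
        samples = [f"s{i}" for i in range(6)]
        cls = {s: ("case" if i < 3 else "control") for i, s in enumerate(samples)}
        design = build_design(samples, class_labels=cls)
        rng = np.random.default_rng(5)
        y = np.vstack([8 + 1e-2 * rng.normal(size=6), 8 + 10.0 * rng.normal(size=6)])
        m = ExpressionMatrix(["tight", "loose"], samples, y)
        fit = fit_genewise(m, design)
        eb = estimate_ebayes(fit)
        assert np.isfinite(eb.d0)
        assert eb.d0 < 10.0

    def test_all_zero_variances_rejected(self):
        samples = [f"s{i}" for i in range(4)]
        cls = {s: ("case" if i < 2 else "control") for i, s in enumerate(samples)}
        design = build_design(samples, class_labels=cls)
        y = np.array([[1.0, 1.0, 2.0, 2.0], [3.0, 3.0, 4.0, 4.0]])
        m = ExpressionMatrix(["p0", "p1"], samples, y)
        fit = fit_genewise(m, design)
        fit.sigma2[:] = 0.0
        with pytest.raises(ValueError):
            estimate_ebayes(fit)


class TestModeratedStatistics:
    def test_zero_prior_df_recovers_ordinary_t(self):
        rng = np.random.default_rng(6)
        m, design, _ = _two_group(rng, 1000, 10)
        fit = fit_genewise(m, design)
        res = moderated_t(fit, EBayesParams(0.0, 1.0), "class[case]")
        scale = fit.se_scale(np.array([0.0, 1.0]))
        ordinary = fit.coefficients[:, 1] / (scale * np.sqrt(fit.sigma2))
        np.testing.assert_allclose(res.statistic, ordinary, atol=1e-9)
        assert res.df_total == fit.df_residual

    def test_infinite_prior_df_shares_one_variance(self):
        rng = np.random.default_rng(7)
        m, design, _ = _two_group(rng, 50, 8)
        fit = fit_genewise(m, design)
        res = moderated_t(fit, EBayesParams(np.inf, 0.5), "class[case]")
        np.testing.assert_allclose(res.s2_post, 0.5)

    def test_zero_estimate_gives_t_zero_p_one(self):
        samples = [f"s{i}" for i in range(8)]
        cls = {s: ("case" if i < 4 else "control") for i, s in enumerate(samples)}
        design = build_design(samples, class_labels=cls)
        rng = np.random.default_rng(8)
        noise = rng.normal(0, 1, size=(3, 4))
        y = np.hstack([noise, noise])  # identical group patterns: zero difference
        m = ExpressionMatrix(["p0", "p1", "p2"], samples, y)
        fit = fit_genewise(m, design)
        res = moderated_t(fit, estimate_ebayes(fit), "class[case]")
        assert res.statistic[0] == pytest.approx(0.0, abs=1e-12)
        assert res.p_value[0] == pytest.approx(1.0)

    def test_missing_ebayes_rejected(self):
        rng = np.random.default_rng(9)
        m, design, _ = _two_group(rng, 10, 6)
        fit = fit_genewise(m, design)
        with pytest.raises(ValueError):
            moderated_t(fit, None, "class[case]")

    def test_shrinkage_direction(self):
        """Moderation pulls |t| down when s2_g < s0^2 and up otherwise."""
        rng = np.random.default_rng(10)
        m, design, _ = _two_group(rng, 2000, 8, noise_sd=1.0)
        # heteroscedastic probes so the prior is finite
        scale = np.exp(rng.normal(0, 0.8, size=2000))
        m = ExpressionMatrix(m.probe_ids, m.sample_ids, 8 + (m.values - 8) * scale[:, None])
        fit = fit_genewise(m, design)
        eb = estimate_ebayes(fit)
        assert np.isfinite(eb.d0)
        mod = moderated_t(fit, eb, "class[case]").statistic
        ordinary = moderated_t(fit, EBayesParams(0.0, 1.0), "class[case]").statistic
        below = fit.sigma2 < eb.s0_sq
        assert np.all(np.abs(mod[below]) <= np.abs(ordinary[below]) + 1e-12)
        assert np.all(np.abs(mod[~below]) >= np.abs(ordinary[~below]) - 1e-12)

    def test_moderated_f_single_contrast_equals_t_squared(self):
        rng = np.random.default_rng(11)
        m, design, _ = _two_group(rng, 200, 10)
        fit = fit_genewise(m, design)
        eb = estimate_ebayes(fit)
        t = moderated_t(fit, eb, "class[case]")
        f = moderated_f(fit, eb, ["class[case]"])
        np.testing.assert_allclose(f.statistic, t.statistic**2, atol=1e-9)
        np.testing.assert_allclose(f.p_value, t.p_value, atol=1e-9)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_agrees_with_limma_reference(self, tmp_path):
        """Independent oracle: limma's lmFit/eBayes on the same matrix."""
        rng = np.random.default_rng(7)
        G, n = 400, 8
        true_var = 0.25 * 5.0 / rng.chisquare(5.0, G)
        y = rng.normal(0, 1, size=(G, n)) * np.sqrt(true_var)[:, None] + 8
        np.savetxt(tmp_path / "y.tsv", y, delimiter="\t")
        script = tmp_path / "check.R"
        script.write_text(
            "suppressMessages(library(limma))\n"
            f"y <- as.matrix(read.table('{tmp_path}/y.tsv', sep='\\t'))\n"
            "design <- cbind(Intercept=1, case=c(rep(1,4), rep(0,4)))\n"
            "fit <- eBayes(lmFit(y, design))\n"
            "out <- cbind(fit$df.prior, fit$s2.prior, fit$t[,'case'], fit$p.value[,'case'])\n"
            f"write.table(out, '{tmp_path}/ref.tsv', row.names=FALSE, col.names=FALSE)\n"
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = np.loadtxt(tmp_path / "ref.tsv")
        samples = [f"s{i}" for i in range(n)]
        cls = {s: ("case" if i < 4 else "control") for i, s in enumerate(samples)}
        m = ExpressionMatrix([f"p{i}" for i in range(G)], samples, y)
        fit = fit_genewise(m, build_design(samples, class_labels=cls))
        eb = estimate_ebayes(fit)
        res = moderated_t(fit, eb, "class[case]")
        assert eb.d0 == pytest.approx(ref[0, 0], rel=1e-5)
        assert eb.s0_sq == pytest.approx(ref[0, 1], rel=1e-5)
        np.testing.assert_allclose(res.statistic, ref[:, 2], atol=1e-6)
        np.testing.assert_allclose(res.p_value, ref[:, 3], atol=1e-6)


class TestPValueAdjustment:
    def test_bh_hand_example(self):
        np.testing.assert_allclose(adjust_pvalues([0.01, 0.02, 0.03], "BH"),
                                   [0.03, 0.03, 0.03])

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(12)
        p = rng.uniform(size=100)
        for method in ("BH", "bonferroni"):
            assert np.all(adjust_pvalues(p, method) >= p - 1e-15)

    def test_count_bounds(self):
        rng = np.random.default_rng(13)
        m, design, _ = _two_group(rng, 30, 8)
        fit = fit_genewise(m, design)
        res = moderated_t(fit, estimate_ebayes(fit), "class[case]")
        assert count_degs(res, 1.0) == 30
        res_null = moderated_t(fit, estimate_ebayes(fit), "class[case]")
        res_null.adj_p[:] = 1.0
        assert count_degs(res_null, 0.9999) == 0

    def test_count_monotone_in_alpha(self):
        rng = np.random.default_rng(14)
        m, design, _ = _two_group(rng, 200, 10)
        fit = fit_genewise(m, design)
        res = moderated_t(fit, estimate_ebayes(fit), "class[case]")
        alphas = np.linspace(0.01, 1.0, 25)
        counts = [count_degs(res, a) for a in alphas]
        assert all(c1 <= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_invalid_alpha_rejected(self):
        rng = np.random.default_rng(15)
        m, design, _ = _two_group(rng, 10, 6)
        fit = fit_genewise(m, design)
        res = moderated_t(fit, estimate_ebayes(fit), "class[case]")
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                count_degs(res, bad)


class TestNullCalibration:
    def test_null_pvalues_uniform_and_fdr_controlled(self):
        """Global-null simulation: raw moderated-t p-values are uniform
        (pooled Kolmogorov-Smirnov) and BH at 0.05 keeps the realized
        false-discovery rate at or under 0.075."""
        rng = np.random.default_rng(21)
        G, n, reps = 10000, 10, 200
        samples = [f"s{i}" for i in range(n)]
        cls = {s: ("case" if i < n // 2 else "control") for i, s in enumerate(samples)}
        design = build_design(samples, class_labels=cls)
        pooled, false_rates = [], []
        for _ in range(reps):
            y = 8 + rng.normal(0, 1, size=(G, n))
            m = ExpressionMatrix([f"p{i}" for i in range(G)], samples, y)
            fit = fit_genewise(m, design)
            res = moderated_t(fit, estimate_ebayes(fit), "class[case]")
            pooled.append(res.p_value[:100])
            rejected = count_degs(res, 0.05)
            false_rates.append(1.0 if rejected > 0 else 0.0)  # every rejection is false
        ks_p = stats.kstest(np.concatenate(pooled), "uniform").pvalue
        assert ks_p > 0.01
        assert np.mean(false_rates) <= 0.075
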