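"""Mixed-model fits, tests, standardization and the Gibbs sampler."""

import numpy as np
import pandas as pd
import pytest

from mutcov import synthetic, varcomp
from mutcov.synthetic import TRAIT_COLS
from mutcov.varcomp import (
    fit_multivariate,
    fit_univariate_lmm,
    levene_test,
    lrt,
    m_matrix,
    mutational_bias_analysis,
    randomized_null_matrices,
    standardize,
)


class TestStandardize:
    def test_postconditions_exact(self, small_ma_table):
        out = standardize(small_ma_table)
        vals = out[list(TRAIT_COLS)].to_numpy()
        assert np.abs(vals.mean(axis=0)).max() < 1e-12
        assert abs(vals.std(axis=0, ddof=1).mean() - 1.0) < 1e-12

    def test_idempotent_up_to_recentering(self, small_ma_table):
        once = standardize(small_ma_table)
        twice = standardize(once)
        a = once[list(TRAIT_COLS)].to_numpy()
        b = twice[list(TRAIT_COLS)].to_numpy()
        assert np.allclose(a, b, atol=1e-10)

    def test_common_scalar_divisor_preserves_relative_spread(self, rng):
        # traits with SDs (2, 2, ..., 2) -> standardized SDs all 1;
        # unequal SDs keep their ratios
        n = 400
        df = pd.DataFrame(
            {c: rng.normal(0, 2.0, n) for c in TRAIT_COLS}
        )
        out = standardize(df)
        sds = out[list(TRAIT_COLS)].to_numpy().std(axis=0, ddof=1)
        assert np.allclose(sds, 1.0, atol=0.1)
        df2 = df.copy()
        df2[TRAIT_COLS[0]] *= 3.0
        out2 = standardize(df2)
        sds2 = out2[list(TRAIT_COLS)].to_numpy().std(axis=0, ddof=1)
        assert abs(sds2.mean() - 1.0) < 1e-12
        assert sds2[0] / sds2[1] == pytest.approx(3.0, rel=0.05)

    def test_zero_spread_rejected(self):
        df = pd.DataFrame({c: [1.0, 1.0, 1.0] for c in TRAIT_COLS})
        with pytest.raises(ValueError, match="standard deviation"):
            standardize(df)


class TestUnivariateLmm:
    def test_reml_matches_balanced_anova_closed_form(self):
        """One random effect, balanced design: REML = ANOVA estimators."""
        rng = np.random.default_rng(8)
        n_groups, k = 30, 4
        group_eff = rng.normal(0, np.sqrt(0.5), n_groups)
        y = np.repeat(group_eff, k) + rng.normal(0, np.sqrt(0.3), n_groups * k)
        df = pd.DataFrame(
            {
                "ln_SF": y,
                "line_id": np.repeat([f"L{i}" for i in range(n_groups)], k),
                "block_id": "B0",
            }
        )
        fit = fit_univariate_lmm(
            df, "ln_SF", fixed_effects=(), random_effects=("line",), method="REML"
        )
        ybar = y.reshape(n_groups, k).mean(axis=1)
        msb = k * ybar.var(ddof=1)
        msw = (y.reshape(n_groups, k) - ybar[:, None]).ravel() @ (
            y.reshape(n_groups, k) - ybar[:, None]
        ).ravel() / (n_groups * (k - 1))
        assert fit.varcomps["residual"] == pytest.approx(msw, abs=1e-6)
        assert fit.varcomps["line"] == pytest.approx((msb - msw) / k, abs=1e-6)

    def test_matches_statsmodels_crossed_fit(self, small_ma_table):
        """Independent oracle: statsmodels MixedLM with variance components."""
        smf = pytest.importorskip("statsmodels.formula.api")
        fit = fit_univariate_lmm(
            small_ma_table, "ln_SB", ("background", "ma"), method="REML"
        )
        df = small_ma_table.copy()
        df["g"] = 1
        df["ma"] = (df.ma_status == "MA").astype(float)
        df["bg"] = (df.genotype == "PB306").astype(float)
        sm_fit = smf.mixedlm(
            "ln_SB ~ bg + ma",
            df,
            groups="g",
            vc_formula={"line": "0 + C(line_id)", "block": "0 + C(block_id)"},
        ).fit(reml=True)
        assert fit.log_lik == pytest.approx(sm_fit.llf, abs=1e-3)
        assert fit.coef("background")[0] == pytest.approx(sm_fit.params["bg"], abs=1e-4)
        assert fit.coef("ma")[0] == pytest.approx(sm_fit.params["ma"], abs=1e-4)
        assert fit.varcomps["residual"] == pytest.approx(sm_fit.scale, rel=1e-3)

    def test_recovers_background_effect_within_3_se(self):
        """Generating background difference of 0.44 on SF is recovered."""
        delta = np.zeros(6)
        delta[0] = 0.44
        designs = synthetic.default_designs(delta_background=delta)
        table = synthetic.simulate_ma_experiment(designs, np.random.default_rng(12))
        fit = fit_univariate_lmm(table, "ln_SF", ("background", "ma"), method="ML")
        est, se = fit.coef("background")
        assert abs(est - 0.44) < 3 * se

    def test_missing_cell_named_in_error(self, small_ma_table):
        broken = small_ma_table[
            ~(
                (small_ma_table.genotype == "PB306")
                & (small_ma_table.ma_status == "ancestor")
            )
        ]
        with pytest.raises(ValueError, match="design cell missing"):
            fit_univariate_lmm(broken, "ln_SF", ("background", "ma", "interaction"))

    def test_zero_variance_generator_boundary(self):
        design = synthetic.single_group_design(
            n_lines=30, n_blocks=5, true_M=np.zeros((6, 6)), block_scale=0.0
        )
        table = synthetic.simulate_phenotypes(design, np.random.default_rng(9))
        fit = fit_univariate_lmm(table, "ln_FB", fixed_effects=(), method="REML")
        assert fit.varcomps["line"] < 0.02
        assert fit.varcomps["block"] < 0.02


class TestLrt:
    def test_identical_models_give_zero_statistic(self, small_ma_table):
        fit = fit_univariate_lmm(small_ma_table, "ln_SF", ("background",))
        stat, p = lrt(fit, fit)
        assert stat == 0.0
        assert p == 1.0

    def test_reml_fits_rejected(self, small_ma_table):
        full = fit_univariate_lmm(small_ma_table, "ln_SF", ("background", "ma"), method="REML")
        red = fit_univariate_lmm(small_ma_table, "ln_SF", ("background",), method="REML")
        with pytest.raises(ValueError, match="ML"):
            lrt(full, red)

    def test_statistic_nonnegative_and_nesting_enforced(self, small_ma_table):
        full = fit_univariate_lmm(small_ma_table, "ln_SF", ("background", "ma"))
        red = fit_univariate_lmm(small_ma_table, "ln_SF", ("background",))
        stat, p = lrt(full, red)
        assert stat >= 0.0
        assert 0.0 <= p <= 1.0
        with pytest.raises(ValueError, match="nested"):
            lrt(red, fit_univariate_lmm(small_ma_table, "ln_SF", ("ma",)))


class TestLevene:
    def test_equal_spread_groups_give_zero_statistic(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.concatenate([a, a + 10.0])
        stat, p = levene_test(values, ["g1"] * 4 + ["g2"] * 4)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p > 0.99

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            levene_test(np.arange(5.0), ["g"] * 5)

    def test_power_against_fourfold_variance_ratio(self):
        rng = np.random.default_rng(15)
        rejections = 0
        for _ in range(50):
            a = rng.normal(0, 1.0, 50)
            b = rng.normal(0, 2.0, 50)
            _, p = levene_test(np.concatenate([a, b]), ["a"] * 50 + ["b"] * 50)
            rejections += p < 0.05
        assert rejections / 50 > 0.8


@pytest.fixture(scope="module")
def bias_report():
    delta = np.zeros(6)
    delta[0] = 0.44
    beta = np.zeros(6)
    beta[2] = 0.188
    designs = synthetic.default_designs(
        n_ma_lines=(20, 22), n_blocks=8, delta_background=delta, beta_ma=beta
    )
    table = synthetic.simulate_ma_experiment(designs, np.random.default_rng(21))
    return mutational_bias_analysis(table)


class TestMutationalBias:
    def test_report_shape_and_columns(self, bias_report):
        assert len(bias_report) == 6
        for col in (
            "background_effect",
            "background_se",
            "background_p",
            "bias_effect",
            "bias_se",
            "bias_p",
            "levene_p",
        ):
            assert col in bias_report.columns

    def test_null_interactions_dropped(self, bias_report):
        # generator has no interaction effect on any trait
        assert bias_report["interaction_dropped"].sum() >= 5

    def test_injected_effects_recovered(self, bias_report):
        sf = bias_report[bias_report.trait == "ln_SF"].iloc[0]
        assert abs(sf.background_effect - 0.44) < 3 * sf.background_se
        fs = bias_report[bias_report.trait == "ln_FS"].iloc[0]
        assert abs(fs.bias_effect - 0.188) < 3 * fs.bias_se

    def test_null_effects_not_significant(self, bias_report):
        # traits without generating effects should rarely reject
        null_bias = bias_report[bias_report.trait != "ln_FS"]["bias_p"]
        assert (null_bias > 0.05).sum() >= 4


@pytest.fixture(scope="module")
def recovery_fit():
    design = synthetic.single_group_design(n_lines=60, n_blocks=8)
    table = synthetic.simulate_phenotypes(design, np.random.default_rng(30))
    post = fit_multivariate(
        table, n_iter=4000, burnin=800, thin=10, rng=np.random.default_rng(31)
    )
    return design, post


class TestMultivariateGibbs:
    def test_fixed_seed_reproduces_chain(self, recovery_fit):
        design, post = recovery_fit
        table = synthetic.simulate_phenotypes(design, np.random.default_rng(30))
        again = fit_multivariate(
            table, n_iter=4000, burnin=800, thin=10, rng=np.random.default_rng(31)
        )
        assert np.array_equal(post.line, again.line)
        assert np.array_equal(post.residual, again.residual)

    def test_posterior_samples_positive_definite(self, recovery_fit):
        _, post = recovery_fit
        for arr in (post.line, post.block, post.residual):
            eigs = np.linalg.eigvalsh(arr)
            assert eigs.min() > 0

    def test_line_covariance_recovered(self, recovery_fit):
        design, post = recovery_fit
        M_est = 0.5 * post.mean_line()
        true = design.true_M
        assert np.trace(M_est) == pytest.approx(np.trace(true), rel=0.35)
        # residual covariance tracks truth at the trace level
        assert np.trace(post.residual.mean(axis=0)) == pytest.approx(
            np.trace(design.true_residual_cov), rel=0.3
        )

    def test_zero_signal_line_variance_shrinks(self):
        # six plates per line so the line component is well identified;
        # the posterior then concentrates near zero relative to residual
        design = synthetic.single_group_design(
            n_lines=50, n_blocks=8, plates_per_line=6, true_M=np.zeros((6, 6))
        )
        table = synthetic.simulate_phenotypes(design, np.random.default_rng(33))
        post = fit_multivariate(
            table, n_iter=3000, burnin=600, thin=10, rng=np.random.default_rng(34)
        )
        line_var = np.diag(post.line.mean(axis=0))
        resid_var = np.diag(post.residual.mean(axis=0))
        assert np.all(line_var < 0.2 * resid_var)

    def test_sample_count_and_autocorr_reported(self, recovery_fit):
        _, post = recovery_fit
        assert post.n_samples == (4000 - 800) // 10
        ac = post.autocorrelation("line", lag=1)
        assert 0.0 <= ac <= 1.0

    def test_too_few_lines_rejected(self, small_ma_table):
        tiny = small_ma_table[small_ma_table.line_id.isin(
            small_ma_table.line_id.unique()[:3]
        )]
        with pytest.raises(ValueError, match="lines"):
            fit_multivariate(tiny, n_iter=100, burnin=10, thin=1)

    def test_non_pd_prior_scale_rejected(self, small_ma_table):
        ma = small_ma_table[small_ma_table.ma_status == "MA"]
        with pytest.raises(ValueError, match="positive definite"):
            fit_multivariate(
                ma, n_iter=100, burnin=10, thin=1, prior_scale=np.zeros((6, 6))
            )


class TestMMatrix:
    def test_half_line_covariance(self, recovery_posterior=None):
        post = varcomp.MatrixPosterior(
            line=np.stack([np.eye(6), 4 * np.eye(6)]),
            block=np.stack([np.eye(6)] * 2),
            residual=np.stack([np.eye(6)] * 2),
            n_iter=2,
            burnin=0,
            thin=1,
        )
        m = m_matrix(post)
        assert np.allclose(m[0], 0.5 * np.eye(6))
        assert np.allclose(np.trace(m[1]), 0.5 * np.trace(post.line[1]))


class TestRandomizedNull:
    def test_null_destroys_line_structure(self):
        design = synthetic.single_group_design(n_lines=40, n_blocks=6)
        table = synthetic.simulate_phenotypes(design, np.random.default_rng(40))
        rng = np.random.default_rng(41)
        nulls = randomized_null_matrices(
            table, n_rand=12, rng=rng, n_iter=800, burnin=200, thin=10
        )
        assert nulls.shape == (12, 6, 6)
        # permutation removes line signal: null mean off-diagonals near zero
        mean_null = nulls.mean(axis=0)
        off = mean_null[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 0.02
        # and the observed trace exceeds the null 95% band (strong signal)
        post = fit_multivariate(
            table, n_iter=3000, burnin=600, thin=10, rng=np.random.default_rng(42)
        )
        observed = np.trace(0.5 * post.mean_line())
        null_traces = np.trace(nulls, axis1=1, axis2=2)
        assert observed > np.quantile(null_traces, 0.975)
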