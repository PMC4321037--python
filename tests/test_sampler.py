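import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import ndtr

import tgblup as tg
from tgblup.sampler import GibbsSampler, build_model, default_priors
from helpers import batch_means_se, make_pheno, naive_threshold_gibbs


def bare_spec(pheno, blocks=("E",), kernels=None):
    """ModelSpec built directly (e.g. fixed-effects-only, for oracle checks)."""
    inc = tg.build_incidence(pheno)
    return tg.ModelSpec(None, tuple(blocks), kernels or {}, inc)


class TestModelCatalogue:
    @pytest.mark.parametrize(
        "model_id, expected",
        [
            (1, {"E", "L"}),
            (2, {"E", "G"}),
            (3, {"E", "G", "GxG"}),
            (4, {"E", "L", "G"}),
            (5, {"E", "L", "G", "GxG"}),
            (6, {"E", "G", "GxE"}),
            (7, {"E", "G", "GxG", "GxE", "GxGxE"}),
            (8, {"E", "L", "G", "GxE"}),
            (9, {"E", "L", "G", "GxG", "GxE", "GxGxE"}),
        ],
    )
    def test_blocks_per_model(self, model_id, expected):
        pheno = make_pheno(["E1", "E1"], ["L1", "L2"], [1, 2])
        inc = tg.build_incidence(pheno)
        G = tg.identity_kernel(inc.line_ids, name="G")
        GA = tg.identity_kernel(inc.line_ids, name="GA")
        spec = build_model(model_id, {"G": G, "GA": GA}, inc)
        assert set(spec.blocks) == expected

    def test_model_one_needs_no_marker_kernel(self):
        pheno = make_pheno(["E1", "E1"], ["L1", "L2"], [1, 2])
        spec = build_model(1, {}, tg.build_incidence(pheno))
        assert set(spec.blocks) == {"E", "L"}

    def test_invalid_model_id(self):
        pheno = make_pheno(["E1"], ["L1"], [1], C=2)
        with pytest.raises(ValueError, match="1..9"):
            build_model(0, {}, tg.build_incidence(pheno))

    def test_missing_kernel_named(self):
        pheno = make_pheno(["E1", "E1"], ["L1", "L2"], [1, 2])
        inc = tg.build_incidence(pheno)
        with pytest.raises(ValueError, match="GxG.*'GA'"):
            build_model(3, {"G": tg.identity_kernel(inc.line_ids, name="G")}, inc)


class TestDefaultPriors:
    def test_single_block_unit_diagonal(self):
        pheno = make_pheno(["E1", "E1"], ["L1", "L2"], [1, 2])
        spec = bare_spec(pheno, ("E", "G"),
                         {"G": tg.identity_kernel(("L1", "L2"), name="G")})
        priors = default_priors(spec, df=5)
        assert priors.scales["G"] == pytest.approx(7.0)

    def test_two_blocks_split_the_prior_mode(self):
        pheno = make_pheno(["E1", "E1"], ["L1", "L2"], [1, 2])
        spec = bare_spec(pheno, ("E", "L", "G"), {
            "L": tg.identity_kernel(("L1", "L2")),
            "G": tg.identity_kernel(("L1", "L2"), name="G"),
        })
        priors = default_priors(spec, df=5)
        assert priors.scales["L"] == pytest.approx(3.5)
        assert priors.scales["G"] == pytest.approx(3.5)

    def test_mean_diagonal_rescales(self):
        pheno = make_pheno(["E1", "E1"], ["L1", "L2"], [1, 2])
        K = tg.Kernel("G", 2.0 * np.eye(2), "line", ("L1", "L2"))
        priors = default_priors(bare_spec(pheno, ("E", "G"), {"G": K}), df=5)
        assert priors.scales["G"] == pytest.approx(3.5)

    def test_invalid_df(self):
        pheno = make_pheno(["E1"], ["L1"], [1], C=2)
        with pytest.raises(ValueError, match="positive"):
            default_priors(bare_spec(pheno), df=0)


class TestLiabilitySampling:
    def sampler_with_uniform_scores(self, score, C, n=100_000):
        pheno = make_pheno(["E1"] * n, [f"L{i}" for i in range(n)], [score] * n, C=C)
        s = GibbsSampler(pheno, bare_spec(pheno), tg.PriorSpec(), seed=0)
        s.beta[:] = 0.0
        s.eta[:] = 0.0
        return s

    def test_truncated_mean_below_zero_threshold(self):
        # category 1 with predictor 0: E[l | l < 0] = -phi(0)/Phi(0) = -0.7979
        s = self.sampler_with_uniform_scores(score=1, C=2)
        draws = s.sample_liabilities(np.random.default_rng(1))
        assert draws.max() < 0.0
        assert draws.mean() == pytest.approx(-0.7978845608, abs=0.01)

    def test_top_category_exceeds_last_threshold(self):
        s = self.sampler_with_uniform_scores(score=2, C=2, n=1000)
        draws = s.sample_liabilities(np.random.default_rng(2))
        assert draws.min() > 0.0

    def test_fixed_seed_reproduces_draws(self):
        s = self.sampler_with_uniform_scores(score=1, C=2, n=500)
        d1 = s.sample_liabilities(np.random.default_rng(7)).copy()
        d2 = s.sample_liabilities(np.random.default_rng(7)).copy()
        np.testing.assert_array_equal(d1, d2)


class TestThresholdSampling:
    def crafted_sampler(self, scores, liabs, C):
        pheno = make_pheno(["E1"] * len(scores),
                          [f"L{i}" for i in range(len(scores))], scores, C=C)
        s = GibbsSampler(pheno, bare_spec(pheno), tg.PriorSpec(), seed=0)
        s.liab = np.asarray(liabs, dtype=float)
        return s

    def test_uniform_between_adjacent_category_liabilities(self):
        # cat-2 max 0.8, cat-3 min 1.5 -> gamma_2 ~ U(0.8, 1.5)
        s = self.crafted_sampler([1, 2, 2, 3, 3], [-0.5, 0.2, 0.8, 1.5, 2.2], C=3)
        rng = np.random.default_rng(3)
        draws = np.array([s.sample_thresholds(rng)[1] for _ in range(20_000)])
        assert draws.min() > 0.8 and draws.max() < 1.5
        assert draws.mean() == pytest.approx(1.15, abs=0.02)

    def test_binary_case_has_nothing_to_sample(self):
        s = self.crafted_sampler([1, 2], [-0.3, 0.4], C=2)
        gamma = s.sample_thresholds(np.random.default_rng(0))
        np.testing.assert_array_equal(gamma, [0.0])

    def test_empty_category_falls_back_to_neighbours(self):
        # no records in category 3 (C=4): gamma_3 interval is
        # (gamma_2-side bound, min liability of category 4)
        s = self.crafted_sampler([1, 2, 2, 4, 4], [-0.8, 0.2, 0.5, 2.0, 2.4], C=4)
        s.gamma = np.array([0.0, 0.6, 1.8])
        rng = np.random.default_rng(4)
        for _ in range(200):
            gamma = s.sample_thresholds(rng)
            assert 0.5 < gamma[1] < gamma[2] < 2.0
            assert gamma[0] == 0.0


class TestLocationEffects:
    def test_fixed_effect_mean_matches_least_squares(self):
        rng = np.random.default_rng(5)
        n = 200
        pheno = make_pheno(["E1"] * n, [f"L{i}" for i in range(n)],
                          rng.integers(1, 4, n), C=3)
        s = GibbsSampler(pheno, bare_spec(pheno), tg.PriorSpec(), seed=0)
        s.liab = rng.normal(0.7, 1.0, n)
        mean, prec = s.beta_conditional()
        assert mean[0] == pytest.approx(s.liab.mean(), abs=1e-6)
        assert prec[0] == pytest.approx(n + 1e-10)

    def test_block_conditional_mean_matches_ridge_solve(self):
        rng = np.random.default_rng(6)
        J, n = 15, 60
        pheno = make_pheno(rng.choice(["E1", "E2"], n),
                          rng.choice([f"L{j}" for j in range(J)], n),
                          rng.integers(1, 4, n), C=3)
        spec = build_model(1, {}, tg.build_incidence(pheno))
        s = GibbsSampler(pheno, spec, default_priors(spec), seed=0)
        s.liab = rng.normal(size=pheno.n_records)
        s.sigma2["L"] = 0.7
        got = s.block_conditional_mean("L")
        Z = spec.inc.Z_L
        resid = s.liab - s.beta[spec.inc.env_codes]
        expected = np.linalg.solve(Z.T @ Z + np.eye(Z.shape[1]) / 0.7, Z.T @ resid)
        np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_zero_variance_block_shrinks_to_nothing(self):
        rng = np.random.default_rng(8)
        n = 40
        pheno = make_pheno(["E1"] * n, [f"L{j % 10}" for j in range(n)],
                          rng.integers(1, 4, n), C=3)
        spec = build_model(1, {}, tg.build_incidence(pheno))
        s = GibbsSampler(pheno, spec, default_priors(spec), seed=0)
        s.sigma2["L"] = 1e-12
        s.sample_location_effects(np.random.default_rng(9))
        assert np.abs(s.blocks["L"].line_effects()).max() < 1e-4


class TestVarianceSampling:
    def fresh_sampler(self, J=20):
        pheno = make_pheno(["E1"] * J, [f"L{j}" for j in range(J)],
                          np.random.default_rng(0).integers(1, 4, J), C=3)
        spec = build_model(1, {}, tg.build_incidence(pheno))
        return GibbsSampler(pheno, spec, default_priors(spec), seed=0)

    def test_prior_draw_mean_with_zero_effects(self):
        s = self.fresh_sampler()
        for seg in s.blocks["L"].segments:
            seg.u = np.zeros_like(seg.u)
        S, df, q = s.priors.scales["L"], s.priors.df, s.blocks["L"].dimension
        rng = np.random.default_rng(10)
        draws = np.array([s.sample_variances(rng)["L"] for _ in range(20_000)])
        assert draws.mean() == pytest.approx(S / (df + q - 2), rel=0.02)

    def test_posterior_concentration_with_unit_sum_of_squares(self):
        s = self.fresh_sampler()
        q = s.blocks["L"].dimension
        for seg in s.blocks["L"].segments:
            seg.u = np.ones_like(seg.u)  # SS = q
        S, df = s.priors.scales["L"], s.priors.df
        rng = np.random.default_rng(11)
        draws = np.array([s.sample_variances(rng)["L"] for _ in range(20_000)])
        assert draws.mean() == pytest.approx((S + q) / (df + q - 2), rel=0.02)

    def test_residual_variance_never_sampled(self, small_model2_fit):
        assert small_model2_fit.priors.residual_variance == 1.0
        with pytest.raises(ValueError, match="identifiability"):
            tg.PriorSpec(residual_variance=0.5)


class TestRunGibbs:
    def test_no_retained_draws_is_an_error(self):
        with pytest.raises(ValueError, match="retain"):
            tg.GibbsSettings(iterations=101, burnin=100, thin=5)
        with pytest.raises(ValueError, match="exceed"):
            tg.GibbsSettings(iterations=100, burnin=100)

    def test_chain_invariants_hold_at_every_retained_draw(self, small_model2_fit):
        gamma = small_model2_fit.draws["gamma"]
        np.testing.assert_array_equal(gamma[:, 0], 0.0)
        assert np.all(np.diff(gamma, axis=1) > 0)
        assert np.all(small_model2_fit.draws["sigma2_G"] > 0)
        assert small_model2_fit.summary.n_draws == (1500 - 500) // 2

    def test_liabilities_stay_inside_category_intervals(self, small_model2_data):
        pheno, geno, _ = small_model2_data
        kernels = tg.prepare_kernels(geno, 2)
        inc = tg.build_incidence(pheno, kernels["G"].ids)
        spec = build_model(2, kernels, inc)
        s = GibbsSampler(pheno, spec, default_priors(spec), seed=13)
        for _ in range(25):
            s.step()
            gf = s.gamma_full
            assert np.all(s.liab > gf[s.y - 1])
            assert np.all(s.liab < gf[s.y])

    def test_same_seed_reproduces_chain(self, small_model2_data):
        pheno, geno, _ = small_model2_data
        settings = tg.GibbsSettings(300, 100, 2, seed=3)
        r1 = tg.fit(pheno, geno, 2, settings)
        r2 = tg.fit(pheno, geno, 2, settings)
        np.testing.assert_array_equal(r1.draws["sigma2_G"], r2.draws["sigma2_G"])
        np.testing.assert_array_equal(r1.draws["beta"], r2.draws["beta"])

    def test_binary_intercept_matches_probit_map_oracle(self):
        # C=2, one environment, no random effects: the posterior mean of beta
        # should match the MAP probit intercept from direct optimization.
        rng = np.random.default_rng(14)
        n, beta_true = 500, 0.4
        y = (rng.normal(beta_true, 1.0, n) > 0.0).astype(int) + 1
        pheno = make_pheno(["E1"] * n, [f"L{i}" for i in range(n)], y, C=2)
        result = tg.run_gibbs(pheno, bare_spec(pheno), tg.PriorSpec(),
                              tg.GibbsSettings(4000, 1000, 2, seed=15))

        def neg_log_post(b):
            p2 = ndtr(b)
            n2 = (y == 2).sum()
            return -(n2 * np.log(p2) + (n - n2) * np.log1p(-p2)) + b**2 / 2e10

        map_est = minimize_scalar(neg_log_post, bounds=(-3, 3), method="bounded").x
        assert result.summary.mean("beta_E1") == pytest.approx(map_est, abs=0.05)

    def test_independent_chains_agree(self, small_model2_data):
        pheno, geno, _ = small_model2_data
        means, ses = [], []
        for seed in (31, 32):
            r = tg.fit(pheno, geno, 2, tg.GibbsSettings(6000, 1000, 1, seed=seed))
            means.append(r.summary.mean("sigma2_G"))
            ses.append(batch_means_se(r.draws["sigma2_G"]))
        tol = 3.0 * np.hypot(*ses)
        assert abs(means[0] - means[1]) <= tol

    def test_matches_independent_naive_implementation(self):
        # two-implementation oracle: an explicitly-inverted, scipy-truncnorm
        # Gibbs sampler should reach the same posterior for model 2
        geno = tg.simulate_genotypes(20, 60, (0.1, 0.9), seed=41)
        config = tg.SimulationConfig(
            n_lines=20, n_envs=2, n_markers=60, categories=3,
            beta=(0.4, 0.1), variances={"G": 0.5}, thresholds=(0.0, 1.0),
            replicates=3, seed=42,
        )
        pheno, _ = tg.simulate_dataset(config, geno)
        fast = tg.fit(pheno, geno, 2, tg.GibbsSettings(20_000, 3_000, 1, seed=43))

        kernels = tg.prepare_kernels(geno, 2)
        G = kernels["G"]
        line_codes = np.array([G.ids.index(l) for l in pheno.records["line"]])
        s2, g2 = naive_threshold_gibbs(
            pheno.score, pheno.env_index, line_codes, G.matrix, C=3,
            iters=8_000, burnin=2_000, seed=44,
        )
        for fast_draws, naive_draws in (
            (fast.draws["sigma2_G"], s2),
            (fast.draws["gamma"][:, 1], g2),
        ):
            tol = 4.0 * np.hypot(batch_means_se(fast_draws), batch_means_se(naive_draws))
            assert abs(fast_draws.mean() - naive_draws.mean()) <= max(tol, 0.02)
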