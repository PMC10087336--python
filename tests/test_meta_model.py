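import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tpcmeta import meta_model as mm
from tpcmeta.data_model import normalize_dispersion
from tpcmeta.meta_model import (Design, DesignError, McmcSettings, ModelSpec,
                                PriorSpec, build_design, fit,
                                hotter_is_better_effects, pointwise_loglik,
                                predict_curve, rank_models, summarize, waic)
from tpcmeta.synthetic_data import (SimScenario, simulate_effects_direct,
                                    simulate_experiment)

from conftest import make_assay, make_draws, make_effect

FAST = McmcSettings(iterations=3_000, warmup=750, chains=2)


class TestBuildDesign:
    def test_intercept_only(self, toy_effects):
        spec = ModelSpec("m", random_levels=("species", "study"))
        d = build_design(toy_effects, spec)
        assert d.colnames == ("intercept",)
        assert d.X.shape == (5, 1)
        assert len(d.level_labels["species"]) == 1
        assert d.level_codes["study"].max() == 0

    def test_cubic_gives_four_columns(self, toy_effects):
        spec = ModelSpec("m", fixed_terms=("dt", "dt2", "dt3"))
        d = build_design(toy_effects, spec)
        assert d.colnames == ("intercept", "dT", "dT^2", "dT^3")
        np.testing.assert_allclose(d.X[:, 2], d.X[:, 1] ** 2)
        np.testing.assert_allclose(d.X[:, 3], d.X[:, 1] ** 3)

    def test_gen_on_missing_generations_instructs_reduced_set(self):
        effects = [make_effect(0, gens=None), make_effect(1, gens=50.0)]
        spec = ModelSpec("m", fixed_terms=("gen",))
        with pytest.raises(DesignError, match="reduced data set"):
            build_design(effects, spec)

    def test_requires_positive_ses(self):
        effects = [make_effect(0, se=None)]
        with pytest.raises(DesignError, match="positive SE"):
            build_design(effects, ModelSpec("m"))

    def test_unknown_term_rejected_at_spec(self):
        with pytest.raises(ValueError, match="unknown fixed term"):
            ModelSpec("m", fixed_terms=("banana",))


class TestWaic:
    def test_constant_matrix_has_zero_penalty(self):
        c, n = -1.3, 7
        out = waic(np.full((50, n), c))
        assert out["lppd"] == pytest.approx(n * c)
        assert out["p_waic"] == pytest.approx(0.0, abs=1e-12)
        assert out["waic"] == pytest.approx(-2 * n * c)

    def test_matches_direct_formula_on_small_matrix(self):
        ll = np.array([[-1.0, -2.0], [-1.5, -2.5], [-0.5, -1.5]])
        out = waic(ll)
        lppd = sum(math.log(np.mean(np.exp(ll[:, i]))) for i in range(2))
        p = sum(np.var(ll[:, i], ddof=1) for i in range(2))
        assert out["lppd"] == pytest.approx(lppd)
        assert out["p_waic"] == pytest.approx(p)
        assert out["waic"] == pytest.approx(-2 * (lppd - p))

    def test_invariant_to_effect_ordering(self):
        rng = np.random.default_rng(0)
        ll = rng.normal(-1, 0.3, size=(40, 9))
        perm = rng.permutation(9)
        assert waic(ll)["waic"] == pytest.approx(waic(ll[:, perm])["waic"])

    def test_deterministic_given_draws(self):
        rng = np.random.default_rng(1)
        ll = rng.normal(-2, 0.5, size=(30, 4))
        assert waic(ll) == waic(ll.copy())


class TestPointwiseLoglik:
    def test_degenerate_posterior_closed_form(self):
        draws = make_draws(sigma2=np.zeros((10, 1)),
                           level_names=("study",),
                           u={"study": np.zeros((10, 1))})
        design = Design(y=np.array([0.0]), s=np.array([1.0]),
                        X=np.ones((1, 1)), colnames=("b0",),
                        level_codes={"study": np.array([0])},
                        level_labels={"study": ("s0",)}, centering={})
        ll = pointwise_loglik(draws, design)
        assert ll.shape == (10, 1)
        np.testing.assert_allclose(ll, -0.5 * math.log(2 * math.pi))

    def test_matches_brute_force_normal_density(self, toy_effects):
        spec = ModelSpec("m", fixed_terms=("dt",),
                         random_levels=("study",), mcmc=FAST)
        design = build_design(toy_effects, spec)
        rng = np.random.default_rng(3)
        d = 100
        draws = make_draws(
            sigma2=rng.uniform(0.01, 0.2, (d, 1)),
            beta=rng.normal(0, 0.5, (d, 2)),
            level_names=("study",),
            u={"study": rng.normal(0, 0.3, (d, 1))},
            colnames=design.colnames)
        ll = pointwise_loglik(draws, design)
        for di in range(0, d, 17):
            for i in range(5):
                mu = (design.X[i] @ draws.beta[di]
                      + draws.u["study"][di, design.level_codes["study"][i]])
                want = stats.norm.logpdf(design.y[i], mu, design.s[i])
                assert ll[di, i] == pytest.approx(want)

    def test_unindexed_level_is_marginalized_into_variance(self, toy_effects):
        spec = ModelSpec("m", random_levels=("study",))
        design = build_design(toy_effects, spec)
        draws = make_draws(
            sigma2=np.full((5, 2), 0.04),
            beta=np.zeros((5, 1)),
            level_names=("study", "tpc"),
            u={"study": np.zeros((5, 1)), "tpc": np.zeros((5, 3))})
        ll = pointwise_loglik(draws, design)
        want = stats.norm.logpdf(design.y[0], 0.0,
                                 math.sqrt(design.s[0] ** 2 + 0.04))
        assert ll[0, 0] == pytest.approx(want)


class TestRanking:
    def _fit_summary(self, name, w, subset="s", n=10):
        params = pd.DataFrame(columns=["parameter", "median", "q2.5",
                                       "q97.5"])
        return mm.ModelFitSummary(name, params, w, 0.0, 0.0, 0.0, n,
                                  subset, 1.0, True)

    def test_two_model_weights(self):
        df = rank_models([self._fit_summary("a", 100.0),
                          self._fit_summary("b", 102.0)])
        assert list(df["model"]) == ["a", "b"]
        np.testing.assert_allclose(df["delta_waic"], [0.0, 2.0])
        np.testing.assert_allclose(df["weight"], [0.731, 0.269], atol=5e-4)

    def test_single_model_weight_one(self):
        df = rank_models([self._fit_summary("only", 50.0)])
        assert df["weight"].iloc[0] == pytest.approx(1.0)

    def test_mixed_subsets_rejected(self):
        with pytest.raises(ValueError, match="different effect subsets"):
            rank_models([self._fit_summary("a", 1.0, subset="x"),
                         self._fit_summary("b", 2.0, subset="y")])


class TestFit:
    def test_parameter_recovery_on_forty_studies(self):
        """Posterior for the grand mean lands near the simulation truth."""
        effects, truth = simulate_effects_direct(
            mu=0.2, sigma_species=0.0, sigma_study=0.1, n_effects=200,
            n_species=40, n_studies_per_species=1,
            se_range=(0.05, 0.0500001), seed=21)
        spec = ModelSpec("m", random_levels=("study",), mcmc=FAST)
        design = build_design(effects, spec)
        draws = fit(design, spec, seed=4)
        med = np.median(draws.beta[:, 0])
        lo, hi = np.quantile(draws.beta[:, 0], [0.025, 0.975])
        assert abs(med - 0.2) < 0.05
        assert lo < 0.2 < hi

    def test_draw_count_contract(self, toy_effects):
        spec = ModelSpec("m", random_levels=("study",),
                         mcmc=McmcSettings(iterations=400, warmup=100,
                                           chains=3))
        draws = fit(build_design(toy_effects, spec), spec, seed=0)
        assert draws.n_draws == 3 * 300
        assert np.all(draws.sigma2 >= 0)

    def test_reproducible_given_seed(self, toy_effects):
        spec = ModelSpec("m", random_levels=("study",),
                         mcmc=McmcSettings(iterations=500, warmup=100,
                                           chains=2))
        design = build_design(toy_effects, spec)
        a = fit(design, spec, seed=9)
        b = fit(design, spec, seed=9)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.sigma2, b.sigma2)

    def test_measurement_error_shrinkage_direction(self):
        """Posterior true effects sit between the observations and the
        population prediction (normal-normal conjugacy)."""
        # each effect is its own TPC, so theta_i = mu + u_tpc(i) is
        # effect-specific and the conjugacy bound applies pointwise
        effects, _ = simulate_effects_direct(
            mu=0.3, sigma_species=0.0, sigma_study=0.0, sigma_tpc=0.25,
            n_effects=40, n_species=20, se_range=(0.1, 0.100001), seed=5)
        spec = ModelSpec("m", random_levels=("tpc",), mcmc=FAST)
        design = build_design(effects, spec)
        draws = fit(design, spec, seed=2)
        mu_pop = draws.beta[:, 0].mean()
        theta = (draws.beta[:, 0][:, None]
                 + draws.u["tpc"][:, design.level_codes["tpc"]]).mean(
            axis=0)
        slack = 0.01
        for yi, ti in zip(design.y, theta):
            lo, hi = sorted((yi, mu_pop))
            assert lo - slack <= ti <= hi + slack

    def test_prior_dominated_limit(self):
        """With huge SEs the posterior of the mean returns the prior."""
        effects = [make_effect(i, y=0.5 * i, se=1e3, tpc=f"t{i}")
                   for i in range(5)]
        spec = ModelSpec("m", random_levels=("study",),
                         priors=PriorSpec(beta_sd=1.0), mcmc=FAST)
        draws = fit(build_design(effects, spec), spec, seed=1)
        mu = draws.beta[:, 0]
        assert abs(mu.mean()) < 0.1
        assert mu.std() == pytest.approx(1.0, rel=0.1)


class TestPredictCurve:
    def test_intercept_model_predicts_flat_curve(self, toy_effects):
        spec = ModelSpec("m", random_levels=("study",), mcmc=FAST)
        design = build_design(toy_effects, spec)
        draws = fit(design, spec, seed=6)
        curve = predict_curve(draws, design, spec, np.linspace(-5, 5, 7))
        med = np.median(draws.beta[:, 0])
        np.testing.assert_allclose(curve["median"], med)

    def test_moderator_shift_is_exactly_the_var_coefficient(self):
        effects = [make_effect(i, dt=float(d), tpc=f"t{i}",
                               var="de_novo" if i % 2 else "standing")
                   for i, d in enumerate([-4, -2, 0, 2, 4, 6])]
        spec = ModelSpec("m", fixed_terms=("dt", "var"),
                         random_levels=("study",), mcmc=FAST)
        design = build_design(effects, spec)
        draws = fit(design, spec, seed=3)
        grid = np.array([-2.0, 0.0, 2.0])
        a = mm.predict_mu_draws(draws, design, spec, grid,
                                {"variation_source": "de_novo"})
        b = mm.predict_mu_draws(draws, design, spec, grid,
                                {"variation_source": "standing"})
        j = design.colnames.index("var[de_novo]")
        # per-draw, mu differs by exactly the var coefficient
        np.testing.assert_allclose(a - b,
                                   np.broadcast_to(draws.beta[:, j], a.shape),
                                   atol=1e-12)

    def test_extrapolation_flagged(self, toy_effects):
        spec = ModelSpec("m", fixed_terms=("dt",), random_levels=("study",),
                         mcmc=FAST)
        design = build_design(toy_effects, spec)
        draws = fit(design, spec, seed=0)
        curve = predict_curve(draws, design, spec, np.array([0.0, 99.0]))
        assert list(curve["extrapolated"]) == [False, True]


class TestHotterIsBetter:
    def _tpc_rows(self, sel_vals, anc_vals, temps=(20.0, 24.0, 28.0, 32.0),
                  **kw):
        return [make_assay(assay_temp=t, f_sel=s, f_anc=a, **kw)
                for t, s, a in zip(temps, sel_vals, anc_vals)]

    def test_max_vs_max_discrete(self):
        rows = self._tpc_rows([1.1, 1.3, 1.5, 1.2], [1.2, 1.15, 1.0, 0.8],
                              temps=(20.0, 25.0, 30.0, 35.0))
        [e] = hotter_is_better_effects(rows)
        assert e.rel_fitness == pytest.approx(1.5 / 1.2 - 1.0)
        want_se = (1.5 / 1.2) * math.hypot(0.1 / 1.5, 0.1 / 1.2)
        assert e.rel_fitness_se == pytest.approx(want_se)
        assert want_se == pytest.approx(0.1332, abs=2e-4)

    def test_identical_curves_give_zero(self):
        vals = [0.8, 1.0, 1.2, 0.9]
        [e] = hotter_is_better_effects(self._tpc_rows(vals, vals))
        assert e.rel_fitness == 0.0

    def test_tie_takes_lowest_temperature(self):
        rows = [make_assay(assay_temp=t, f_sel=s, f_anc=1.0,
                           disp_sel=d, disp_anc=0.1)
                for t, s, d in [(20.0, 1.5, 0.03), (24.0, 1.5, 0.4),
                                (28.0, 1.0, 0.1), (32.0, 0.9, 0.1)]]
        [e] = hotter_is_better_effects(rows)
        want = 1.5 * math.hypot(0.03 / 1.5, 0.1 / 1.0)
        assert e.rel_fitness_se == pytest.approx(want)

    def test_three_temperature_tpcs_skipped(self):
        rows = self._tpc_rows([1.0, 1.1, 1.2], [1.0, 1.0, 1.0],
                              temps=(20.0, 25.0, 30.0))
        assert hotter_is_better_effects(rows) == []

    def test_hb_scenario_yields_positive_mean_effect(self):
        records = [normalize_dispersion(r) for r in simulate_experiment(
            SimScenario(scenario="hotter_is_better", seed=17,
                        n_species=10))]
        effects = hotter_is_better_effects(records)
        assert len(effects) >= 20
        assert np.mean([e.rel_fitness for e in effects]) > 0
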