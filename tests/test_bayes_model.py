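"""Design coding, the Kuo-Mallick sampler, and Bayes-factor mechanics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from pps.bayes import (BayesGLMM, MCMCSettings, ModelFit, ModelSpec,
                       PriorSpec, build_design, fit, posterior_mode,
                       term_matrix)


class TestDesign:
    def test_sum_to_zero_coding(self):
        df = pd.DataFrame({"f": ["a", "b", "c", "a", "b", "c"]})
        X, names = term_matrix(df, "f")
        assert X.shape == (6, 2)
        assert np.allclose(X.sum(axis=0), 0.0)  # balanced -> columns sum 0
        assert names == ["f[a]", "f[b]"]

    def test_interaction_is_columnwise_product(self):
        df = pd.DataFrame({"f": ["a", "b"] * 4, "x": np.arange(8.0)})
        Xf, _ = term_matrix(df, "f")
        Xi, _ = term_matrix(df, "f:x")
        assert np.allclose(Xi[:, 0], Xf[:, 0] * df["x"])

    def test_unknown_level_rejected(self):
        df = pd.DataFrame({"f": ["a", "b"]})
        with pytest.raises(ValueError):
            term_matrix(df, "f", levels={"f": ["a", "c"]})

    def test_intercept_term(self):
        df = pd.DataFrame({"x": [1.0, 2.0]})
        d = build_design(df, ["1", "x"])
        assert d.colnames == ["(Intercept)", "x"]
        assert np.allclose(d.X[:, 0], 1.0)


def _toy_fit(gamma_a, gamma_b, inclusion_prob=0.5):
    """Hand-built ModelFit with two selectable terms."""
    spec = ModelSpec(response="y", forced=("1",), selectable=("a", "b"),
                     priors=PriorSpec(inclusion_prob=inclusion_prob))
    C, T = gamma_a.shape
    gamma = np.stack([gamma_a, gamma_b], axis=-1).astype(np.int8)
    return ModelFit(spec=spec, settings=MCMCSettings.test_scale(),
                    beta=np.zeros((C, T, 3)), gamma=gamma,
                    sigma=np.ones((C, T)), sd_rand=np.zeros((C, T, 0)),
                    colnames=["(Intercept)", "a", "b"],
                    term_slices={"1": slice(0, 1), "a": slice(1, 2),
                                 "b": slice(2, 3)},
                    forced_terms=["1"], selectable_terms=["a", "b"],
                    rand_colnames=[], levels={}, y_offset=0.0,
                    n_obs=10, n_groups=0)


class TestBayesFactor:
    def test_indifference_gives_bf_one(self):
        rng = np.random.default_rng(0)
        g = (np.arange(4000).reshape(2, 2000) % 2).astype(float)
        f = _toy_fit(g, g)
        assert f.bayes_factor("a").bf10 == pytest.approx(1.0)

    def test_bf_invariant_to_other_terms(self):
        rng = np.random.default_rng(1)
        ga = (rng.uniform(size=(2, 2000)) < 0.8).astype(float)
        gb1 = (rng.uniform(size=(2, 2000)) < 0.3).astype(float)
        gb2 = (rng.uniform(size=(2, 2000)) < 0.9).astype(float)
        bf1 = _toy_fit(ga, gb1).bayes_factor("a").bf10
        bf2 = _toy_fit(ga, gb2).bayes_factor("a").bf10
        assert bf1 == bf2

    def test_constant_indicator_reported_as_bound(self):
        g1 = np.ones((2, 2000))
        r = _toy_fit(g1, g1).bayes_factor("a")
        assert r.bound == ">"
        assert r.bf10 == 4000.0
        r0 = _toy_fit(1 - g1, g1).bayes_factor("a")
        assert r0.bound == "<"

    def test_prior_odds_enter_the_bf(self):
        g = (np.arange(4000).reshape(2, 2000) % 2).astype(float)
        r = _toy_fit(g, g, inclusion_prob=0.2).bayes_factor("a")
        # posterior odds 1 against prior odds 0.25 -> BF 4
        assert r.bf10 == pytest.approx(4.0)

    def test_unknown_term_rejected(self):
        g = np.ones((2, 200))
        with pytest.raises(KeyError):
            _toy_fit(g, g).bayes_factor("zzz")


class TestSampler:
    def test_retained_draw_count_matches_settings(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"y": rng.standard_normal(15),
                           "x": rng.standard_normal(15)})
        spec = ModelSpec(response="y", forced=("1", "x"))
        f = fit(spec, df, MCMCSettings(n_chains=3, n_iter=500, n_burnin=50,
                                       n_adapt=50, seed=0))
        assert f.beta.shape == (3, 500, 2)
        assert f.settings.total_draws == 1500
        # the full-scale profile retains 5 x 15000 draws
        assert MCMCSettings().total_draws == 75_000

    def test_exact_fit_limit_recovers_slope(self):
        x = np.linspace(-2, 2, 40)
        df = pd.DataFrame({"y": 3.0 * x, "x": x})
        spec = ModelSpec(response="y", forced=("1", "x"),
                         priors=PriorSpec(sigma_fixed=0.01,
                                          effect_scale=10.0))
        f = fit(spec, df, MCMCSettings.test_scale(seed=0))
        mo = posterior_mode(f.term_coef_draws("x").ravel())
        assert mo == pytest.approx(3.0, abs=0.02)

    def test_seeded_determinism(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": rng.standard_normal(30),
                           "x": rng.standard_normal(30),
                           "g": list("ababab") * 5})
        spec = ModelSpec(response="y", forced=("1",), selectable=("x",),
                         random_slopes=("1",), group="g")
        s = MCMCSettings(n_chains=2, n_iter=300, n_burnin=50, n_adapt=50,
                         seed=9)
        f1, f2 = fit(spec, df, s), fit(spec, df, s)
        assert np.array_equal(f1.beta, f2.beta)
        assert np.array_equal(f1.gamma, f2.gamma)
        assert np.array_equal(f1.sigma, f2.sigma)

    def test_rank_deficient_forced_design_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "x": [1.0, 1.0, 1.0]})
        spec = ModelSpec(response="y", forced=("1", "x"))
        with pytest.raises(ValueError, match="rank"):
            fit(spec, df, MCMCSettings.test_scale())

    def test_nonfinite_response_rejected(self):
        df = pd.DataFrame({"y": [1.0, np.nan], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="finite"):
            fit(ModelSpec(response="y", forced=("1",)), df,
                MCMCSettings.test_scale())

    def test_binomial_response_must_be_binary(self):
        df = pd.DataFrame({"y": [0.0, 0.5], "x": [0.0, 1.0]})
        with pytest.raises(ValueError, match="0/1"):
            fit(ModelSpec(response="y", forced=("1",), family="binomial"),
                df, MCMCSettings.test_scale())


class TestConjugateOracle:
    def test_km_bf_matches_analytic_marginal_ratio(self):
        rng = np.random.default_rng(7)
        n = 20
        x = rng.standard_normal(n)
        y = 0.45 * x + rng.standard_normal(n)
        sdy = np.std(y, ddof=1)
        spec = ModelSpec(response="y", forced=(), selectable=("x",),
                         priors=PriorSpec(effect_scale=1.0 / sdy,
                                          sigma_fixed=1.0))
        df = pd.DataFrame({"y": y, "x": x})
        f = fit(spec, df, MCMCSettings(n_chains=5, n_iter=4000,
                                       n_burnin=500, n_adapt=500, seed=0))
        r = f.bayes_factor("x")
        yc = y - y.mean()
        m1 = multivariate_normal.logpdf(yc, np.zeros(n),
                                        np.eye(n) + np.outer(x, x))
        m0 = multivariate_normal.logpdf(yc, np.zeros(n), np.eye(n))
        analytic = float(np.exp(m1 - m0))
        assert abs(r.bf10 - analytic) <= 3 * max(r.mc_se, 1e-3)


class TestEstimator:
    def test_sklearn_params_roundtrip(self):
        est = BayesGLMM(response="y", forced=("1", "x"),
                        settings=MCMCSettings.test_scale())
        params = est.get_params()
        est2 = BayesGLMM(**{k: v for k, v in params.items()})
        assert est2.get_params()["response"] == "y"

    def test_fitted_attributes(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"y": rng.standard_normal(25),
                           "x": rng.standard_normal(25)})
        est = BayesGLMM(response="y", forced=("1",), selectable=("x",),
                        settings=MCMCSettings(n_chains=2, n_iter=300,
                                              n_burnin=50, n_adapt=50,
                                              seed=0))
        est.fit(df)
        assert set(est.bf_) == {"x"}
        assert all(v > 0 for v in est.rhat_.values())
        pred = est.predict(df.head(3))
        assert pred.shape == (3,)


class TestSerialization:
    def test_model_spec_json_roundtrip(self):
        spec = ModelSpec(response="cce", forced=("1",),
                         selectable=("group", "group:condition"),
                         random_slopes=("1", "condition"),
                         group="participant",
                         priors=PriorSpec(effect_scale=0.7))
        back = ModelSpec.from_json(spec.to_json())
        assert back == spec

    def test_fit_exports_draws_csv_and_summary_json(self):
        import json
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"y": rng.standard_normal(40),
                           "x": rng.standard_normal(40)})
        spec = ModelSpec(response="y", forced=("1",), selectable=("x",))
        f = fit(spec, df, MCMCSettings(n_chains=2, n_iter=300, n_burnin=50,
                                       n_adapt=50, seed=0))
        frame = f.draws_frame()
        assert len(frame) == 600
        assert {"chain", "iteration", "beta:x", "gamma:x",
                "sigma"} <= set(frame.columns)
        summary = json.loads(f.summary_json())
        assert "x" in summary["bayes_factors"]
        assert "beta:x" in summary["rhat"]
        assert len(summary["hpdi"]["x"]) == 2
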