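"""scikit-learn style estimator facade over the Kuo-Mallick sampler."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .spec import ModelSpec, MCMCSettings, PriorSpec
from . import sampler, diagnostics

__all__ = ["BayesGLMM"]


class BayesGLMM(BaseEstimator):
    """Hierarchical Bayesian GLM with Kuo-Mallick term selection.

    A fit/predict wrapper around :func:`pps.bayes.fit` that composes with
    sklearn tooling (``get_params`` / ``set_params``, cloning). ``fit`` takes
    a single DataFrame containing the response, factors, covariates and the
    grouping column.

    Parameters
    ----------
    response : str
        Response column (finite floats for gaussian, 0/1 for binomial).
    forced, selectable : sequence of str
        Fixed-effect terms, formula-style (``"group:condition"``); selectable
        terms carry an inclusion indicator with prior probability
        ``inclusion_prob``.
    random_slopes : sequence of str
        Per-group random-slope terms; ``"1"`` gives random intercepts.
    group : str
        Grouping (participant) column for the random effects.
    family : {"gaussian", "binomial"}
    effect_scale, inclusion_prob, scale_ratio, sigma_fixed
        Prior hyperparameters, see :class:`pps.bayes.PriorSpec`.
    settings : MCMCSettings, optional
        Chain layout; defaults to the full-scale profile.

    Attributes
    ----------
    fit_ : ModelFit
        Full posterior container (draws, indicators, metadata).
    bf_ : dict[str, BFResult]
        Bayes factor per selectable term.
    rhat_ : dict[str, float]
        Gelman-Rubin diagnostic per monitored parameter.
    """

    def __init__(self, response="y", forced=("1",), selectable=(),
                 random_slopes=(), group=None, family="gaussian",
                 effect_scale=1.0, inclusion_prob=0.5, scale_ratio=1.0,
                 sigma_fixed=None, settings=None):
        self.response = response
        self.forced = forced
        self.selectable = selectable
        self.random_slopes = random_slopes
        self.group = group
        self.family = family
        self.effect_scale = effect_scale
        self.inclusion_prob = inclusion_prob
        self.scale_ratio = scale_ratio
        self.sigma_fixed = sigma_fixed
        self.settings = settings

    def _spec(self) -> ModelSpec:
        return ModelSpec(
            response=self.response, forced=tuple(self.forced),
            selectable=tuple(self.selectable),
            random_slopes=tuple(self.random_slopes), group=self.group,
            family=self.family,
            priors=PriorSpec(effect_scale=self.effect_scale,
                             inclusion_prob=self.inclusion_prob,
                             scale_ratio=self.scale_ratio,
                             sigma_fixed=self.sigma_fixed))

    def fit(self, X: pd.DataFrame, y=None):
        settings = self.settings or MCMCSettings()
        self.fit_ = sampler.fit(self._spec(), X, settings)
        self.bf_ = self.fit_.bayes_factors()
        self.rhat_ = self.fit_.rhat()
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Posterior-mean population-level prediction per row."""
        draws = self.fit_.predict_fixed(X)
        if self.family == "binomial":
            draws = 1.0 / (1.0 + np.exp(-draws))
        return draws.mean(axis=0)

    def predict_draws(self, X: pd.DataFrame) -> np.ndarray:
        return self.fit_.predict_fixed(X)

    def bayes_factor(self, term: str):
        return self.fit_.bayes_factor(term)

    def hpdi(self, term_or_draws, mass=0.99):
        if isinstance(term_or_draws, str):
            draws = self.fit_.term_coef_draws(term_or_draws).ravel()
        else:
            draws = np.asarray(term_or_draws)
        return diagnostics.hpdi(draws, mass)
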