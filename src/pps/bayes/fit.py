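"""Fitted-model container, Bayes factors and posterior summaries."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diagnostics
from .design import build_design

__all__ = ["ModelFit", "BFResult", "bayes_factor"]


@dataclass(frozen=True)
class BFResult:
    """Bayes factor for one selectable term.

    ``bound`` is None for a regular estimate; ``">"`` (``"<"``) marks a
    one-sided bound reported when the indicator never left (never entered)
    the model across all retained draws.
    """

    term: str
    bf10: float
    band: str
    posterior_inclusion: float
    mc_se: float
    bound: str | None = None

    def supports_alternative(self) -> bool:
        return self.bf10 >= 3.0

    def supports_null(self) -> bool:
        return self.bf10 <= 1.0 / 3.0

    def to_dict(self) -> dict:
        return {"term": self.term, "bf10": self.bf10, "band": self.band,
                "posterior_inclusion": self.posterior_inclusion,
                "mc_se": self.mc_se, "bound": self.bound}


@dataclass
class ModelFit:
    """All retained draws plus enough design metadata to predict.

    Arrays are shaped (chains, iterations, ...): ``beta`` over all fixed
    columns (forced first), ``gamma`` over selectable terms (0/1), ``sigma``
    the residual SD (zeros for binomial fits), ``sd_rand`` the random-effect
    SDs.
    """

    spec: object
    settings: object
    beta: np.ndarray
    gamma: np.ndarray
    sigma: np.ndarray
    sd_rand: np.ndarray
    colnames: list
    term_slices: dict
    forced_terms: list
    selectable_terms: list
    rand_colnames: list
    levels: dict
    y_offset: float
    n_obs: int
    n_groups: int
    _rhat_cache: dict = field(default_factory=dict, repr=False)

    # ---- diagnostics ----

    def rhat(self) -> dict:
        """Gelman-Rubin R-hat per monitored parameter."""
        if self._rhat_cache:
            return dict(self._rhat_cache)
        out = {}
        for i, name in enumerate(self.colnames):
            out[f"beta:{name}"] = diagnostics.rhat(self.beta[:, :, i])
        if self.spec.family == "gaussian" and self.sigma.any():
            out["sigma"] = diagnostics.rhat(self.sigma)
        for i, name in enumerate(self.rand_colnames):
            out[f"sd:{name}"] = diagnostics.rhat(self.sd_rand[:, :, i])
        self._rhat_cache.update(out)
        return out

    def convergence_warnings(self) -> list:
        return [name for name, v in self.rhat().items()
                if not diagnostics.rhat_flag(v)]

    # ---- Bayes factors ----

    def bayes_factor(self, term: str) -> BFResult:
        return bayes_factor(self, term)

    def bayes_factors(self) -> dict:
        return {t: bayes_factor(self, t) for t in self.selectable_terms}

    # ---- prediction ----

    def _theta_draws(self) -> np.ndarray:
        """Effective coefficients gamma_j * beta_j, flattened over chains."""
        C, T, p = self.beta.shape
        theta = self.beta.reshape(C * T, p).copy()
        g = self.gamma.reshape(C * T, -1)
        for j, t in enumerate(self.selectable_terms):
            s = self.term_slices[t]
            theta[:, s] *= g[:, j:j + 1]
        return theta

    def predict_fixed(self, newdata: pd.DataFrame) -> np.ndarray:
        """Posterior draws of the population-level linear predictor.

        Selectable terms enter multiplied by their indicator draws, so the
        result is model-averaged. Returns (n_draws, n_rows); on the response
        scale for gaussian models, the logit scale for binomial.
        """
        d = build_design(newdata, self.forced_terms + self.selectable_terms,
                         self.levels)
        eta = self._theta_draws() @ d.X.T
        return eta + self.y_offset

    def term_coef_draws(self, term: str) -> np.ndarray:
        """Draws (n_draws, p_term) of a term's coefficients times indicator."""
        s = self.term_slices[term]
        C, T, _ = self.beta.shape
        out = self.beta[:, :, s].reshape(C * T, -1).copy()
        if term in self.selectable_terms:
            j = self.selectable_terms.index(term)
            out *= self.gamma.reshape(C * T, -1)[:, j:j + 1]
        return out

    # ---- export ----

    def draws_frame(self) -> pd.DataFrame:
        C, T, p = self.beta.shape
        cols = {"chain": np.repeat(np.arange(C), T),
                "iteration": np.tile(np.arange(T), C)}
        flat = self.beta.reshape(C * T, p)
        for i, name in enumerate(self.colnames):
            cols[f"beta:{name}"] = flat[:, i]
        g = self.gamma.reshape(C * T, -1)
        for j, t in enumerate(self.selectable_terms):
            cols[f"gamma:{t}"] = g[:, j]
        if self.spec.family == "gaussian":
            cols["sigma"] = self.sigma.reshape(C * T)
        sr = self.sd_rand.reshape(C * T, -1)
        for i, name in enumerate(self.rand_colnames):
            cols[f"sd:{name}"] = sr[:, i]
        return pd.DataFrame(cols)

    def summary_json(self, hpdi_mass: float = 0.99) -> str:
        bfs = {t: r.to_dict() for t, r in self.bayes_factors().items()}
        C, T, p = self.beta.shape
        flat = self.beta.reshape(C * T, p)
        intervals = {name: diagnostics.hpdi(flat[:, i], hpdi_mass)
                     for i, name in enumerate(self.colnames)}
        return json.dumps({"bayes_factors": bfs, "rhat": self.rhat(),
                           "hpdi": intervals, "hpdi_mass": hpdi_mass,
                           "n_obs": self.n_obs, "n_groups": self.n_groups},
                          indent=1)


def bayes_factor(fit: ModelFit, term: str) -> BFResult:
    """Kuo-Mallick Bayes factor from posterior vs prior inclusion odds.

    BF10 = [p_post / (1 - p_post)] / [p_prior / (1 - p_prior)]. The Monte
    Carlo SE of the inclusion probability is estimated from the spread of
    per-chain inclusion frequencies and propagated by the delta method. When
    the indicator is constant across every retained draw, the BF is reported
    as a one-sided bound at the total number of draws.
    """
    if term not in fit.selectable_terms:
        raise KeyError(f"term {term!r} is not selectable in this model")
    j = fit.selectable_terms.index(term)
    g = fit.gamma[:, :, j].astype(float)
    C, T = g.shape
    total = C * T
    p_post = float(g.mean())
    chain_means = g.mean(axis=1)
    se_p = float(chain_means.std(ddof=1) / np.sqrt(C)) if C > 1 else float(
        g.std(ddof=1) / np.sqrt(T))
    p_prior = fit.spec.priors.inclusion_prob
    prior_odds = p_prior / (1.0 - p_prior)
    if p_post >= 1.0:
        bf = float(total) / prior_odds
        return BFResult(term, bf, diagnostics.raftery_band(bf), p_post,
                        se_p, bound=">")
    if p_post <= 0.0:
        bf = 1.0 / (float(total) * prior_odds)
        return BFResult(term, bf, diagnostics.raftery_band(bf), p_post,
                        se_p, bound="<")
    bf = (p_post / (1.0 - p_post)) / prior_odds
    mc_se = se_p / ((1.0 - p_post) ** 2) / prior_odds
    return BFResult(term, bf, diagnostics.raftery_band(bf), p_post, mc_se)
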