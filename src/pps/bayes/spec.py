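"""Model and sampler configuration objects.

A :class:`ModelSpec` names the response, the fixed-effect terms (split into
*forced* terms that are always in the model and *selectable* terms that carry
a Kuo-Mallick inclusion indicator), the random-slope terms and their grouping
column, and the model family. :class:`MCMCSettings` carries the chain layout;
its defaults are the full-scale profile (5 chains x 15000 retained draws,
2000 burn-in, 2000 adaptation), with :meth:`MCMCSettings.test_scale` as the
cheap profile used throughout the test pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

__all__ = ["PriorSpec", "MCMCSettings", "ModelSpec"]


@dataclass(frozen=True)
class PriorSpec:
    """Prior hyperparameters.

    effect_scale
        Standard deviation of the Normal(0, tau^2) coefficient prior, as a
        multiple of sd(y) for gaussian models and in logit units for binomial
        models.
    inclusion_prob
        Prior inclusion probability of each selectable term's indicator.
    scale_ratio
        Scale A of the half-Cauchy priors on the residual and random-effect
        SDs, as a multiple of sd(y) (gaussian) or absolute (binomial).
    sigma_fixed
        If not None, the residual SD is held at this value instead of being
        sampled (used for conjugate-oracle checks).
    """

    effect_scale: float = 1.0
    inclusion_prob: float = 0.5
    scale_ratio: float = 1.0
    sigma_fixed: float | None = None

    def __post_init__(self):
        if not 0.0 < self.inclusion_prob < 1.0:
            raise ValueError("inclusion_prob must lie strictly in (0, 1)")
        if self.effect_scale <= 0 or self.scale_ratio <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class MCMCSettings:
    n_chains: int = 5
    n_iter: int = 15000
    n_burnin: int = 2000
    n_adapt: int = 2000
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chains", "n_iter", "n_burnin", "n_adapt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def test_scale(cls, seed: int = 0, n_chains: int = 3,
                   n_iter: int = 2000) -> "MCMCSettings":
        """Reduced profile for fast runs (3 chains x 2000 retained draws)."""
        return cls(n_chains=n_chains, n_iter=n_iter, n_burnin=500,
                   n_adapt=500, seed=seed)

    @property
    def total_draws(self) -> int:
        return self.n_chains * self.n_iter


@dataclass(frozen=True)
class ModelSpec:
    response: str
    forced: tuple = ("1",)
    selectable: tuple = ()
    random_slopes: tuple = ()
    group: str | None = None
    family: str = "gaussian"
    priors: PriorSpec = field(default_factory=PriorSpec)
    levels: dict | None = None

    def __post_init__(self):
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.random_slopes and self.group is None:
            raise ValueError("random slopes need a grouping column")
        dup = set(self.forced) & set(self.selectable)
        if dup:
            raise ValueError(f"terms both forced and selectable: {sorted(dup)}")

    def to_json(self) -> str:
        d = asdict(self)
        for k in ("forced", "selectable", "random_slopes"):
            d[k] = list(d[k])
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ModelSpec":
        d = json.loads(text)
        pri = d.pop("priors", None)
        return cls(priors=PriorSpec(**pri) if pri else PriorSpec(),
                   forced=tuple(d.pop("forced", ("1",))),
                   selectable=tuple(d.pop("selectable", ())),
                   random_slopes=tuple(d.pop("random_slopes", ())),
                   **d)
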