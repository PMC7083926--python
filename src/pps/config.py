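"""Pipeline configuration: TOML in, dataclasses out.

The shipped defaults reproduce the emulated study design end to end; every
knob the generator and analyses expose is settable from one file.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path

from .bayes import MCMCSettings
from .synth import CohortConfig, EffectSpec, PhysioGroundTruth

__all__ = ["PipelineConfig", "default_toml"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "pps_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    effects: EffectSpec = field(default_factory=EffectSpec)
    physio_truth: PhysioGroundTruth = field(
        default_factory=PhysioGroundTruth)
    mcmc_profile: str = "test"         # "test" (3 x 2000) or "full" (5 x 15000)
    outlier_scope: str = "global"      # or "participant"
    run_baseline_merge: bool = True
    run_posthocs: bool = True
    run_covariations: bool = True
    run_feedback: bool = True
    skip_audio: bool = True            # audio round-trip is opt-in (heavy)
    cce_amplitude: float = 100.0

    def settings(self, seed_offset: int = 0) -> MCMCSettings:
        if self.mcmc_profile in ("full", "paper"):
            return MCMCSettings(seed=self.seed + seed_offset)
        return MCMCSettings.test_scale(seed=self.seed + seed_offset)

    def config_hash(self) -> str:
        d = _as_jsonable(self)
        d.pop("out_dir", None)  # paths do not affect the science
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_toml(cls, path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        kw = {}
        for key in ("seed", "out_dir", "mcmc_profile", "outlier_scope",
                    "run_baseline_merge", "run_posthocs",
                    "run_covariations", "run_feedback", "skip_audio",
                    "cce_amplitude"):
            if key in raw:
                kw[key] = raw[key]
        seed = kw.get("seed", 0)
        coh = dict(raw.get("cohort", {}))
        coh.setdefault("seed", seed)
        if "groups" in coh:
            coh["groups"] = tuple(coh["groups"])
        if "sessions" in coh:
            coh["sessions"] = tuple(coh["sessions"])
        kw["cohort"] = CohortConfig(**coh)
        eff = dict(raw.get("effects", {}))
        amp = kw.get("cce_amplitude", 100.0)
        if "cce_unilateral" not in eff:
            from .synth import default_unilateral_cce
            eff["cce_unilateral"] = default_unilateral_cce(amp)
        kw["effects"] = EffectSpec(**eff)
        kw["physio_truth"] = PhysioGroundTruth(**raw.get("physio", {}))
        return cls(**kw)


def _as_jsonable(cfg: PipelineConfig) -> dict:
    d = asdict(cfg)
    d["effects"]["cce_unilateral"] = {
        f"{g}.{c}": v for (g, c), v in cfg.effects.cce_unilateral.items()}
    d["effects"]["feedback_p_correct"] = {
        f"{g}.{c}": v for (g, c), v in cfg.effects.feedback_p_correct.items()}
    if isinstance(cfg.effects.cce_bilateral, dict):
        d["effects"]["cce_bilateral"] = {
            f"{g}.{c}": v for (g, c), v in cfg.effects.cce_bilateral.items()}
    return d


def default_toml() -> str:
    """The default configuration, as a commented TOML document."""
    c = PipelineConfig()
    return f"""\
# PPS pipeline configuration (defaults shown)
seed = {c.seed}
out_dir = "{c.out_dir}"
mcmc_profile = "{c.mcmc_profile}"       # "test" = 3 chains x 2000; "full" = 5 x 15000
outlier_scope = "{c.outlier_scope}"     # "global" | "participant"
run_baseline_merge = {str(c.run_baseline_merge).lower()}
run_posthocs = {str(c.run_posthocs).lower()}
run_covariations = {str(c.run_covariations).lower()}
run_feedback = {str(c.run_feedback).lower()}
skip_audio = {str(c.skip_audio).lower()}   # audio rendering + voice-onset round trip is opt-in
cce_amplitude = {c.cce_amplitude}       # planted unilateral CCE (ms) in PPS-present cells

[cohort]
n_per_group = {c.cohort.n_per_group}
trials_baseline = {c.cohort.trials_baseline}
trials_block = {c.cohort.trials_block}
control_rate = {c.cohort.control_rate}

[effects]
base_rt = {c.effects.base_rt}
rt_sd = {c.effects.rt_sd}
error_rate = {c.effects.error_rate}
lapse_rate_control = {c.effects.lapse_rate_control}
participant_cce_sd = {c.effects.participant_cce_sd}

[physio]
scl_range = {c.physio_truth.scl_range}
scl_base = {c.physio_truth.scl_base}
ibi_mean = {c.physio_truth.ibi_mean}
rsa_amplitude = {c.physio_truth.rsa_amplitude}
resp_freq = {c.physio_truth.resp_freq}
sample_rate = {c.physio_truth.sample_rate}
"""
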