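"""The study's concrete statistical analyses.

Everything here works on the crossmodal congruency effect (CCE): for each
participant x block x laterality cell, the mean inverse-efficiency of
incongruent trials minus that of congruent trials. A positive unilateral
CCE that exceeds the bilateral one indexes an intact peripersonal-space
representation. The CCE cells feed hierarchical gaussian models with
Kuo-Mallick term selection; movement verbal feedback feeds a hierarchical
binomial model plus closed-form point-hypothesis Bayes factors (85% vs 50%
correct); physiological, interoceptive and clinical covariates enter as
standardized covariates interacting with Group and Condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import bayes
from .bayes import (ModelSpec, MCMCSettings, PriorSpec, BFResult,
                    posterior_mode, hpdi, raftery_band)
from .errors import DataError, DesignError, InsufficientDataError
from .synth import GROUPS, CONDITIONS

__all__ = [
    "CCE_TERMS", "cce_table", "baseline_equivalence", "fit_cce_model",
    "posthoc_laterality", "cce_analysis", "CCESummary",
    "feedback_analysis", "FeedbackSummary", "point_hypothesis_bf",
    "covary", "CovariationResult",
]

#: the seven selectable fixed terms of the full CCE model
CCE_TERMS = ("group", "condition", "laterality",
             "group:condition", "group:laterality", "condition:laterality",
             "group:condition:laterality")

#: random-slope terms of the full CCE model, grouped by participant
CCE_RANDOM = ("1", "laterality", "condition", "laterality:condition",
              "block_order_z")

HPDI_MASS = 0.99
GATE_BF = 3.0


def _test_settings(settings):
    return settings if settings is not None else MCMCSettings.test_scale()


# ---------------------------------------------------------------------------
# CCE construction

def cce_table(ie: pd.DataFrame, lateralities=("Unilateral", "Bilateral")
              ) -> pd.DataFrame:
    """CCE per participant x session x block x laterality.

    CCE = mean IE over incongruent trials - mean over congruent trials
    within the cell; cells missing either congruency are dropped.
    """
    need = {"participant", "session", "block", "laterality", "congruency",
            "ie"}
    if not need <= set(ie.columns):
        raise DataError(f"IE table lacks columns {sorted(need - set(ie.columns))}")
    sub = ie[ie["laterality"].isin(lateralities)]
    keys = ["participant", "group", "session", "block", "condition",
            "laterality"]
    keys = [k for k in keys if k in sub.columns]
    wide = (sub.groupby(keys + ["congruency"])["ie"].mean()
            .unstack("congruency"))
    wide = wide.reindex(columns=["Incongruent", "Congruent"])
    wide = wide.dropna(subset=["Incongruent", "Congruent"])
    out = wide.reset_index()
    out["cce"] = out["Incongruent"] - out["Congruent"]
    if "block_order_z" in ie.columns:
        z = ie.groupby(["participant", "session", "block"])[
            "block_order_z"].first().reset_index()
        out = out.merge(z, on=["participant", "session", "block"])
    return out.drop(columns=["Incongruent", "Congruent"])


# ---------------------------------------------------------------------------
# baseline vs follow-up

def baseline_equivalence(ie: pd.DataFrame,
                         settings: MCMCSettings | None = None) -> dict:
    """Test whether baseline (block 1) and follow-up (block 8) share one
    PPS representation.

    Fits the CCE model with Laterality, Condition (Baseline/FollowUp) and
    their interaction selectable, random within-subject terms by
    participant, and recommends merging the blocks iff the interaction BF
    supports the null (BF10 <= 1/3).
    """
    sub = ie[ie["block"].isin([1, 8])].copy()
    if not (sub["block"] == 8).any():
        raise DataError("no follow-up (block 8) data: cannot test "
                        "baseline equivalence")
    sub["condition"] = np.where(sub["block"] == 1, "Baseline", "FollowUp")
    cce = cce_table(sub)
    spec = ModelSpec(
        response="cce", forced=("1",),
        selectable=("laterality", "condition", "laterality:condition"),
        random_slopes=("1", "laterality", "condition"),
        group="participant")
    f = bayes.fit(spec, cce, _test_settings(settings))
    bf = f.bayes_factor("laterality:condition")
    return {"fit": f, "interaction_bf": bf,
            "merge_recommended": bool(bf.supports_null())}


# ---------------------------------------------------------------------------
# full CCE model

def _check_design(cce: pd.DataFrame):
    counts = cce.groupby(["group", "condition", "laterality"],
                         observed=True).size()
    groups = sorted(cce["group"].unique())
    conds = sorted(cce["condition"].unique())
    empty = [(g, c, l) for g in groups for c in conds
             for l in ("Unilateral", "Bilateral")
             if (g, c, l) not in counts.index]
    if empty:
        raise DesignError(f"empty design cells: {empty}")


def fit_cce_model(ie: pd.DataFrame, settings: MCMCSettings | None = None):
    """Full CCE model on the merged 5-level Condition factor.

    Selectable fixed terms: Group, Condition, Laterality and all their
    interactions (seven Bayes factors); random slopes for Laterality,
    Condition, their interaction and the standardized block order, grouped
    by participant (dual-session participants keep one id, so their two
    sessions pool).

    Returns ``(fit, {term: BFResult})`` on the CCE cell table.
    """
    cce = cce_table(ie)
    _check_design(cce)
    # factors with a single level (e.g. one-group cohorts) cannot carry
    # fixed terms; drop the terms that involve them
    degenerate = {f for f in ("group", "condition", "laterality")
                  if cce[f].nunique() < 2}
    terms = tuple(t for t in CCE_TERMS
                  if not degenerate & set(t.split(":")))
    random = tuple(t for t in CCE_RANDOM
                   if not degenerate & set(t.split(":")))
    spec = ModelSpec(response="cce", forced=("1",), selectable=terms,
                     random_slopes=random, group="participant")
    f = bayes.fit(spec, cce, _test_settings(settings))
    return f, f.bayes_factors()


def _cell_grid(groups, conds):
    rows = [{"group": g, "condition": c, "laterality": l,
             "block_order_z": 0.0}
            for g in groups for c in conds
            for l in ("Unilateral", "Bilateral")]
    return pd.DataFrame(rows)


def cell_estimates(fit, groups=GROUPS, conds=CONDITIONS) -> pd.DataFrame:
    """Model-averaged posterior CCE per design cell: mode + 99% HPDI (ms)."""
    grid = _cell_grid(groups, conds)
    draws = fit.predict_fixed(grid)
    rows = []
    for i, r in grid.iterrows():
        lo, hi = hpdi(draws[:, i], HPDI_MASS)
        rows.append({"group": r["group"], "condition": r["condition"],
                     "laterality": r["laterality"],
                     "mode": posterior_mode(draws[:, i]),
                     "hpdi_lo": lo, "hpdi_hi": hi})
    return pd.DataFrame(rows)


def posthoc_laterality(ie: pd.DataFrame, group: str, condition: str,
                       settings: MCMCSettings | None = None,
                       full_random: bool = True, min_cells: int = 8) -> dict:
    """Unilateral-vs-Bilateral CCE contrast within one group x condition.

    Refits the CCE model on the subset with Laterality selectable; the
    returned BF tests whether the unilateral CCE differs from the bilateral
    one (the PPS signature). Cell estimates (mode, 99% HPDI, ms) come from
    the same fit.
    """
    cce = cce_table(ie)
    sub = cce[(cce["group"] == group) & (cce["condition"] == condition)]
    if len(sub) < min_cells:
        raise InsufficientDataError(
            f"only {len(sub)} CCE cells for {group}/{condition}")
    random = ("1", "laterality", "block_order_z") if full_random else ("1",)
    spec = ModelSpec(response="cce", forced=("1",),
                     selectable=("laterality",), random_slopes=random,
                     group="participant")
    f = bayes.fit(spec, sub, _test_settings(settings))
    bf = f.bayes_factor("laterality")
    grid = pd.DataFrame([
        {"laterality": l, "block_order_z": 0.0}
        for l in ("Unilateral", "Bilateral")])
    draws = f.predict_fixed(grid)
    est = {}
    for i, l in enumerate(("Unilateral", "Bilateral")):
        lo, hi = hpdi(draws[:, i], HPDI_MASS)
        est[l] = {"mode": posterior_mode(draws[:, i]),
                  "hpdi_lo": lo, "hpdi_hi": hi}
    contrast = draws[:, 0] - draws[:, 1]
    lo, hi = hpdi(contrast, HPDI_MASS)
    return {"fit": f, "bf": bf, "estimates": est,
            "contrast": {"mode": posterior_mode(contrast),
                         "hpdi_lo": lo, "hpdi_hi": hi}}


@dataclass
class CCESummary:
    omnibus: dict
    cells: pd.DataFrame
    contrasts: pd.DataFrame
    rhat: dict = field(default_factory=dict)
    posthoc_gated: bool = True
    fit: object = None  # the omnibus ModelFit; not serialized

    def to_dict(self):
        return {
            "omnibus": {t: r.to_dict() for t, r in self.omnibus.items()},
            "cells": self.cells.to_dict(orient="records"),
            "contrasts": self.contrasts.to_dict(orient="records"),
            "rhat": self.rhat, "posthoc_gated": self.posthoc_gated,
        }


def cce_analysis(ie: pd.DataFrame, settings: MCMCSettings | None = None,
                 posthoc_settings: MCMCSettings | None = None) -> CCESummary:
    """Omnibus CCE model plus gated post-hoc laterality contrasts.

    Post-hocs run only when a Laterality-involving omnibus term supports
    the alternative (BF10 >= 3), mirroring the reporting rule of the study
    design; otherwise the contrast table is empty and ``posthoc_gated`` is
    False.
    """
    f, bfs = fit_cce_model(ie, settings)
    cce = cce_table(ie)
    groups = sorted(cce["group"].unique())
    conds = sorted(cce["condition"].unique())
    cells = cell_estimates(f, groups, conds)
    lat_terms = [t for t in bfs if "laterality" in t]
    gated = any(bfs[t].supports_alternative() for t in lat_terms)
    rows = []
    if gated:
        for g in groups:
            for c in conds:
                ph = posthoc_laterality(ie, g, c, posthoc_settings
                                        or settings)
                rows.append({"group": g, "condition": c,
                             "bf10": ph["bf"].bf10, "band": ph["bf"].band,
                             "mode": ph["contrast"]["mode"],
                             "hpdi_lo": ph["contrast"]["hpdi_lo"],
                             "hpdi_hi": ph["contrast"]["hpdi_hi"]})
    contrasts = pd.DataFrame(rows, columns=["group", "condition", "bf10",
                                            "band", "mode", "hpdi_lo",
                                            "hpdi_hi"])
    return CCESummary(omnibus=bfs, cells=cells, contrasts=contrasts,
                      rhat=f.rhat(), posthoc_gated=gated, fit=f)


# ---------------------------------------------------------------------------
# movement verbal feedback

def point_hypothesis_bf(k: int, n: int, p1: float = 0.85,
                        p0: float = 0.5) -> float:
    """Closed-form Bayes factor Bin(k; n, p1) / Bin(k; n, p0).

    Tests informed accuracy (p1, 85% by default) against guessing (p0,
    50%) for one accuracy count.
    """
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    return float(binom.pmf(k, n, p1) / binom.pmf(k, n, p0))


@dataclass
class FeedbackSummary:
    counts: pd.DataFrame              # group, condition, k, n
    model_bfs: dict                   # term -> BFResult
    point_bfs: pd.DataFrame           # group, condition, bf10, band
    pairwise: pd.DataFrame | None = None
    rhat: dict = field(default_factory=dict)

    def to_dict(self):
        d = {"counts": self.counts.to_dict(orient="records"),
             "model_bfs": {t: r.to_dict() for t, r in self.model_bfs.items()},
             "point_bfs": self.point_bfs.to_dict(orient="records"),
             "rhat": self.rhat}
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        return d


def feedback_analysis(accuracy: pd.DataFrame,
                      settings: MCMCSettings | None = None,
                      pairwise: bool = False) -> FeedbackSummary:
    """Hierarchical binomial analysis of movement verbal feedback.

    ``accuracy`` holds one 0/1 outcome per participant x video (columns
    participant, group, condition, accuracy). Fits Group, Condition and
    their interaction (selectable) with Condition random slopes by
    participant, and computes the closed-form point-hypothesis BF (85% vs
    50% correct) per group x condition cell. Pairwise condition
    comparisons within each group are model refits on condition pairs (no
    multiplicity adjustment: Bayes factors compare models directly).
    """
    acc = accuracy.dropna(subset=["accuracy"]).copy()
    counts = (acc.groupby(["group", "condition"])["accuracy"]
              .agg(k="sum", n="count").reset_index())
    counts = counts[counts["n"] > 0]
    spec = ModelSpec(response="accuracy", forced=("1",),
                     selectable=("group", "condition", "group:condition"),
                     random_slopes=("1", "condition"), group="participant",
                     family="binomial",
                     priors=PriorSpec(effect_scale=2.5))
    f = bayes.fit(spec, acc, _test_settings(settings))
    point = [{"group": r["group"], "condition": r["condition"],
              "k": int(r["k"]), "n": int(r["n"]),
              "bf10": point_hypothesis_bf(int(r["k"]), int(r["n"])),
              }
             for _, r in counts.iterrows()]
    point_df = pd.DataFrame(point)
    point_df["band"] = point_df["bf10"].map(raftery_band)
    pw = None
    if pairwise:
        rows = []
        for g in sorted(acc["group"].unique()):
            sub_g = acc[acc["group"] == g]
            conds = sorted(sub_g["condition"].unique())
            for i, a in enumerate(conds):
                for b in conds[i + 1:]:
                    sub = sub_g[sub_g["condition"].isin([a, b])]
                    sp = ModelSpec(response="accuracy", forced=("1",),
                                   selectable=("condition",),
                                   random_slopes=("1",),
                                   group="participant", family="binomial",
                                   priors=PriorSpec(effect_scale=2.5))
                    fp = bayes.fit(sp, sub, _test_settings(settings))
                    r = fp.bayes_factor("condition")
                    rows.append({"group": g, "a": a, "b": b,
                                 "bf10": r.bf10, "band": r.band})
        pw = pd.DataFrame(rows)
    return FeedbackSummary(counts=counts, model_bfs=f.bayes_factors(),
                           point_bfs=point_df, pairwise=pw, rhat=f.rhat())


# ---------------------------------------------------------------------------
# covariation analyses

@dataclass
class CovariationResult:
    which: str
    bfs: dict                       # term -> BFResult
    slopes: pd.DataFrame            # covariate, condition, mode, lo, hi
    rhat: dict = field(default_factory=dict)

    def to_dict(self):
        return {"which": self.which,
                "bfs": {t: r.to_dict() for t, r in self.bfs.items()},
                "slopes": self.slopes.to_dict(orient="records"),
                "rhat": self.rhat}


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        return x * np.nan
    return (x - x.mean()) / sd


def covary(ie: pd.DataFrame, covariates: pd.DataFrame, which: str,
           settings: MCMCSettings | None = None) -> CovariationResult:
    """Covariation of the unilateral CCE with external measures.

    ``which`` selects the analysis: "physio" (scl + rsa, merged by
    participant x session x block), "bpq" (per participant), or "clinical"
    (ais + nli numeric codes, CP and IP participants only). The response is
    the unilateral CCE (standardized within the analysis set, so slopes are
    per SD of covariate on the SD scale of the CCE); covariates are
    z-scored. Fixed terms: Group, Condition, each covariate and its
    interactions with Group and Condition (all selectable); random slopes
    for Condition and block order by participant.

    Per-condition slope posteriors (mode, 99% HPDI) are reported only for
    covariate terms whose BF supports the alternative.
    """
    cov_cols = {"physio": ["scl", "rsa"], "bpq": ["bpq"],
                "clinical": ["ais", "nli"]}.get(which)
    if cov_cols is None:
        raise ValueError(f"unknown covariation analysis {which!r}")
    cce = cce_table(ie, lateralities=("Unilateral",))
    if which == "clinical":
        cce = cce[cce["group"].isin(["CP", "IP"])]
    join_keys = [k for k in ("participant", "session", "block")
                 if k in covariates.columns]
    data = cce.merge(covariates, on=join_keys, how="inner")
    missing = [c for c in cov_cols if c not in data.columns]
    if missing:
        raise DataError(f"covariate columns missing: {missing}")
    data = data.dropna(subset=cov_cols + ["cce"]).copy()
    if data.empty:
        raise InsufficientDataError("no rows after joining covariates")
    data["cce_z"] = _zscore(data["cce"])
    kept_covs = []
    for c in cov_cols:
        z = _zscore(data[c].astype(float))
        if z.isna().all():
            import warnings
            warnings.warn(f"covariate {c!r} constant after "
                          "standardization; dropped")
            continue
        data[f"z_{c}"] = z
        kept_covs.append(f"z_{c}")
    if not kept_covs:
        raise DataError("no usable covariates")
    multi_group = data["group"].nunique() > 1
    selectable = ["condition"] + (["group"] if multi_group else [])
    for zc in kept_covs:
        selectable.append(zc)
        selectable.append(f"condition:{zc}")
        if multi_group:
            selectable.append(f"group:{zc}")
            selectable.append(f"group:condition:{zc}")
    random = ("1", "condition", "block_order_z")
    spec = ModelSpec(response="cce_z", forced=("1",),
                     selectable=tuple(selectable), random_slopes=random,
                     group="participant")
    f = bayes.fit(spec, data, _test_settings(settings))
    bfs = f.bayes_factors()

    # per-condition slopes for supported covariate terms
    groups = sorted(data["group"].unique())
    conds = sorted(data["condition"].unique())
    rows = []
    for zc in kept_covs:
        terms = [t for t in selectable if zc in t]
        if not any(bfs[t].supports_alternative() for t in terms):
            continue
        for c in conds:
            base = pd.DataFrame([
                {"group": g, "condition": c, "block_order_z": 0.0,
                 **{k: 0.0 for k in kept_covs}} for g in groups])
            plus = base.copy()
            plus[zc] = 1.0
            slope = (f.predict_fixed(plus) - f.predict_fixed(base)
                     ).mean(axis=1)
            lo, hi = hpdi(slope, HPDI_MASS)
            rows.append({"covariate": zc[2:], "condition": c,
                         "mode": posterior_mode(slope),
                         "hpdi_lo": lo, "hpdi_hi": hi})
    slopes = pd.DataFrame(rows, columns=["covariate", "condition", "mode",
                                         "hpdi_lo", "hpdi_hi"])
    return CovariationResult(which=which, bfs=bfs, slopes=slopes,
                             rhat=f.rhat())
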