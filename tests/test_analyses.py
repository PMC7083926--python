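"""Composed analyses: CCE table, baseline merge decision, feedback BFs,
covariation gating."""

import numpy as np
import pandas as pd
import pytest

from pps import analyses, preprocess, synth
from pps.bayes import MCMCSettings
from pps.errors import DataError, DesignError, InsufficientDataError


def _settings(seed=0):
    return MCMCSettings(n_chains=2, n_iter=1200, n_burnin=300, n_adapt=300,
                        seed=seed)


class TestCCETable:
    def test_cce_is_incongruent_minus_congruent(self):
        rows = []
        for cong, ie in (("Incongruent", 500.0), ("Congruent", 380.0)):
            for i in range(3):
                rows.append({"participant": "P1", "group": "C",
                             "session": "S", "block": 2,
                             "condition": "V+M+",
                             "laterality": "Unilateral",
                             "congruency": cong, "ie": ie + i,
                             "block_order_z": 0.0})
        cce = analyses.cce_table(pd.DataFrame(rows))
        assert len(cce) == 1
        assert cce["cce"].iloc[0] == pytest.approx(120.0)

    def test_incomplete_cells_dropped(self):
        rows = [{"participant": "P1", "group": "C", "session": "S",
                 "block": 2, "condition": "V+M+",
                 "laterality": "Unilateral", "congruency": "Congruent",
                 "ie": 300.0, "block_order_z": 0.0}]
        cce = analyses.cce_table(pd.DataFrame(rows))
        assert cce.empty

    def test_missing_columns_rejected(self):
        with pytest.raises(DataError):
            analyses.cce_table(pd.DataFrame({"participant": []}))


class TestBaselineEquivalence:
    def test_null_cohort_recommends_merge(self, small_ie):
        res = analyses.baseline_equivalence(small_ie, _settings(1))
        assert res["interaction_bf"].bf10 < 1.0
        assert res["merge_recommended"]

    def test_planted_followup_shift_detected(self, small_config):
        # plant a follow-up-only unilateral CCE by editing the trial table
        roster = synth.gen_cohort(small_config)
        eff = synth.EffectSpec(cce_unilateral={}, participant_cce_sd=0.0)
        trials = synth.gen_trials(roster, eff, small_config)
        mask = ((trials["block"] == 8)
                & (trials["laterality"] == "Unilateral")
                & (trials["congruency"] == "Incongruent"))
        trials.loc[mask, "rt_ms"] += 400.0  # ~3 residual SDs at cell level
        ie, _ = preprocess.preprocess(trials)
        res = analyses.baseline_equivalence(ie, _settings(2))
        assert res["interaction_bf"].bf10 > 3.0
        assert not res["merge_recommended"]

    def test_missing_block8_rejected(self, small_ie):
        with pytest.raises(DataError):
            analyses.baseline_equivalence(
                small_ie[small_ie["block"] != 8], _settings())


class TestCCEModel:
    def test_empty_cell_rejected(self, small_ie):
        broken = small_ie[~((small_ie["group"] == "C")
                            & (small_ie["condition"] == "V+M+")
                            & (small_ie["laterality"] == "Unilateral"))]
        merged = preprocess.merge_baseline_followup(broken)
        with pytest.raises(DesignError, match="V\\+M\\+"):
            analyses.fit_cce_model(merged, _settings())

    def test_grouping_units_pool_across_sessions(self, default_ie):
        merged = preprocess.merge_baseline_followup(default_ie)
        cce = analyses.cce_table(merged)
        assert cce["participant"].nunique() == 70

    def test_posthoc_needs_enough_cells(self, small_ie):
        merged = preprocess.merge_baseline_followup(small_ie)
        one = merged[merged["participant"] == merged["participant"].iloc[0]]
        with pytest.raises(InsufficientDataError):
            analyses.posthoc_laterality(one, one["group"].iloc[0],
                                        "NoStimulation", _settings())

    def test_null_cohort_gates_posthocs_off(self, small_config):
        roster = synth.gen_cohort(small_config)
        eff = synth.EffectSpec(cce_unilateral={}, participant_cce_sd=0.0)
        trials = synth.gen_trials(roster, eff, small_config)
        ie, _ = preprocess.preprocess(trials)
        merged = preprocess.merge_baseline_followup(ie)
        s = analyses.cce_analysis(merged, _settings(3))
        lat_bfs = [s.omnibus[t].bf10 for t in analyses.CCE_TERMS
                   if "laterality" in t]
        if not s.posthoc_gated:
            assert s.contrasts.empty
            assert all(b < 3.0 for b in lat_bfs)
        else:  # gate is data driven; if it fired, a BF must justify it
            assert any(b >= 3.0 for b in lat_bfs)


class TestFeedback:
    def test_point_bf_closed_forms(self):
        assert analyses.point_hypothesis_bf(42, 42) == pytest.approx(
            (0.85 / 0.5) ** 42, rel=1e-9)
        from scipy.stats import binom
        expect = binom.pmf(33, 42, 0.85) / binom.pmf(33, 42, 0.5)
        assert analyses.point_hypothesis_bf(33, 42) == pytest.approx(
            expect, rel=1e-12)

    def test_chance_counts_favour_the_null(self):
        assert analyses.point_hypothesis_bf(21, 42) < 1.0

    def test_invalid_count_rejected(self):
        with pytest.raises(ValueError):
            analyses.point_hypothesis_bf(43, 42)

    def test_feedback_analysis_counts_and_cells(self, small_config):
        roster = synth.gen_cohort(small_config)
        eff = synth.EffectSpec()
        fb = synth.gen_feedback(roster, eff, small_config)
        acc = preprocess.recode_feedback(fb)
        res = analyses.feedback_analysis(acc, _settings(4))
        # every group x condition cell present: participants x 3 videos
        assert (res.counts["n"] > 0).all()
        assert set(res.model_bfs) == {"group", "condition",
                                      "group:condition"}
        assert (res.point_bfs["k"] <= res.point_bfs["n"]).all()


class TestCovary:
    def test_planted_slope_in_one_condition_detected(self, small_config):
        roster = synth.gen_cohort(small_config)
        cov_z = synth.gen_covariates(roster, small_config)
        eff = synth.EffectSpec(covariate_slopes={"scl": {"V-M-": 150.0}},
                               participant_cce_sd=0.0)
        trials = synth.gen_trials(roster, eff, small_config,
                                  covariate_z=cov_z)
        ie, _ = preprocess.preprocess(trials)
        ie = preprocess.merge_baseline_followup(ie)
        wide = cov_z.pivot_table(index=["participant", "session", "block"],
                                 columns="name", values="z").reset_index()
        res = analyses.covary(ie, wide, "physio", _settings(5))
        assert res.bfs["condition:z_scl"].bf10 > 3.0
        sl = res.slopes[(res.slopes["covariate"] == "scl")
                        & (res.slopes["condition"] == "V-M-")]
        assert len(sl) == 1 and sl["mode"].iloc[0] > 0.0

    def test_pure_noise_covariate_not_supported(self, small_ie):
        ie = preprocess.merge_baseline_followup(small_ie)
        rng = np.random.default_rng(0)
        parts = ie[["participant", "session", "block"]].drop_duplicates()
        parts["scl"] = rng.standard_normal(len(parts))
        parts["rsa"] = rng.standard_normal(len(parts))
        res = analyses.covary(ie, parts, "physio", _settings(6))
        cov_terms = [t for t in res.bfs if "z_" in t]
        assert np.median([res.bfs[t].bf10 for t in cov_terms]) < 1.0

    def test_clinical_covariates_use_numeric_recoding(self, default_roster,
                                                      small_ie):
        # AIS letters are already numeric codes in the roster: A -> 1
        cp = default_roster[default_roster["group"] == "CP"]
        assert (cp["ais_code"] == 1).all()
        ip = default_roster[default_roster["group"] == "IP"]
        assert ip["ais_code"].isin([2, 3, 4]).all()

    def test_constant_covariate_dropped_with_warning(self, small_ie):
        ie = preprocess.merge_baseline_followup(small_ie)
        parts = ie[["participant"]].drop_duplicates()
        parts["bpq"] = 100.0
        with pytest.raises(DataError):
            with pytest.warns(UserWarning, match="constant"):
                analyses.covary(ie, parts, "bpq", _settings(7))
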