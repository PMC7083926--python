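"""Shared fixtures: synthetic cohorts at two scales.

The study-scale cohort (14 per group, both sessions, full trial counts) is
generated once per session; reduced cohorts keep the structure but shrink
trial counts for fast model fits.
"""

import numpy as np
import pandas as pd
import pytest

from pps import preprocess, synth


@pytest.fixture(scope="session")
def default_config():
    return synth.CohortConfig(seed=11)


@pytest.fixture(scope="session")
def default_roster(default_config):
    return synth.gen_cohort(default_config)


@pytest.fixture(scope="session")
def default_trials(default_config, default_roster):
    return synth.gen_trials(default_roster, synth.EffectSpec(),
                            default_config)


@pytest.fixture(scope="session")
def default_ie(default_trials):
    ie, log = preprocess.preprocess(default_trials)
    return ie


@pytest.fixture(scope="session")
def small_config():
    return synth.CohortConfig(n_per_group=6, trials_baseline=24,
                              trials_block=16, seed=7)


@pytest.fixture(scope="session")
def small_ie(small_config):
    roster = synth.gen_cohort(small_config)
    trials = synth.gen_trials(roster, synth.EffectSpec(), small_config)
    ie, _ = preprocess.preprocess(trials)
    return ie
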