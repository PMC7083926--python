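# pps-pipeline

A reusable analysis pipeline for crossmodal-congruency studies of
**peripersonal space (PPS)** — the multisensory margin of space around a
body part — in spinal-cord-injury research. It covers the full path from
raw inputs to Bayesian inference: voice-onset reaction times from 8000 Hz
WAV recordings, an inverse-efficiency preprocessing cascade, autonomic
indices (skin-conductance range, log respiratory sinus arrhythmia), and
hierarchical Bayesian models with **Kuo–Mallick indicator-variable Bayes
factors**. A first-class synthetic-data generator reproduces the
experimental design with plantable ground-truth effects, so every stage is
testable against known truth.

## The model at the core

For tactile judgements with visual distractors, the crossmodal congruency
effect is the inverse-efficiency cost of incongruent distractors,

    CCE = IE(incongruent) − IE(congruent),    IE = RT / p(correct per block),

and PPS is indexed by the *unilateral* CCE exceeding the *bilateral* one.
Per participant × block × laterality cell the CCE feeds a hierarchical
Gaussian model

    CCE = Σ_j γ_j X_j β_j + Z u + ε,   γ_j ∈ {0,1},  Pr(γ_j = 1) = ½,

whose selectable fixed terms are Group, Condition, Laterality and all
their interactions, with random slopes (Laterality, Condition, their
interaction, standardized block order) grouped by participant. The Bayes
factor for a term is its posterior-vs-prior inclusion odds,
BF₁₀ = [p/(1−p)] / [π/(1−π)], interpreted on Raftery's bands (3 / 20 /
150 and reciprocals). Movement verbal feedback uses a hierarchical
binomial model plus the closed-form point test
Bin(k; n, 0.85) / Bin(k; n, 0.5). Estimates are posterior modes with 99%
highest-posterior-density intervals; convergence is monitored with the
Gelman–Rubin R̂ (flagged at 1.1).

## Worked example

```python
from pps import synth, preprocess, analyses
from pps.bayes import MCMCSettings

cfg = synth.CohortConfig(seed=1)            # 3 groups x 14/session, 2 sessions
roster = synth.gen_cohort(cfg)
trials = synth.gen_trials(roster, synth.EffectSpec(), cfg)
ie, log = preprocess.preprocess(trials)     # gate -> 100 ms cut -> IE -> +-2.5 SD

base = analyses.baseline_equivalence(ie, MCMCSettings.test_scale(seed=1))
ie = preprocess.merge_baseline_followup(ie)
fit, bfs = analyses.fit_cce_model(ie, MCMCSettings.test_scale(seed=2))
ph = analyses.posthoc_laterality(ie, "C", "NoStimulation",
                                 MCMCSettings.test_scale(seed=3))
```

prints (via the surrounding script):

```
70 participants, 30576 trials, 24382 IE entries (1.74% outliers removed)
baseline vs follow-up interaction: BF10 = 0.044 (strong (null)); merge = True
laterality: BF10 > 6e+03 (very strong)
group:condition:laterality: BF10 > 6e+03 (very strong)
C / NoStimulation unilateral-bilateral contrast: Mo = 93.0 ms,
    99% HPDI [46.4, 136.7], BF10 = 6e+03
```

Reading it: baseline and follow-up blocks show no PPS difference (BF₁₀ =
0.044 supports the null), so they merge into one "NoStimulation"
condition. Laterality and the three-way Group:Condition:Laterality
interaction are decisively supported — the planted PPS pattern is
detected — and the control group's no-stimulation contrast recovers the
planted 100 ms unilateral CCE (mode 93 ms, interval covering it). BFs
reported as `> 6e+03` are one-sided bounds: the term's indicator never
left the model across all retained draws.

The same workflow is scriptable from a shell:

```bash
pps defaults > config.toml        # all defaults, commented
pps run --config config.toml --seed 1 --out results/
pps report --results results/results.json
```

`pps run` writes the trial tables, IE table, physiological indices, BF
tables with evidence bands, a Condition × Laterality × Group estimate CSV,
violin plots of posterior CCE distributions, a structured log, and a text
report that names any parameter with R̂ ≥ 1.1.

## Layout

```
src/pps/
  synth.py        cohorts, trials, audio, physiology with ground truth
  preprocess.py   RT extraction and the exclusion cascade
  physio.py       SCL range and ln RSA extraction
  bayes/          design matrices, Kuo-Mallick sampler, diagnostics,
                  sklearn-style BayesGLMM estimator
  analyses.py     baseline equivalence, CCE model + post hocs, feedback,
                  covariation analyses
  pipeline.py     simulate -> preprocess -> analyse -> report orchestration
  cli.py          the `pps` command
docs/methods.md   modelling assumptions, defaults, limitations
```
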