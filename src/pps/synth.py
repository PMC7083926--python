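"""Synthetic cohorts for the peripersonal-space (PPS) experiment.

Generates everything the analysis pipeline consumes, with known ground
truth: participant rosters (three groups - healthy controls C, complete
paraplegics CP, incomplete paraplegics IP - with clinical scores), trial
tables for the visuo-tactile crossmodal congruency task (8 blocks per
session: baseline and follow-up of 56 trials, six 36-trial video blocks),
verbal-response audio at 8000 Hz, movement-feedback responses, and
physiological traces (skin conductance, pulse wave, respiration) with a
plantable respiratory-sinus-arrhythmia amplitude.

The default configuration reproduces the study design it emulates: 14
participants per group per session, two sessions (one per video type), with
9 CP and 5 IP participants taking part in both sessions, giving 70 distinct
participants. Reaction times are log-normal with an additive crossmodal
congruency effect (CCE) planted on incongruent trials; the default CCE
pattern places a 100 ms unilateral effect exactly where the emulated study
found PPS (controls: visuo-motor-congruent conditions plus no-stimulation;
CP: only when the legs are actually moved; IP: whenever vision or motion
signals movement).
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import ConfigurationError, GenerationError

__all__ = [
    "GROUPS", "SESSIONS", "CONDITIONS", "PPS_PATTERN",
    "CohortConfig", "EffectSpec", "PhysioGroundTruth", "PhysioRecording",
    "gen_cohort", "gen_trials", "gen_covariates", "gen_feedback",
    "gen_audio", "render_block_audio", "gen_physio", "write_physio_csv",
    "default_unilateral_cce", "default_feedback_p",
]

GROUPS = ("C", "CP", "IP")
SESSIONS = ("VisionMobilisation", "VisionNoMobilisation")
#: five-level condition factor after baseline/follow-up merging
CONDITIONS = ("NoStimulation", "V+M+", "V+M-", "V-M+", "V-M-")
VIDEO_CONDITIONS = {
    "VisionMobilisation": ("V+M+", "V+M-"),
    "VisionNoMobilisation": ("V-M+", "V-M-"),
}
LATERALITIES = ("Unilateral", "Bilateral")
CONGRUENCIES = ("Congruent", "Incongruent")

#: group x condition cells where a PPS representation (unilateral CCE) is
#: planted by default: controls in visuo-motor congruent conditions and at
#: rest, paraplegics whenever their legs are actually moved, incomplete
#: paraplegics additionally when only vision signals movement.
PPS_PATTERN = frozenset({
    ("C", "NoStimulation"), ("C", "V+M+"), ("C", "V-M-"),
    ("CP", "V+M+"), ("CP", "V-M+"),
    ("IP", "V+M+"), ("IP", "V-M+"), ("IP", "V+M-"),
})


def default_unilateral_cce(amplitude: float = 100.0) -> dict:
    """Planted unilateral CCE (ms) per (group, condition) cell."""
    return {(g, c): (amplitude if (g, c) in PPS_PATTERN else 0.0)
            for g in GROUPS for c in CONDITIONS}


def default_feedback_p() -> dict:
    """Movement-feedback accuracy per (group, condition): the per-cell
    proportions the emulated study reported (counts out of 42)."""
    counts = {("C", "V+M+"): 42, ("C", "V+M-"): 42,
              ("C", "V-M+"): 42, ("C", "V-M-"): 41,
              ("CP", "V+M+"): 34, ("CP", "V+M-"): 37,
              ("CP", "V-M+"): 42, ("CP", "V-M-"): 38,
              ("IP", "V+M+"): 42, ("IP", "V+M-"): 36,
              ("IP", "V-M+"): 33, ("IP", "V-M-"): 36}
    return {k: v / 42.0 for k, v in counts.items()}


@dataclass(frozen=True)
class CohortConfig:
    n_per_group: int = 14
    groups: tuple = GROUPS
    sessions: tuple = SESSIONS
    seed: int = 0
    trials_baseline: int = 56
    trials_block: int = 36
    n_blocks: int = 8
    #: dual-session participants per group (only used with both sessions);
    #: defaults give 70 distinct participants over 84 session slots
    n_dual: dict = field(default_factory=lambda: {"C": 0, "CP": 9, "IP": 5})
    #: control ("luci") + false-stimulation ("niente") trials, as a fraction
    #: of the target trials in each block
    control_rate: float = 0.10

    def __post_init__(self):
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        for name in ("trials_baseline", "trials_block"):
            v = getattr(self, name)
            if v <= 0 or v % 4:
                raise ConfigurationError(
                    f"{name} must be a positive multiple of 4 so the four "
                    f"laterality x congruency cells fill evenly, got {v}")
        if not set(self.groups) <= set(GROUPS):
            raise ConfigurationError(f"unknown groups {self.groups}")
        if not set(self.sessions) <= set(SESSIONS):
            raise ConfigurationError(f"unknown sessions {self.sessions}")


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effects planted in the trial tables.

    RTs are log-normal with median ``base_rt`` and coefficient of variation
    ``rt_sd / base_rt``; incongruent trials are shifted additively (ms) by
    the cell's CCE. ``participant_cce_sd`` adds participant-level unilateral
    CCE variability; ``covariate_slopes[name][condition]`` couples a
    standardized per-participant(-block) covariate to the unilateral CCE.
    """

    base_rt: float = 600.0
    rt_sd: float = 150.0
    cce_unilateral: dict = field(default_factory=default_unilateral_cce)
    cce_bilateral: dict | float = 0.0
    error_rate: float = 0.10
    lapse_rate_control: float = 0.05
    feedback_p_correct: dict = field(default_factory=default_feedback_p)
    participant_cce_sd: float = 20.0
    covariate_slopes: dict = field(default_factory=dict)

    def __post_init__(self):
        for p in (self.error_rate, self.lapse_rate_control):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("rates must lie in [0, 1]")
        for p in self.feedback_p_correct.values():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError("feedback probabilities in [0, 1]")
        if self.rt_sd <= 0:
            raise ConfigurationError("rt_sd must be positive")
        vals = list(self.cce_unilateral.values())
        if isinstance(self.cce_bilateral, dict):
            vals += list(self.cce_bilateral.values())
        else:
            vals += [self.cce_bilateral]
        if not np.all(np.isfinite(vals)):
            raise ConfigurationError("CCE values must be finite")

    def unilateral(self, group, condition) -> float:
        return float(self.cce_unilateral.get((group, condition), 0.0))

    def bilateral(self, group, condition) -> float:
        if isinstance(self.cce_bilateral, dict):
            return float(self.cce_bilateral.get((group, condition), 0.0))
        return float(self.cce_bilateral)


@dataclass(frozen=True)
class PhysioGroundTruth:
    scl_range: float = 5.0
    scl_base: float = 2.0
    ibi_mean: float = 0.8
    rsa_amplitude: float = 0.1
    resp_freq: float = 0.25
    sample_rate: float = 100.0

    def __post_init__(self):
        if self.sample_rate <= 2 * self.resp_freq:
            raise ConfigurationError("sample_rate must exceed twice the "
                                     "respiratory frequency")
        if self.rsa_amplitude < 0:
            raise ConfigurationError("rsa_amplitude must be >= 0")
        if self.ibi_mean <= 0:
            raise ConfigurationError("ibi_mean must be positive")
        if self.rsa_amplitude >= self.ibi_mean:
            raise ConfigurationError(
                "rsa_amplitude >= ibi_mean would produce non-positive "
                "heart periods")


# ---------------------------------------------------------------------------
# roster

_NLI_NAMES = ([f"C{i}" for i in range(1, 9)] + [f"T{i}" for i in range(1, 13)]
              + [f"L{i}" for i in range(1, 6)] + [f"S{i}" for i in range(1, 6)])


def nli_label(code: int) -> str:
    """Numeric neurological level (C1=1 ... S5=30) back to its segment name."""
    if not 1 <= code <= 30:
        raise ValueError(f"NLI code out of range: {code}")
    return _NLI_NAMES[code - 1]


AIS_CODES = {"A": 1, "B": 2, "C": 3, "D": 4, "E": 5}


def stable_seed(*parts) -> int:
    """Deterministic sub-seed from string/int parts (CRC32, process-safe)."""
    return zlib.crc32("|".join(map(str, parts)).encode()) % (2 ** 31)


def gen_cohort(config: CohortConfig) -> pd.DataFrame:
    """Participant roster with sessions, AIS/NLI numeric codes and BPQ.

    Complete paraplegics are all AIS grade A (code 1); incomplete
    paraplegics draw grades B-D; controls carry no AIS/NLI. BPQ Body
    Awareness scores are drawn per participant (normal, mean 100, SD 25,
    clipped to the 42-210 scale range; ``bpq_z`` keeps the standardized
    draw as ground truth).
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    pid = 0
    both = len(config.sessions) == 2
    for g in config.groups:
        n_dual = config.n_dual.get(g, 0) if both else 0
        n_dual = min(n_dual, config.n_per_group)
        n_single = config.n_per_group - n_dual
        plan = [("both",)] * n_dual
        for s in config.sessions:
            plan += [(s,)] * n_single
        for (membership,) in plan:
            pid += 1
            z = float(rng.standard_normal())
            bpq = float(np.clip(100.0 + 25.0 * z, 42.0, 210.0))
            row = {"participant": f"P{pid:03d}", "group": g,
                   "sessions": membership, "bpq": bpq, "bpq_z": z}
            if g == "CP":
                row["ais"] = "A"
                row["nli_code"] = int(rng.integers(9, 21))
            elif g == "IP":
                row["ais"] = str(rng.choice(["B", "C", "D"]))
                row["nli_code"] = int(rng.integers(9, 26))
            else:
                row["ais"] = None
                row["nli_code"] = None
            row["ais_code"] = AIS_CODES.get(row["ais"]) if row["ais"] else None
            row["nli"] = (nli_label(row["nli_code"])
                          if row["nli_code"] else None)
            rows.append(row)
    return pd.DataFrame(rows)


def roster_sessions(roster: pd.DataFrame, config: CohortConfig):
    """(participant row, session) pairs in generation order."""
    out = []
    for _, r in roster.iterrows():
        if r["sessions"] == "both":
            for s in config.sessions:
                out.append((r, s))
        else:
            out.append((r, r["sessions"]))
    return out


# ---------------------------------------------------------------------------
# trials

def _block_conditions(session: str, flip: bool) -> list:
    """Conditions of blocks 1..8: baseline, 3+3 video blocks, follow-up."""
    a, b = VIDEO_CONDITIONS[session]
    if flip:
        a, b = b, a
    return (["NoStimulation"] + [a] * 3 + [b] * 3 + ["NoStimulation"])


def gen_covariates(roster: pd.DataFrame, config: CohortConfig,
                   names=("scl", "rsa")) -> pd.DataFrame:
    """Standardized ground-truth covariate values per participant x block.

    These are the latent z-scores that (a) scale the physiological traces
    and (b) shift the unilateral CCE when ``EffectSpec.covariate_slopes``
    couples them to behaviour.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 71]))
    rows = []
    for r, session in roster_sessions(roster, config):
        for block in range(1, config.n_blocks + 1):
            for name in names:
                rows.append({"participant": r["participant"],
                             "session": session, "block": block,
                             "name": name,
                             "z": float(rng.standard_normal())})
    return pd.DataFrame(rows)


def gen_trials(roster: pd.DataFrame, effects: EffectSpec,
               config: CohortConfig,
               covariate_z: pd.DataFrame | None = None) -> pd.DataFrame:
    """Trial table for every participant x session.

    Per session: block 1 (baseline) and block 8 (follow-up) are
    no-stimulation blocks of ``trials_baseline`` target trials; blocks 2-7
    carry the two session conditions in two runs of three consecutive
    blocks (order alternating across participants), ``trials_block`` target
    trials each. Every block balances the four laterality x congruency
    cells exactly and appends control/false-stimulation trials at
    ``control_rate``.
    """
    ss = np.random.SeedSequence([config.seed, 17])
    rng = np.random.default_rng(ss)
    sigma_log = effects.rt_sd / effects.base_rt
    zlook = {}
    if covariate_z is not None:
        for _, row in covariate_z.iterrows():
            zlook[(row["participant"], row["session"], int(row["block"]),
                   row["name"])] = float(row["z"])
    bpq_z = dict(zip(roster["participant"], roster.get(
        "bpq_z", pd.Series(dtype=float))))

    rows = []
    for k, (r, session) in enumerate(roster_sessions(roster, config)):
        part, group = r["participant"], r["group"]
        dev = float(rng.normal(0.0, effects.participant_cce_sd))
        conds = _block_conditions(session, flip=bool(k % 2))
        for block, cond in enumerate(conds, start=1):
            n_t = (config.trials_baseline if cond == "NoStimulation"
                   else config.trials_block)
            cells = [(lat, con) for lat in LATERALITIES
                     for con in CONGRUENCIES] * (n_t // 4)
            order = rng.permutation(len(cells))
            # planted unilateral CCE for this participant x block
            cov_shift = 0.0
            for name, slopes in effects.covariate_slopes.items():
                slope = slopes.get(cond, 0.0)
                if not slope:
                    continue
                if name == "bpq":
                    z = bpq_z.get(part, 0.0)
                else:
                    z = zlook.get((part, session, block, name), 0.0)
                cov_shift += slope * z
            cce_uni = effects.unilateral(group, cond) + dev + cov_shift
            cce_bil = effects.bilateral(group, cond)
            for trial_i, idx in enumerate(order, start=1):
                lat, con = cells[idx]
                rt = effects.base_rt * float(np.exp(
                    sigma_log * rng.standard_normal()))
                if con == "Incongruent":
                    rt += cce_uni if lat == "Unilateral" else cce_bil
                correct = bool(rng.uniform() >= effects.error_rate)
                site = "index" if rng.uniform() < 0.5 else "thumb"
                target_resp = "TAH" if site == "index" else "TOH"
                resp = target_resp if correct else (
                    "TOH" if site == "index" else "TAH")
                rows.append({
                    "participant": part, "group": group, "session": session,
                    "block": block, "trial": trial_i, "condition": cond,
                    "laterality": lat, "congruency": con,
                    "tactile_site": site,
                    "side": "L" if rng.uniform() < 0.5 else "R",
                    "trial_type": "target", "response": resp,
                    "rt_ms": max(rt, 1.0), "correct": correct})
            # control ("luci") and false-stimulation ("niente") trials
            n_ctrl = int(round(config.control_rate * n_t))
            for j in range(n_ctrl):
                ttype = "control" if j % 2 == 0 else "false_stimulation"
                expected = "luci" if ttype == "control" else "niente"
                ok = bool(rng.uniform() >= effects.lapse_rate_control)
                rt = effects.base_rt * float(np.exp(
                    sigma_log * rng.standard_normal()))
                rows.append({
                    "participant": part, "group": group, "session": session,
                    "block": block, "trial": n_t + j + 1, "condition": cond,
                    "laterality": None, "congruency": None,
                    "tactile_site": None, "side": None, "trial_type": ttype,
                    "response": expected if ok else "TAH",
                    "rt_ms": max(rt, 1.0), "correct": ok})
    return pd.DataFrame(rows)


def gen_feedback(roster: pd.DataFrame, effects: EffectSpec,
                 config: CohortConfig) -> pd.DataFrame:
    """Movement verbal feedback, one yes/no response per video block.

    After each of the six 2-minute videos participants report whether their
    legs were moved; the response is correct with the cell's
    ``feedback_p_correct`` probability.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 29]))
    rows = []
    for k, (r, session) in enumerate(roster_sessions(roster, config)):
        conds = _block_conditions(session, flip=bool(k % 2))
        for block, cond in enumerate(conds, start=1):
            if cond == "NoStimulation":
                continue
            moved = cond in ("V+M+", "V-M+")
            p = effects.feedback_p_correct.get((r["group"], cond), 0.85)
            ok = bool(rng.uniform() < p)
            resp = ("yes" if moved else "no") if ok else (
                "no" if moved else "yes")
            rows.append({"participant": r["participant"],
                         "group": r["group"], "session": session,
                         "block": block, "condition": cond,
                         "motion": "Mobilisation" if moved
                         else "NoMobilisation",
                         "response": resp})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# audio

BURST_FREQ_HZ = 1000.0
BURST_DUR_S = 0.200
BURST_AMP = 0.8
NOISE_FLOOR = 0.001
ONSET_OFFSET_S = 0.25


def render_block_audio(rts_ms, sample_rate: int = 8000,
                       trial_window_s: float = 3.0, seed: int = 0):
    """Render one block's verbal responses as a mono PCM waveform.

    Each trial occupies a fixed window; the stimulus onset sits
    ``ONSET_OFFSET_S`` into the window and the vocal burst (1 kHz tone,
    200 ms, amplitude 0.8 over a 0.001 noise floor) starts exactly the
    trial's RT after its onset. NaN RTs render silence (no response).

    Returns ``(samples_int16, onset_samples)``.
    """
    rng = np.random.default_rng(seed)
    fs = int(sample_rate)
    win = int(round(trial_window_s * fs))
    onset_in_win = int(round(ONSET_OFFSET_S * fs))
    n = win * len(rts_ms)
    x = rng.uniform(-NOISE_FLOOR, NOISE_FLOOR, size=n)
    burst_n = int(round(BURST_DUR_S * fs))
    t = np.arange(burst_n) / fs
    burst = BURST_AMP * np.sin(2 * np.pi * BURST_FREQ_HZ * t)
    onsets = []
    for i, rt in enumerate(rts_ms):
        onset = i * win + onset_in_win
        onsets.append(onset)
        if rt is None or (isinstance(rt, float) and np.isnan(rt)):
            continue
        if rt < 0:
            raise GenerationError(f"negative RT at trial {i}")
        start = onset + int(round(rt * fs / 1000.0))
        if start + burst_n > (i + 1) * win:
            raise GenerationError(
                f"RT {rt:.0f} ms places the response burst beyond the "
                f"{trial_window_s} s trial window (trial {i})")
        x[start:start + burst_n] += burst
    samples = np.clip(x, -1.0, 1.0)
    return (samples * 32767.0).astype(np.int16), np.array(onsets, dtype=int)


def gen_audio(trials: pd.DataFrame, out_dir, sample_rate: int = 8000,
              trial_window_s: float = 3.0) -> pd.DataFrame:
    """Write one WAV + onset-marker CSV per participant x session x block.

    Returns an index table (participant, session, block, wav, markers).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    idx_rows = []
    for (part, session, block), g in trials.groupby(
            ["participant", "session", "block"], sort=True):
        g = g.sort_values("trial")
        rts = g["rt_ms"].to_numpy(dtype=float)
        seed = stable_seed(part, session, int(block))
        samples, onsets = render_block_audio(
            rts, sample_rate, trial_window_s, seed=seed)
        stem = f"{part}_{session}_block{block}"
        wav_path = out_dir / f"{stem}.wav"
        wavfile.write(wav_path, sample_rate, samples)
        markers = pd.DataFrame({"trial": g["trial"].to_numpy(),
                                "onset_sample": onsets})
        mk_path = out_dir / f"{stem}.markers.csv"
        markers.to_csv(mk_path, index=False)
        idx_rows.append({"participant": part, "session": session,
                         "block": block, "wav": str(wav_path),
                         "markers": str(mk_path)})
    return pd.DataFrame(idx_rows)


# ---------------------------------------------------------------------------
# physiology

@dataclass
class PhysioRecording:
    """One 2-minute epoch of skin conductance, pulse wave and respiration."""

    scl: np.ndarray
    ppg: np.ndarray
    resp: np.ndarray
    sample_rate: float
    window: tuple = (0.0, 120.0)
    beat_times: np.ndarray | None = None  # ground truth, not an input


def gen_physio(truth: PhysioGroundTruth, duration: float = 120.0,
               seed: int = 0, noise_60hz: float = 0.0) -> PhysioRecording:
    """Physiological traces with known SCL range and RSA amplitude.

    The SCL trace is a slow raised-cosine drift spanning exactly
    ``scl_range`` (plus optional 60 Hz contamination, for exercising the
    40 Hz low-pass). Beats are placed so successive inter-beat intervals
    follow ``ibi_mean + (rsa_amplitude / 2) * sin(2 pi f_resp t)``: the
    per-respiratory-cycle peak-valley IBI excursion is ``rsa_amplitude``.
    """
    if duration < 3.0 / truth.resp_freq:
        raise GenerationError("duration must cover several respiratory "
                              "cycles")
    fs = truth.sample_rate
    t = np.arange(0.0, duration, 1.0 / fs)
    scl = truth.scl_base + truth.scl_range * (
        0.5 - 0.5 * np.cos(2 * np.pi * t / duration))
    if noise_60hz:
        scl = scl + noise_60hz * np.sin(2 * np.pi * 60.0 * t)
    resp = np.sin(2 * np.pi * truth.resp_freq * t)
    beats = [0.1]
    while True:
        ibi = truth.ibi_mean + 0.5 * truth.rsa_amplitude * np.sin(
            2 * np.pi * truth.resp_freq * beats[-1])
        nxt = beats[-1] + ibi
        if nxt >= duration:
            break
        beats.append(nxt)
    beats = np.array(beats)
    ppg = np.zeros_like(t)
    width = 0.04
    for bt in beats:
        lo = max(0, int((bt - 4 * width) * fs))
        hi = min(len(t), int((bt + 4 * width) * fs) + 1)
        ppg[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - bt) / width) ** 2)
    return PhysioRecording(scl=scl, ppg=ppg, resp=resp, sample_rate=fs,
                           window=(0.0, duration), beat_times=beats)


def write_physio_csv(rec: PhysioRecording, path) -> None:
    """CSV export: a header line declares the sample rate, then columns
    time_s, scl, ppg, resp."""
    buf = io.StringIO()
    buf.write(f"# sample_rate_hz={rec.sample_rate}\n")
    t = np.arange(len(rec.scl)) / rec.sample_rate
    pd.DataFrame({"time_s": t, "scl": rec.scl, "ppg": rec.ppg,
                  "resp": rec.resp}).to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())
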