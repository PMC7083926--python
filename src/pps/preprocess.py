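"""From raw audio and trial tables to the filtered inverse-efficiency set.

The exclusion cascade is fixed and mirrors the study design: (1) per
participant, an accuracy gate at strictly > 44% correct over target trials;
(2) removal of reaction times under 100 ms; (3) inverse-efficiency (IE)
scores, dividing each correct trial's RT by the block's proportion correct;
(4) a single-pass outlier cut keeping values inside the inclusive range
[mean - 2.5 SD, mean + 2.5 SD]. Every stage reports what it removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .errors import DataError, MarkerError, InsufficientDataError

__all__ = [
    "ACCURACY_GATE", "MIN_RT_MS",
    "extract_rt_from_wav", "accuracy_gate", "filter_rts", "compute_ie",
    "remove_outliers", "recode_feedback", "merge_baseline_followup",
    "block_order_z", "CascadeLog", "preprocess",
]

#: chance-level accuracy bound (strict), over target trials only
ACCURACY_GATE = 0.44
#: minimum plausible detection latency (ms); faster responses are removed
MIN_RT_MS = 100.0

RMS_WINDOW_S = 0.010
THRESHOLD_FACTOR = 5.0


def _moving_rms(x: np.ndarray, win: int) -> np.ndarray:
    """Causal RMS over the past ``win`` samples, same length as x."""
    c = np.concatenate([[0.0], np.cumsum(x * x)])
    lo = np.maximum(np.arange(1, len(x) + 1) - win, 0)
    counts = np.arange(1, len(x) + 1) - lo
    return np.sqrt((c[1:] - c[lo]) / counts)


def extract_rt_from_wav(wav_path, onset_markers, rms_window_s=RMS_WINDOW_S,
                        threshold_factor=THRESHOLD_FACTOR) -> pd.DataFrame:
    """Voice-onset RTs from a response recording.

    For each marked stimulus onset, the RT is the time from the onset
    sample to the first sample at which the short-window RMS envelope
    exceeds ``threshold_factor`` times the file's first-decile RMS (a
    silence-floor estimate). A window with no burst before the next onset
    yields a missing RT.

    ``onset_markers`` is a sequence of onset samples or a DataFrame with an
    ``onset_sample`` column (and optionally ``trial``).

    Returns a DataFrame (trial, onset_sample, rt_ms).
    """
    try:
        fs, x = wavfile.read(wav_path)
    except (OSError, ValueError) as e:
        raise DataError(f"cannot read WAV {wav_path}: {e}") from e
    if x.ndim != 1:
        raise DataError("expected mono audio")
    x = x.astype(float) / 32768.0
    if isinstance(onset_markers, pd.DataFrame):
        onsets = onset_markers["onset_sample"].to_numpy(dtype=int)
        trials = (onset_markers["trial"].to_numpy()
                  if "trial" in onset_markers else np.arange(1, len(onsets) + 1))
    else:
        onsets = np.asarray(onset_markers, dtype=int)
        trials = np.arange(1, len(onsets) + 1)
    if len(onsets) == 0:
        raise MarkerError("no onset markers supplied")
    if np.any(np.diff(onsets) < 0):
        raise MarkerError("onset markers must be sorted")
    if onsets[-1] >= len(x) or onsets[0] < 0:
        raise MarkerError("onset marker beyond file bounds")

    win = max(int(round(rms_window_s * fs)), 1)
    env = _moving_rms(x, win)
    floor = np.quantile(env, 0.10)
    thr = threshold_factor * max(floor, 1e-8)
    above = env >= thr
    rows = []
    bounds = list(onsets[1:]) + [len(x)]
    for tr, onset, end in zip(trials, onsets, bounds):
        seg = above[onset:end]
        hit = np.flatnonzero(seg)
        rt = float(hit[0]) / fs * 1000.0 if hit.size else np.nan
        rows.append({"trial": tr, "onset_sample": int(onset), "rt_ms": rt})
    return pd.DataFrame(rows)


def accuracy_gate(trials: pd.DataFrame, threshold: float = ACCURACY_GATE):
    """Per-participant accuracy gate over target trials only.

    Returns a DataFrame (participant, n_target, prop_correct, passed);
    passing requires proportion correct strictly above ``threshold``.
    Participants with zero target trials are flagged (``passed`` NA).
    """
    tg = trials[trials["trial_type"] == "target"]
    rows = []
    for part, g in trials.groupby("participant", sort=True):
        gt = tg[tg["participant"] == part]
        n = len(gt)
        if n == 0:
            rows.append({"participant": part, "n_target": 0,
                         "prop_correct": np.nan, "passed": pd.NA})
            continue
        p = float(gt["correct"].mean())
        rows.append({"participant": part, "n_target": n, "prop_correct": p,
                     "passed": bool(p > threshold)})
    return pd.DataFrame(rows)


def filter_rts(trials: pd.DataFrame, min_rt_ms: float = MIN_RT_MS):
    """Drop trials with RT below ``min_rt_ms`` (>= is retained).

    Returns ``(retained, n_removed)``; missing RTs are also dropped and
    counted.
    """
    rt = trials["rt_ms"].to_numpy(dtype=float)
    keep = rt >= min_rt_ms
    return trials[keep].copy(), int((~keep).sum())


def block_order_z(blocks: pd.Series) -> pd.Series:
    """Standardize block order to mean 0, SD 1 (population SD)."""
    b = blocks.astype(float)
    sd = b.std(ddof=0)
    if sd == 0:
        return b * 0.0
    return (b - b.mean()) / sd


def compute_ie(trials: pd.DataFrame) -> pd.DataFrame:
    """Inverse-efficiency entries: RT / block proportion correct.

    For each participant x session x block, p = proportion correct over that
    block's target trials (incorrect trials count in the denominator but
    contribute no IE entry). Blocks with p = 0 are dropped with a warning
    column in the log. The block order is standardized within participant x
    session (``block_order_z``).
    """
    tg = trials[trials["trial_type"] == "target"].copy()
    if tg.empty:
        raise DataError("no target trials")
    keys = ["participant", "session", "block"]
    acc = tg.groupby(keys)["correct"].mean().rename("block_accuracy")
    tg = tg.merge(acc.reset_index(), on=keys)
    tg = tg[tg["block_accuracy"] > 0]
    out = tg[tg["correct"]].copy()
    out["ie"] = out["rt_ms"] / out["block_accuracy"]
    # standardize the *distinct* block numbers within participant x session
    # (each block counts once, however many trials it retains)
    zmaps = {}
    for key, d in out.groupby(["participant", "session"]):
        blocks = np.sort(d["block"].unique()).astype(float)
        zmaps[key] = dict(zip(blocks, block_order_z(pd.Series(blocks))))
    out["block_order_z"] = [
        zmaps[(p, s)][float(b)] for p, s, b in
        zip(out["participant"], out["session"], out["block"])]
    cols = ["participant", "group", "session", "block", "block_order_z",
            "condition", "laterality", "congruency", "rt_ms",
            "block_accuracy", "ie"]
    return out[[c for c in cols if c in out.columns]].reset_index(drop=True)


def remove_outliers(values, scope: pd.Series | None = None,
                    n_sd: float = 2.5):
    """Single-pass outlier cut at mean +/- n_sd SD, bounds included.

    ``values`` may be a Series/array; mean and SD are computed once on the
    input (globally, or within the groups of ``scope`` when given).
    Constant input (SD = 0) removes nothing. Returns ``(mask, fraction
    removed)`` where ``mask`` is True for retained values.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("need at least 2 values")

    def _mask(x):
        mu, sd = x.mean(), x.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            return np.ones(x.size, dtype=bool)
        return (x >= mu - n_sd * sd) & (x <= mu + n_sd * sd)

    if scope is None:
        mask = _mask(v)
    else:
        mask = np.ones(v.size, dtype=bool)
        codes = pd.Series(scope).to_numpy()
        for s in pd.unique(codes):
            idx = codes == s
            if idx.sum() >= 2:
                mask[idx] = _mask(v[idx])
    return mask, float(1.0 - mask.mean())


def recode_feedback(feedback: pd.DataFrame) -> pd.DataFrame:
    """Yes/no movement reports to 0/1 accuracy against the motion state.

    1 iff the reported state matches the actual Motion condition; missing
    responses are flagged and excluded.
    """
    fb = feedback.copy()
    resp = fb["response"].astype("string").str.lower()
    missing = (resp.isna() | ~resp.isin(["yes", "no"])).to_numpy()
    moved = fb["motion"].astype(str).str.lower().str.startswith(
        "mobil").to_numpy()
    said_yes = (resp == "yes").fillna(False).to_numpy()
    fb["accuracy"] = np.where(said_yes == moved, 1.0, 0.0)
    fb.loc[missing, "accuracy"] = np.nan
    fb["missing"] = missing
    return fb[~missing].copy()


def merge_baseline_followup(ie: pd.DataFrame) -> pd.DataFrame:
    """Relabel blocks 1 and 8 as the single "NoStimulation" condition.

    Values are untouched; row count is unchanged. A table lacking block 8
    is relabelled on block 1 alone (partial input).
    """
    out = ie.copy()
    out.loc[out["block"].isin([1, 8]), "condition"] = "NoStimulation"
    return out


@dataclass
class CascadeLog:
    """What each preprocessing stage removed."""

    gate_failures: list = field(default_factory=list)
    n_rt_removed: int = 0
    n_blocks_zero_accuracy: int = 0
    outlier_fraction: float = 0.0
    n_input_trials: int = 0
    n_ie_entries: int = 0

    def to_dict(self):
        return {
            "gate_failures": list(self.gate_failures),
            "n_rt_removed": self.n_rt_removed,
            "outlier_fraction": self.outlier_fraction,
            "n_input_trials": self.n_input_trials,
            "n_ie_entries": self.n_ie_entries,
        }


def preprocess(trials: pd.DataFrame, outlier_scope: str = "global"):
    """Run the full cascade: gate -> RT filter -> IE -> outlier removal.

    ``outlier_scope`` is "global" (mean/SD over the whole IE set, the
    default) or "participant". Returns ``(ie_table, CascadeLog)``.
    """
    log = CascadeLog(n_input_trials=len(trials))
    gate = accuracy_gate(trials)
    failed = set(gate[gate["passed"] == False]["participant"])  # noqa: E712
    log.gate_failures = sorted(failed)
    kept = trials[~trials["participant"].isin(failed)]
    kept, log.n_rt_removed = filter_rts(kept)
    ie = compute_ie(kept)
    scope = ie["participant"] if outlier_scope == "participant" else None
    mask, frac = remove_outliers(ie["ie"], scope=scope)
    log.outlier_fraction = frac
    ie = ie[mask].reset_index(drop=True)
    log.n_ie_entries = len(ie)
    return ie, log
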