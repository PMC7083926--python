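"""Autonomic indices: skin-conductance level range and log RSA.

Two indices per 2-minute video epoch: the SCL range (max - min of the
low-pass-filtered skin-conductance trace, an orthosympathetic arousal
measure) and the natural log of the respiratory sinus arrhythmia (RSA, a
vagal-tone measure). RSA uses the peak-valley method: within each
respiratory cycle, the excursion between the longest and shortest
inter-beat interval; the index is the log of the mean excursion over
cycles.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .errors import (DataError, DegenerateSignalError,
                     InsufficientDataError)
from .synth import PhysioRecording

__all__ = ["scl_index", "detect_beats", "rsa_index", "read_physio_csv",
           "physio_indices"]

SCL_CUTOFF_HZ = 40.0
IBI_MIN_S = 0.3
IBI_MAX_S = 2.0


def read_physio_csv(path) -> PhysioRecording:
    """Read a trace CSV written by the generator (header line declares the
    sample rate, then time_s, scl, ppg, resp columns)."""
    path = Path(path)
    with path.open() as fh:
        first = fh.readline().strip()
        if not first.startswith("# sample_rate_hz="):
            raise DataError(f"{path}: missing sample-rate header")
        fs = float(first.split("=", 1)[1])
        df = pd.read_csv(fh)
    dur = len(df) / fs
    return PhysioRecording(scl=df["scl"].to_numpy(float),
                           ppg=df["ppg"].to_numpy(float),
                           resp=df["resp"].to_numpy(float),
                           sample_rate=fs, window=(0.0, dur))


def _window_slice(n: int, fs: float, window) -> slice:
    lo = int(round(window[0] * fs))
    hi = int(round(window[1] * fs))
    lo, hi = max(lo, 0), min(hi, n)
    if hi <= lo:
        raise DataError("empty analysis window")
    return slice(lo, hi)


def scl_index(scl: np.ndarray, sample_rate: float,
              window: tuple | None = None,
              cutoff_hz: float = SCL_CUTOFF_HZ) -> float:
    """SCL range: zero-phase 40 Hz low-pass, then max - min in the window.

    The 4th-order Butterworth filter is skipped (with a warning) when the
    sample rate cannot represent the cutoff (fs <= 2 * cutoff).
    """
    x = np.asarray(scl, dtype=float)
    if window is not None:
        x = x[_window_slice(len(x), sample_rate, window)]
    if x.size == 0:
        raise DataError("empty SCL window")
    if sample_rate > 2.0 * cutoff_hz:
        b, a = signal.butter(4, cutoff_hz, fs=sample_rate)
        # Gustafsson forward-backward filtering minimizes edge transients;
        # a short guard band drops what remains of them
        x = signal.filtfilt(b, a, x, method="gust")
        guard = int(round(0.020 * sample_rate))
        if x.size > 4 * guard:
            x = x[guard:x.size - guard]
    else:
        warnings.warn(f"sample rate {sample_rate} Hz too low for a "
                      f"{cutoff_hz} Hz low-pass; filter skipped")
    return float(x.max() - x.min())


def detect_beats(ppg: np.ndarray, sample_rate: float):
    """Systolic peaks with a refractory constraint; returns beat times
    and inter-beat intervals (seconds).

    IBIs outside the physiologically plausible 0.3-2.0 s band are flagged
    (returned mask), not interpolated.

    Returns ``(beat_times_s, ibis_s, plausible_mask)``.
    """
    x = np.asarray(ppg, dtype=float)
    if x.size < int(2 * IBI_MIN_S * sample_rate):
        raise InsufficientDataError("trace shorter than two beats")
    height = x.min() + 0.5 * (x.max() - x.min())
    if x.max() == x.min():
        raise DataError("flat pulse trace: no peaks found")
    peaks, _ = signal.find_peaks(x, height=height,
                                 distance=max(int(IBI_MIN_S * sample_rate), 1))
    if peaks.size == 0:
        raise DataError("no pulse peaks found")
    # sub-sample refinement: parabola through the peak and its neighbours
    t_peak = peaks.astype(float)
    inner = (peaks > 0) & (peaks < len(x) - 1)
    p = peaks[inner]
    denom = x[p - 1] - 2.0 * x[p] + x[p + 1]
    ok = denom < 0
    shift = np.zeros(p.size)
    shift[ok] = 0.5 * (x[p - 1] - x[p + 1])[ok] / denom[ok]
    t_peak[inner] += np.clip(shift, -0.5, 0.5)
    beat_times = t_peak / sample_rate
    ibis = np.diff(beat_times)
    plaus = (ibis >= IBI_MIN_S) & (ibis <= IBI_MAX_S)
    return beat_times, ibis, plaus


def rsa_index(ibis: np.ndarray, resp: np.ndarray, sample_rate: float,
              ibi_times: np.ndarray | None = None) -> float:
    """ln RSA by the peak-valley method.

    Respiratory cycles are segmented at rising zero crossings of the
    (mean-removed) respiration trace; each cycle with at least two beats
    contributes max(IBI) - min(IBI); the index is the natural log of the
    mean excursion. Zero variability is a degenerate signal.

    ``ibi_times`` places each interval in time (its end-beat time); when
    omitted, intervals are laid end to end from t = 0.
    """
    ibis = np.asarray(ibis, dtype=float)
    if ibi_times is None:
        ibi_times = np.cumsum(ibis)
    r = np.asarray(resp, dtype=float)
    r = r - r.mean()
    rising = np.flatnonzero((r[:-1] < 0) & (r[1:] >= 0))
    cross_t = rising / sample_rate
    if cross_t.size < 3:
        raise InsufficientDataError("fewer than 2 complete respiratory "
                                    "cycles")
    # IBI attributed to the interval's end beat
    t_ibi = np.asarray(ibi_times, dtype=float)
    excursions = []
    for lo, hi in zip(cross_t[:-1], cross_t[1:]):
        sel = ibis[(t_ibi >= lo) & (t_ibi < hi)]
        if sel.size >= 2:
            excursions.append(float(sel.max() - sel.min()))
    if len(excursions) < 2:
        raise InsufficientDataError("fewer than 2 respiratory cycles with "
                                    ">= 2 beats")
    mean_exc = float(np.mean(excursions))
    if mean_exc <= 0.0:
        raise DegenerateSignalError("no inter-beat variability within "
                                    "respiratory cycles")
    return float(np.log(mean_exc))


def physio_indices(rec: PhysioRecording) -> dict:
    """Both indices for one recording epoch."""
    out = {"scl_range": scl_index(rec.scl, rec.sample_rate, rec.window)}
    beat_times, ibis, plaus = detect_beats(rec.ppg, rec.sample_rate)
    try:
        out["ln_rsa"] = rsa_index(ibis[plaus], rec.resp, rec.sample_rate,
                                  ibi_times=beat_times[1:][plaus])
    except (InsufficientDataError, DegenerateSignalError):
        out["ln_rsa"] = np.nan
    return out
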