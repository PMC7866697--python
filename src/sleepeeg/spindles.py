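"""Automated sleep-spindle detection.

The detector band-limits the EEG to the 10-15 Hz spindle range (10-15 Hz
bandpass cascaded with a Butterworth design specified by its stopband and
passband corners, applied zero-phase), smooths with a 750-ms sliding RMS,
cubes the envelope to sharpen the signal-to-noise ratio, and thresholds:
the start/end of a spindle are crossings of 1.2 x the mean cubed envelope
and a detection must also exceed 3.5 x the mean at its peak.  Events must
be strictly longer than 0.5 s and strictly shorter than 10 s.

Because both thresholds are multiples of the recording's own mean, the
detector is invariant to global amplitude scaling of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "SpindleParams",
    "Spindle",
    "spindle_band_filter",
    "rms_envelope",
    "cube_signal",
    "detect_spindles",
    "detect_spindles_in_eeg",
    "spindle_metrics",
]


@dataclass(frozen=True)
class SpindleParams:
    band_hz: tuple[float, float] = (10.0, 15.0)
    # Butterworth design corners: stopband 3 Hz / passband 10-15 Hz /
    # stopband 22 Hz with 24 dB stopband attenuation
    stopband1_hz: float = 3.0
    passband1_hz: float = 10.0
    passband2_hz: float = 15.0
    stopband2_hz: float = 22.0
    attenuation_db: float = 24.0
    passband_ripple_db: float = 3.0
    rms_window_ms: float = 750.0
    lower_mult: float = 1.2
    upper_mult: float = 3.5
    min_dur_s: float = 0.5
    max_dur_s: float = 10.0

    def __post_init__(self) -> None:
        if not (0 < self.lower_mult < self.upper_mult):
            raise ValueError("need 0 < lower_mult < upper_mult")
        if not (0 < self.min_dur_s < self.max_dur_s):
            raise ValueError("need 0 < min_dur_s < max_dur_s")
        if not (
            self.stopband1_hz < self.passband1_hz < self.passband2_hz < self.stopband2_hz
        ):
            raise ValueError("filter corners must be strictly ordered")


@dataclass
class Spindle:
    start_s: float
    end_s: float
    peak_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def spindle_band_filter(
    eeg: np.ndarray, fs: float, params: SpindleParams | None = None
) -> np.ndarray:
    """Zero-phase cascade of the 10-15 Hz bandpass and the corner-specified
    Butterworth design; partially redundant by construction, applied as two
    stages on purpose."""
    params = params or SpindleParams()
    if fs <= 2 * params.stopband2_hz:
        raise ValueError(
            f"fs={fs} too low for a {params.stopband2_hz} Hz stopband edge"
        )
    sos_bp = sps.butter(4, params.band_hz, btype="bandpass", fs=fs, output="sos")
    order, wn = sps.buttord(
        wp=[params.passband1_hz, params.passband2_hz],
        ws=[params.stopband1_hz, params.stopband2_hz],
        gpass=params.passband_ripple_db,
        gstop=params.attenuation_db,
        fs=fs,
    )
    sos_design = sps.butter(order, wn, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos_bp, np.asarray(eeg, dtype=float))
    return sps.sosfiltfilt(sos_design, x)


def rms_envelope(filtered: np.ndarray, fs: float, rms_window_ms: float = 750.0) -> np.ndarray:
    """Centered sliding-window RMS, same length as the input.

    Edges use shrunken windows (the running mean of the squared signal is
    normalized by the actual number of samples in the window).
    """
    x = np.asarray(filtered, dtype=float)
    w = int(round(rms_window_ms / 1000.0 * fs))
    if w < 1 or w > x.size:
        raise ValueError("RMS window must be >= 1 sample and <= signal length")
    # centered running mean of x^2 via cumulative sums (O(n))
    half_l = w // 2
    half_r = w - half_l  # window covers [i - half_l, i + half_r)
    c = np.concatenate(([0.0], np.cumsum(x**2)))
    n = x.size
    i0 = np.clip(np.arange(n) - half_l, 0, n)
    i1 = np.clip(np.arange(n) + half_r, 0, n)
    return np.sqrt((c[i1] - c[i0]) / (i1 - i0))


def cube_signal(envelope: np.ndarray) -> np.ndarray:
    """Pointwise third power; order-preserving on the nonnegative envelope."""
    env = np.asarray(envelope, dtype=float)
    if np.any(env < 0):
        raise ValueError("envelope must be nonnegative")
    return env**3


def detect_spindles(
    cubed_envelope: np.ndarray, fs: float, params: SpindleParams | None = None
) -> list[Spindle]:
    """Threshold the cubed envelope into spindle events.

    Candidates are maximal intervals strictly above ``lower_mult x mean``;
    a candidate is kept iff its maximum exceeds ``upper_mult x mean`` and
    ``min_dur_s < duration < max_dur_s`` (strict).  The peak is the argmax
    within the interval.
    """
    params = params or SpindleParams()
    env = np.asarray(cubed_envelope, dtype=float)
    if env.size == 0:
        raise ValueError("empty envelope")
    baseline = float(env.mean())
    if baseline <= 0:
        return []
    lower = params.lower_mult * baseline
    upper = params.upper_mult * baseline

    above = env > lower
    if not np.any(above):
        return []
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(env.size)

    out: list[Spindle] = []
    for i0, i1 in zip(starts, ends):
        dur = (i1 - i0) / fs
        if not (params.min_dur_s < dur < params.max_dur_s):
            continue
        seg = env[i0:i1]
        if seg.max() <= upper:
            continue
        peak = i0 + int(np.argmax(seg))
        out.append(Spindle(i0 / fs, i1 / fs, peak / fs))
    return out


def detect_spindles_in_eeg(
    eeg: np.ndarray, fs: float, params: SpindleParams | None = None
) -> list[Spindle]:
    """Filter -> RMS envelope -> cube -> threshold, in one call."""
    params = params or SpindleParams()
    filtered = spindle_band_filter(eeg, fs, params)
    env = rms_envelope(filtered, fs, params.rms_window_ms)
    return detect_spindles(cube_signal(env), fs, params)


def spindle_metrics(spindles: list[Spindle], total_sleep_s: float) -> dict:
    """Raw count and count per hour of sleep (NaN when no sleep time)."""
    count = len(spindles)
    if total_sleep_s > 0:
        rate = count / (total_sleep_s / 3600.0)
    else:
        rate = float("nan")
    return {"count": count, "count_per_sleep_hour": rate}


def spindles_to_frame(spindles: list[Spindle]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "start_s": s.start_s,
                "end_s": s.end_s,
                "peak_s": s.peak_s,
                "duration_s": s.duration_s,
            }
            for s in spindles
        ],
        columns=["start_s", "end_s", "peak_s", "duration_s"],
    )
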