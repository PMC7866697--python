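"""Two-pass epileptiform spike counting.

Pipeline: trim recording edges -> segment EEG into 30-s windows -> first
pass marks any sample beyond ``sd_mult`` standard deviations from the
window mean ("amplitude" is the signed sample value, excursions judged
two-sided) -> second pass confirms a candidate as a peak only if the
``flank_pts`` samples on each side are strictly monotone toward/away from
it, in the direction of the excursion -> windows containing any activity
above the threshold are excluded entirely (movement artifact) -> count.

Counts from recordings of different durations are not comparable, so the
result always carries an hours-analyzed and rate-per-hour field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import Recording, trim_edges

__all__ = [
    "SpikeParams",
    "SpikeResult",
    "window_amplitude_stats",
    "demarcate_candidates",
    "confirm_peaks",
    "exclude_active_windows",
    "count_spikes",
]


@dataclass(frozen=True)
class SpikeParams:
    window_s: float = 30.0
    sd_mult: float = 2.5
    flank_pts: int = 3
    trim_head_h: float = 3.0
    trim_tail_h: float = 3.0
    activity_threshold: float = 0.0  # any count above this flags the window
    merge_radius_s: float = 0.02  # refractory merge of confirmed candidates

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if self.sd_mult <= 0:
            raise ValueError("sd_mult must be > 0")
        if self.flank_pts < 1:
            raise ValueError("flank_pts must be >= 1")


@dataclass
class SpikeResult:
    """Total count plus the per-event table and normalization fields."""

    events: pd.DataFrame  # columns: time_s, amplitude_uv, window_index
    total_count: int
    hours_analyzed: float
    rate_per_h: float
    n_windows_total: int
    n_windows_excluded: int


def window_amplitude_stats(
    eeg: np.ndarray, fs: float, window_s: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window (mean, sd) of the signed amplitude.

    Trailing samples that do not fill a complete window are discarded.
    """
    wlen = int(round(window_s * fs))
    n_win = eeg.size // wlen
    if n_win < 1:
        raise ValueError(f"signal shorter than one {window_s}-s window")
    x = np.asarray(eeg[: n_win * wlen], dtype=float).reshape(n_win, wlen)
    return x.mean(axis=1), x.std(axis=1)


def demarcate_candidates(
    eeg_window: np.ndarray, mean: float, sd: float, sd_mult: float = 2.5
) -> np.ndarray:
    """Indices whose amplitude deviates more than ``sd_mult`` SD from the mean."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return np.array([], dtype=int)
    return np.flatnonzero(np.abs(np.asarray(eeg_window) - mean) > sd_mult * sd)


def _strictly_monotone_peak(x: np.ndarray, i: int, flank: int, positive: bool) -> bool:
    before = x[i - flank : i + 1]
    after = x[i : i + flank + 1]
    if positive:
        return bool(np.all(np.diff(before) > 0) and np.all(np.diff(after) < 0))
    return bool(np.all(np.diff(before) < 0) and np.all(np.diff(after) > 0))


def confirm_peaks(
    eeg_window: np.ndarray,
    candidate_indices: np.ndarray,
    flank_pts: int = 3,
    mean: float | None = None,
) -> list[int]:
    """Keep candidates whose flanks rise strictly to and fall strictly from
    the candidate (mirrored for negative excursions).

    Candidates within ``flank_pts`` of a window edge are dropped; ties in
    the flanks break toward rejection (strict monotonicity).
    """
    x = np.asarray(eeg_window, dtype=float)
    mu = float(x.mean()) if mean is None else mean
    out: list[int] = []
    for i in np.asarray(candidate_indices, dtype=int):
        if i < flank_pts or i >= x.size - flank_pts:
            continue
        if _strictly_monotone_peak(x, i, flank_pts, positive=x[i] >= mu):
            out.append(int(i))
    return out


def exclude_active_windows(
    n_windows: int,
    window_s: float,
    activity: np.ndarray,
    activity_fs: float,
    threshold: float = 0.0,
) -> np.ndarray:
    """Indices of windows with no activity sample above ``threshold``."""
    act = np.asarray(activity, dtype=float)
    wlen = window_s * activity_fs
    keep = []
    for w in range(n_windows):
        i0 = int(round(w * wlen))
        i1 = int(round((w + 1) * wlen))
        if not np.any(act[i0:i1] > threshold):
            keep.append(w)
    return np.array(keep, dtype=int)


def _merge_refractory(events: list[tuple[float, float, int]], radius_s: float):
    """Collapse confirmed candidates closer than ``radius_s`` into one event,
    keeping the largest-magnitude sample."""
    if not events:
        return events
    merged = [events[0]]
    for ev in events[1:]:
        if ev[0] - merged[-1][0] <= radius_s:
            if abs(ev[1]) > abs(merged[-1][1]):
                merged[-1] = ev
        else:
            merged.append(ev)
    return merged


def count_spikes(rec: Recording, params: SpikeParams | None = None) -> SpikeResult:
    """Full spike-count pipeline on one recording; deterministic."""
    params = params or SpikeParams()
    if params.trim_head_h or params.trim_tail_h:
        rec = trim_edges(rec, params.trim_head_h, params.trim_tail_h)

    fs = rec.eeg_fs
    wlen = int(round(params.window_s * fs))
    means, sds = window_amplitude_stats(rec.eeg, fs, params.window_s)
    n_win = means.size

    kept = exclude_active_windows(
        n_win, params.window_s, rec.activity, rec.activity_fs, params.activity_threshold
    )
    kept_set = set(kept.tolist())

    events: list[tuple[float, float, int]] = []
    for w in range(n_win):
        if w not in kept_set:
            continue
        seg = rec.eeg[w * wlen : (w + 1) * wlen]
        cands = demarcate_candidates(seg, means[w], sds[w], params.sd_mult)
        if cands.size == 0:
            continue
        confirmed = confirm_peaks(seg, cands, params.flank_pts, mean=means[w])
        for i in confirmed:
            events.append(((w * wlen + i) / fs, float(seg[i]), w))

    events = _merge_refractory(sorted(events), params.merge_radius_s)
    df = pd.DataFrame(events, columns=["time_s", "amplitude_uv", "window_index"])
    hours = len(kept_set) * params.window_s / 3600.0
    rate = len(df) / hours if hours > 0 else float("nan")
    return SpikeResult(
        events=df,
        total_count=len(df),
        hours_analyzed=hours,
        rate_per_h=rate,
        n_windows_total=n_win,
        n_windows_excluded=n_win - len(kept_set),
    )
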