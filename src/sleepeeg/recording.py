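"""Core data model for telemetry recordings and clock/light-cycle conventions.

A :class:`Recording` bundles the three channels emitted by the wireless
implant telemetry (EEG, EMG, activity) together with their sampling rates
and the wall-clock hour at which the recording started.  All analysis
stages consume this container.

Time convention: seconds from recording start; intervals are half-open
``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "LightDarkScheme",
    "preprocess_eeg",
    "trim_edges",
    "clock_hour_of",
]


@dataclass
class Recording:
    """Multichannel physiological signal container.

    Parameters
    ----------
    eeg, emg : ndarray
        Signals in microvolts.
    activity : ndarray
        Integer movement counts; nonzero means movement was detected.
    eeg_fs, emg_fs, activity_fs : float
        Sampling rates in Hz.
    start_clock_h : float
        Hour-of-day in ``[0, 24)`` at the first sample.
    """

    eeg: np.ndarray
    emg: np.ndarray
    activity: np.ndarray
    eeg_fs: float = 500.0
    emg_fs: float = 500.0
    activity_fs: float = 200.0
    start_clock_h: float = 0.0
    subject_id: str = "subject"
    group_label: str = ""

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        self.emg = np.asarray(self.emg, dtype=np.float64)
        self.activity = np.asarray(self.activity, dtype=np.float64)
        for name in ("eeg_fs", "emg_fs", "activity_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.eeg.size == 0:
            raise ValueError("recording must contain at least one EEG sample")
        d_eeg = self.eeg.size / self.eeg_fs
        d_emg = self.emg.size / self.emg_fs
        if abs(d_eeg - d_emg) > 1.0 / min(self.eeg_fs, self.emg_fs) + 1e-9:
            raise ValueError(
                "EEG and EMG must cover the same duration "
                f"(got {d_eeg:.3f} s vs {d_emg:.3f} s)"
            )
        self.start_clock_h = float(self.start_clock_h) % 24.0

    @property
    def duration_s(self) -> float:
        """Recording duration in seconds (from the EEG channel)."""
        return self.eeg.size / self.eeg_fs

    @property
    def duration_h(self) -> float:
        return self.duration_s / 3600.0


@dataclass(frozen=True)
class LightDarkScheme:
    """Clock partition into light and dark phases.

    The light interval is the half-open clock window
    ``[lights_on_h, lights_off_h)``; dark is its complement in ``[0, 24)``.
    Defaults follow the vivarium schedule of lights on 7 a.m. to 7 p.m.
    """

    lights_on_h: float = 7.0
    lights_off_h: float = 19.0

    def __post_init__(self) -> None:
        if self.lights_on_h % 24 == self.lights_off_h % 24:
            raise ValueError("lights_on_h and lights_off_h must differ")

    def is_light(self, clock_h: float | np.ndarray) -> bool | np.ndarray:
        """Whether a clock hour-of-day falls in the light phase."""
        h = np.asarray(clock_h, dtype=float) % 24.0
        on = self.lights_on_h % 24.0
        off = self.lights_off_h % 24.0
        if on < off:
            out = (h >= on) & (h < off)
        else:  # light interval wraps midnight
            out = (h >= on) | (h < off)
        return bool(out) if np.isscalar(clock_h) else out

    def cycle_of(self, clock_h: float) -> str:
        return "light" if self.is_light(clock_h) else "dark"


def clock_hour_of(sample_time_s: float | np.ndarray, start_clock_h: float) -> float | np.ndarray:
    """Map elapsed recording time to hour-of-day.

    ``(start_clock_h + t/3600) mod 24``.
    """
    t = np.asarray(sample_time_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("sample_time_s must be >= 0")
    out = (start_clock_h + t / 3600.0) % 24.0
    return float(out) if np.isscalar(sample_time_s) else out


def preprocess_eeg(rec: Recording, cutoff_hz: float = 50.0, order: int = 4) -> np.ndarray:
    """Zero-phase low-pass of the EEG at ``cutoff_hz``.

    The acquisition chain band-limits the signal to the 0-50 Hz range of
    interest.  A true 0 Hz high-pass edge is a no-op (and the hardware
    already applied a 0.1 Hz high-pass), so only the low-pass half is
    realized here, as a 4th-order zero-phase Butterworth.
    """
    if rec.eeg_fs <= 2 * cutoff_hz:
        raise ValueError("eeg_fs must exceed twice the low-pass cutoff")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=rec.eeg_fs, output="sos")
    return sps.sosfiltfilt(sos, rec.eeg)


def trim_edges(rec: Recording, head_h: float, tail_h: float) -> Recording:
    """Drop ``head_h`` hours from the start and ``tail_h`` from the end.

    The analysis convention discards the settling periods at both ends of
    a recording (e.g. 3 h head + 3 h tail of a 24 h recording leaves an
    18 h window).  ``start_clock_h`` advances by ``head_h`` modulo 24.
    """
    if head_h < 0 or tail_h < 0:
        raise ValueError("trim amounts must be >= 0")
    if (head_h + tail_h) * 3600.0 >= rec.duration_s:
        raise ValueError(
            f"trim of {head_h}+{tail_h} h exceeds duration {rec.duration_h:.3f} h"
        )

    def cut(x: np.ndarray, fs: float) -> np.ndarray:
        i0 = int(round(head_h * 3600.0 * fs))
        i1 = x.size - int(round(tail_h * 3600.0 * fs))
        return x[i0:i1]

    return replace(
        rec,
        eeg=cut(rec.eeg, rec.eeg_fs),
        emg=cut(rec.emg, rec.emg_fs),
        activity=cut(rec.activity, rec.activity_fs),
        start_clock_h=(rec.start_clock_h + head_h) % 24.0,
    )
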