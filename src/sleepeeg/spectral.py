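"""Welch power spectral density, band powers and delta summaries.

Band power is, by default, the plain sum of the PSD bins falling in the
band ("adding the density data"), not a trapezoidal integral; pass
``integrate=True`` for a proper ``sum * df`` integration.  Bands are
half-open ``[low, high)`` except the top band, which is closed at 50 Hz.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import LightDarkScheme, Recording, clock_hour_of

__all__ = [
    "DEFAULT_BANDS",
    "BandScheme",
    "PowerSpectrum",
    "DeltaSummary",
    "welch_psd",
    "band_power",
    "delta_summary",
    "light_dark_psd",
]

#: conventional rodent EEG bands, Hz
DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (5.0, 9.0),
    "alpha": (9.0, 12.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 50.0),
}

TOTAL_RANGE = (0.5, 50.0)


@dataclass(frozen=True)
class BandScheme:
    """Named half-open frequency intervals; the top edge (50 Hz) is closed."""

    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def __post_init__(self) -> None:
        top = max(hi for _, hi in self.bands.values())
        for name, (lo, hi) in self.bands.items():
            if not (0 <= lo < hi <= 50.0):
                raise ValueError(f"band {name} [{lo},{hi}) outside [0, 50]")

    def mask(self, freqs: np.ndarray, name: str) -> np.ndarray:
        lo, hi = self.bands[name]
        top = max(h for _, h in self.bands.values())
        if hi == top:  # closed top edge
            return (freqs >= lo) & (freqs <= hi)
        return (freqs >= lo) & (freqs < hi)


@dataclass
class PowerSpectrum:
    freqs_hz: np.ndarray
    psd: np.ndarray  # uV^2/Hz

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs_hz.shape != self.psd.shape:
            raise ValueError("freqs and psd must have matching shapes")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        if np.any(self.psd < -1e-12):
            raise ValueError("psd must be nonnegative")

    @property
    def df(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])


@dataclass
class DeltaSummary:
    """Total delta power, total 0.5-50 Hz power, and their ratio."""

    total_delta: float
    total_power: float
    relative_delta: float


def welch_psd(
    signal: np.ndarray,
    fs: float,
    segment_s: float = 4.0,
    overlap_frac: float = 0.5,
) -> PowerSpectrum:
    """Welch PSD on Hann-windowed overlapping segments.

    Default 4-s segments give 0.25 Hz resolution, enough to resolve the
    0.5 Hz lower delta edge.
    """
    x = np.asarray(signal, dtype=float)
    nperseg = int(round(segment_s * fs))
    if x.size < nperseg:
        raise ValueError(
            f"signal of {x.size} samples shorter than one {nperseg}-sample segment"
        )
    noverlap = int(round(nperseg * overlap_frac))
    freqs, psd = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap, detrend="constant"
    )
    return PowerSpectrum(freqs, np.maximum(psd, 0.0))


def band_power(
    spectrum: PowerSpectrum,
    band: tuple[float, float] | str,
    scheme: BandScheme | None = None,
    integrate: bool = False,
) -> float:
    """Sum of PSD values whose frequency falls in the band.

    ``integrate=True`` multiplies by the grid step for a true integral.
    """
    scheme = scheme or BandScheme()
    if isinstance(band, str):
        mask = scheme.mask(spectrum.freqs_hz, band)
    else:
        lo, hi = band
        closed = hi >= max(h for _, h in scheme.bands.values())
        mask = (spectrum.freqs_hz >= lo) & (
            (spectrum.freqs_hz <= hi) if closed else (spectrum.freqs_hz < hi)
        )
    if not np.any(mask):
        warnings.warn("band contains no frequency bins", stacklevel=2)
        return 0.0
    total = float(np.sum(spectrum.psd[mask]))
    return total * spectrum.df if integrate else total


def delta_summary(
    spectrum: PowerSpectrum, scheme: BandScheme | None = None, integrate: bool = False
) -> DeltaSummary:
    """Total delta, total 0.5-50 Hz power and relative delta."""
    scheme = scheme or BandScheme()
    lo, hi = scheme.bands["delta"]
    total_delta = band_power(spectrum, (lo, hi), scheme, integrate=integrate)
    mask = (spectrum.freqs_hz >= TOTAL_RANGE[0]) & (spectrum.freqs_hz <= TOTAL_RANGE[1])
    total_power = float(np.sum(spectrum.psd[mask]))
    if integrate:
        total_power *= spectrum.df
    if total_power <= 0:
        raise ValueError("total power is zero; relative delta undefined")
    return DeltaSummary(total_delta, total_power, total_delta / total_power)


def light_dark_psd(
    rec: Recording,
    scheme: LightDarkScheme | None = None,
    segment_s: float = 4.0,
    overlap_frac: float = 0.5,
) -> dict[str, PowerSpectrum | None]:
    """Welch PSD computed separately over light-phase and dark-phase samples.

    The recording is cut at clock light/dark boundaries and Welch is run per
    contiguous same-cycle block (segments never straddle a boundary); the
    per-cycle spectrum is the segment-count-weighted average of its blocks.
    A cycle with no block long enough for one segment yields ``None``.
    """
    scheme = scheme or LightDarkScheme()
    fs = rec.eeg_fs
    n_sec = int(rec.duration_s)
    sec_clock = clock_hour_of(np.arange(n_sec, dtype=float), rec.start_clock_h)
    is_light = scheme.is_light(sec_clock)

    nperseg = int(round(segment_s * fs))
    accum: dict[str, list[tuple[np.ndarray, int]]] = {"light": [], "dark": []}
    # contiguous same-cycle blocks in seconds
    change = np.flatnonzero(np.diff(is_light.astype(int)) != 0) + 1
    bounds = [0, *change.tolist(), n_sec]
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        seg = rec.eeg[int(b0 * fs) : int(b1 * fs)]
        if seg.size < nperseg:
            continue
        ps = welch_psd(seg, fs, segment_s, overlap_frac)
        # number of Welch segments used, for weighting
        step = nperseg - int(round(nperseg * overlap_frac))
        k = 1 + (seg.size - nperseg) // step
        accum["light" if is_light[b0] else "dark"].append((ps.psd, k))

    out: dict[str, PowerSpectrum | None] = {}
    freqs = None
    for cycle in ("light", "dark"):
        blocks = accum[cycle]
        if not blocks:
            warnings.warn(f"no complete Welch segment in the {cycle} cycle", stacklevel=2)
            out[cycle] = None
            continue
        wsum = sum(k for _, k in blocks)
        psd = sum(p * k for p, k in blocks) / wsum
        if freqs is None:
            freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
        out[cycle] = PowerSpectrum(freqs, psd)
    return out
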