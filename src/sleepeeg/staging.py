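"""Rule-based sleep staging and sleep-architecture metrics.

EEG is segmented into 1-s windows; each second is classified into one of
four states from amplitude, spectral content and EMG tone:

* high EMG tone -> active wake;
* high EEG amplitude and delta-dominant spectrum -> slow-wave sleep;
* low amplitude and theta-over-delta spectrum -> paradoxical sleep;
* otherwise -> wake.

Seconds are then voted into 10-s epochs: an epoch takes the majority label
only when that label covers at least 50% of the epoch AND is the unique
mode; otherwise the epoch is unscored (excluded from analysis).  The
hypnogram feeds bout/latency/total-sleep metrics and clock-aligned 2-h bin
summaries with light/dark aggregation (720 possible 10-s scores per
complete 2-h bin).

The amplitude/EMG thresholds are multiples of the recording's own median
1-s RMS, so staging is invariant to global gain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .recording import LightDarkScheme, Recording, clock_hour_of
from .simulate import STAGES

__all__ = [
    "StageRuleParams",
    "SecondFeatures",
    "Hypnogram",
    "SleepMetrics",
    "BinSummary",
    "compute_second_features",
    "stage_second",
    "stage_recording",
    "score_epochs",
    "extract_bouts",
    "sleep_metrics",
    "bin_2h",
    "aggregate_cycles",
]

EPOCH_S = 10
SLEEP_STAGES = ("sws", "paradoxical")
AWAKE_STAGES = ("wake", "active_wake")


@dataclass(frozen=True)
class StageRuleParams:
    """Quantitative thresholds behind the qualitative staging rules.

    Multipliers apply to the recording median of the 1-s RMS.  These are
    calibration parameters validated against simulator ground truth.
    """

    amp_high_mult: float = 1.5
    emg_high_mult: float = 2.0
    delta_frac_min: float = 0.3
    theta_over_delta_min: float = 4.0

    def __post_init__(self) -> None:
        if min(self.amp_high_mult, self.emg_high_mult) <= 0:
            raise ValueError("multipliers must be > 0")
        if not (0 < self.delta_frac_min < 1):
            raise ValueError("delta_frac_min must be in (0, 1)")
        if self.theta_over_delta_min <= 0:
            raise ValueError("theta_over_delta_min must be > 0")


@dataclass
class SecondFeatures:
    """Per-1-s-window features used by the staging decision tree."""

    eeg_rms: np.ndarray
    delta_power: np.ndarray  # periodogram power in [0.5, 4) Hz
    theta_power: np.ndarray  # [5, 9) Hz
    total_power: np.ndarray  # [0.5, 50] Hz
    emg_rms: np.ndarray


@dataclass
class Hypnogram:
    """Ordered 10-s epoch labels with the start clock hour."""

    labels: np.ndarray  # over STAGES + ("unscored",)
    epoch_s: int = EPOCH_S
    start_clock_h: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)

    def __len__(self) -> int:
        return self.labels.size

    @property
    def duration_s(self) -> float:
        return self.labels.size * self.epoch_s

    def to_frame(self) -> pd.DataFrame:
        start_s = np.arange(len(self)) * float(self.epoch_s)
        return pd.DataFrame(
            {
                "epoch_index": np.arange(len(self)),
                "start_s": start_s,
                "clock_h": clock_hour_of(start_s, self.start_clock_h),
                "label": self.labels,
            }
        )


@dataclass
class SleepMetrics:
    mean_bout_s: dict  # per state
    latency_s: float  # NaN when no wake->sleep transition exists
    latency_paradoxical_s: float  # awake-run onset -> next paradoxical onset
    total_sleep_s: float
    n_bouts: dict


@dataclass
class BinSummary:
    """Counts of 10-s scores in one clock-aligned 2-h bin."""

    bin_start_clock_h: float
    cycle: str  # light | dark
    counts: dict  # per state + unscored + combined awake
    n_epochs: int  # epochs actually present
    possible: int = 720
    complete: bool = True
    percent: dict = field(default_factory=dict)  # of possible epochs
    percent_of_scored: dict = field(default_factory=dict)


def compute_second_features(rec: Recording) -> SecondFeatures:
    """Vectorized per-second EEG amplitude/band power and EMG RMS."""
    fs = int(round(rec.eeg_fs))
    n_sec = rec.eeg.size // fs
    x = rec.eeg[: n_sec * fs].reshape(n_sec, fs)
    eeg_rms = np.sqrt(np.mean(x**2, axis=1))

    spec = np.abs(np.fft.rfft(x, axis=1)) ** 2
    freqs = np.fft.rfftfreq(fs, d=1.0 / rec.eeg_fs)
    delta = spec[:, (freqs >= 0.5) & (freqs < 4.0)].sum(axis=1)
    theta = spec[:, (freqs >= 5.0) & (freqs < 9.0)].sum(axis=1)
    total = spec[:, (freqs >= 0.5) & (freqs <= 50.0)].sum(axis=1)

    emg_fs = int(round(rec.emg_fs))
    m_sec = rec.emg.size // emg_fs
    e = rec.emg[: m_sec * emg_fs].reshape(m_sec, emg_fs)
    emg_rms = np.sqrt(np.mean(e**2, axis=1))
    k = min(n_sec, m_sec)
    return SecondFeatures(eeg_rms[:k], delta[:k], theta[:k], total[:k], emg_rms[:k])


def stage_second(
    eeg_rms: float,
    delta_power: float,
    theta_power: float,
    total_power: float,
    emg_rms: float,
    params: StageRuleParams,
    amp_ref: float,
    emg_ref: float,
) -> str:
    """Classify one second; ``amp_ref``/``emg_ref`` are the recording
    medians of the corresponding 1-s RMS features."""
    if total_power <= 0 or (eeg_rms == 0 and emg_rms == 0):
        return "unscored"
    if emg_rms > params.emg_high_mult * emg_ref:
        return "active_wake"
    amp_high = eeg_rms > params.amp_high_mult * amp_ref
    if amp_high and delta_power / total_power >= params.delta_frac_min:
        return "sws"
    if not amp_high and delta_power > 0 and theta_power / delta_power >= params.theta_over_delta_min:
        return "paradoxical"
    return "wake"


def stage_recording(
    rec: Recording, params: StageRuleParams | None = None
) -> np.ndarray:
    """Per-second stage labels for a whole recording."""
    params = params or StageRuleParams()
    f = compute_second_features(rec)
    # amplitude reference from low-delta (non-slow-wave-like) seconds, so the
    # threshold survives recordings where slow-wave sleep is the majority
    with np.errstate(invalid="ignore", divide="ignore"):
        dfrac = np.where(f.total_power > 0, f.delta_power / f.total_power, 0.0)
    low_delta = dfrac < params.delta_frac_min
    if np.any(low_delta):
        amp_ref = float(np.median(f.eeg_rms[low_delta]))
    else:
        amp_ref = float(np.median(f.eeg_rms))
    emg_ref = float(np.median(f.emg_rms))
    if amp_ref == 0 or emg_ref == 0:
        # degenerate recording: fall back to tiny positive refs so the
        # zero-feature rule (unscored) still applies per second
        amp_ref = amp_ref or 1e-12
        emg_ref = emg_ref or 1e-12
    labels = np.empty(f.eeg_rms.size, dtype=object)
    for i in range(labels.size):
        labels[i] = stage_second(
            f.eeg_rms[i],
            f.delta_power[i],
            f.theta_power[i],
            f.total_power[i],
            f.emg_rms[i],
            params,
            amp_ref,
            emg_ref,
        )
    return labels


def score_epochs(
    per_second_labels: np.ndarray,
    epoch_s: int = EPOCH_S,
    majority_frac: float = 0.5,
    start_clock_h: float = 0.0,
) -> Hypnogram:
    """Vote 1-s labels into epochs.

    The epoch label is the modal second label if its share is at least
    ``majority_frac`` and the mode is unique; otherwise ``unscored``.  A
    trailing partial epoch is dropped.
    """
    labels = np.asarray(per_second_labels, dtype=object)
    n_epochs = labels.size // epoch_s
    if n_epochs < 1:
        raise ValueError("need at least one complete epoch")
    out = np.empty(n_epochs, dtype=object)
    for e in range(n_epochs):
        chunk = labels[e * epoch_s : (e + 1) * epoch_s]
        vals, counts = np.unique(chunk.astype(str), return_counts=True)
        order = np.argsort(counts)[::-1]
        top = counts[order[0]]
        unique_mode = len(order) == 1 or counts[order[1]] < top
        if top >= majority_frac * epoch_s and unique_mode and vals[order[0]] != "unscored":
            out[e] = str(vals[order[0]])
        else:
            out[e] = "unscored"
    return Hypnogram(out, epoch_s=epoch_s, start_clock_h=start_clock_h)


def extract_bouts(hyp: Hypnogram) -> dict:
    """Maximal runs of identical non-unscored labels, per state, as
    half-open (start_s, end_s); an unscored epoch terminates a bout."""
    bouts: dict[str, list[tuple[float, float]]] = {s: [] for s in STAGES}
    labels = hyp.labels
    i = 0
    while i < labels.size:
        lab = labels[i]
        j = i
        while j < labels.size and labels[j] == lab:
            j += 1
        if lab in bouts:
            bouts[lab].append((i * float(hyp.epoch_s), j * float(hyp.epoch_s)))
        i = j
    return bouts


def sleep_metrics(hyp: Hypnogram) -> SleepMetrics:
    """Mean bout duration per state, mean sleep latency and total sleep time.

    Latency averages, over every awake-run -> sleep-bout transition, the
    interval from the awake run's onset to the sleep bout's onset; either
    wake state may start the run.  With no such transition it is NaN.
    """
    if len(hyp) == 0:
        raise ValueError("empty hypnogram")
    bouts = extract_bouts(hyp)
    mean_bout = {
        s: (float(np.mean([e - st for st, e in bouts[s]])) if bouts[s] else float("nan"))
        for s in STAGES
    }
    n_bouts = {s: len(bouts[s]) for s in STAGES}
    total_sleep = float(
        sum(e - st for s in SLEEP_STAGES for st, e in bouts[s])
    )

    # awake runs: consecutive wake/active_wake epochs (either kind)
    latencies: list[float] = []
    par_latencies: list[float] = []
    labels = hyp.labels
    i = 0
    while i < labels.size:
        if labels[i] in AWAKE_STAGES:
            j = i
            while j < labels.size and labels[j] in AWAKE_STAGES:
                j += 1
            if j < labels.size and labels[j] in SLEEP_STAGES:
                latencies.append((j - i) * float(hyp.epoch_s))
            # latency to the next paradoxical onset after this awake run
            k = j
            while k < labels.size and labels[k] != "paradoxical":
                k += 1
            if k < labels.size:
                par_latencies.append((k - i) * float(hyp.epoch_s))
            i = max(j, i + 1)
        else:
            i += 1
    latency = float(np.mean(latencies)) if latencies else float("nan")
    par_latency = float(np.mean(par_latencies)) if par_latencies else float("nan")
    return SleepMetrics(mean_bout, latency, par_latency, total_sleep, n_bouts)


def bin_2h(hyp: Hypnogram, scheme: LightDarkScheme | None = None) -> list[BinSummary]:
    """Assign epochs to clock-aligned 2-h bins (0-2, 2-4, ... of the day).

    Counts of each state plus unscored are taken per bin; wake and active
    wake are additionally combined into an ``awake`` readout.  Percent is
    count over the 720 possible scores of a complete bin; partial first or
    last bins are flagged and their percent uses the actual epoch count.
    """
    scheme = scheme or LightDarkScheme()
    starts_s = np.arange(len(hyp)) * float(hyp.epoch_s)
    clock = clock_hour_of(starts_s, hyp.start_clock_h)
    bin_start = (np.floor(clock / 2.0) * 2.0) % 24.0
    # sequential bin id: increments whenever the clock-aligned bin changes
    change = np.flatnonzero(np.diff(bin_start) != 0) + 1
    bounds = [0, *change.tolist(), len(hyp)]

    possible = int(round(2 * 3600 / hyp.epoch_s))
    out: list[BinSummary] = []
    for b0, b1 in zip(bounds[:-1], bounds[1:]):
        chunk = hyp.labels[b0:b1]
        counts = {s: int(np.sum(chunk == s)) for s in STAGES}
        counts["unscored"] = int(np.sum(chunk == "unscored"))
        counts["awake"] = counts["wake"] + counts["active_wake"]
        n = b1 - b0
        complete = n == possible
        denom = possible if complete else n
        pct = {k: 100.0 * v / denom for k, v in counts.items()}
        scored = sum(counts[s] for s in STAGES)
        pct_scored = {
            k: (100.0 * counts[k] / scored if scored else float("nan")) for k in counts
        }
        out.append(
            BinSummary(
                bin_start_clock_h=float(bin_start[b0]),
                cycle=scheme.cycle_of(float(bin_start[b0])),
                counts=counts,
                n_epochs=n,
                possible=possible,
                complete=complete,
                percent=pct,
                percent_of_scored=pct_scored,
            )
        )
    return out


def aggregate_cycles(bins: list[BinSummary]) -> dict:
    """Per-cycle summed counts and epoch-weighted mean percents."""
    out: dict[str, dict] = {}
    for cycle in ("light", "dark"):
        sel = [b for b in bins if b.cycle == cycle]
        if not sel:
            continue
        keys = sel[0].counts.keys()
        counts = {k: sum(b.counts[k] for b in sel) for k in keys}
        n_epochs = sum(b.n_epochs for b in sel)
        percent = {
            k: (
                sum(b.percent[k] * b.n_epochs for b in sel) / n_epochs
                if n_epochs
                else float("nan")
            )
            for k in keys
        }
        out[cycle] = {"counts": counts, "percent": percent, "n_epochs": n_epochs}
    return out
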