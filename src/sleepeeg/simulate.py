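"""Synthetic telemetry generator with known ground truth.

Produces :class:`~sleepeeg.recording.Recording` objects whose EEG/EMG/activity
channels carry the statistical signatures every downstream analysis stage
assumes: a four-state sleep-wake architecture (active wake, wake, slow-wave
sleep, paradoxical sleep) driven by a semi-Markov bout schedule, stage
dependent band-limited EEG spectra, EMG tone tied to active wake, injected
epileptiform transients and 11 Hz spindle bursts, and a light/dark dwell
bias.  The generator's hidden state is returned as :class:`GroundTruth`, so
detector recall/precision and staging accuracy are directly measurable.

Stage signatures:

* slow-wave sleep - high-amplitude, delta-dominant EEG, low EMG tone;
* paradoxical sleep - low-amplitude, theta-dominant EEG, low EMG tone;
* wake - low-amplitude broadband EEG, low EMG tone;
* active wake - like wake but with high EMG tone and nonzero activity counts.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .recording import LightDarkScheme, Recording, clock_hour_of

__all__ = [
    "STAGES",
    "SimConfig",
    "GroundTruth",
    "simulate_stage_schedule",
    "synthesize_signals",
    "simulate_recording",
    "generate_cohort",
]

#: stage codes used throughout the package
STAGES = ("active_wake", "wake", "sws", "paradoxical")


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of one synthetic recording.

    Amplitudes are microvolt RMS targets; rates are strictly positive unless
    an event type is disabled by setting its rate to 0.
    """

    duration_h: float = 24.0
    eeg_fs: float = 500.0
    emg_fs: float = 500.0
    activity_fs: float = 200.0
    start_clock_h: float = 0.0
    lights_on_h: float = 7.0
    lights_off_h: float = 19.0
    # mean bout dwell per stage, seconds
    stage_mean_bout_s: dict = field(
        default_factory=lambda: {
            "active_wake": 240.0,
            "wake": 240.0,
            "sws": 420.0,
            "paradoxical": 90.0,
        }
    )
    stage_dwell_bias_dark: float = 2.0  # multiplier on wake dwell in the dark
    amp_sws: float = 80.0
    amp_wake: float = 20.0
    delta_gain: float = 1.0
    theta_gain: float = 1.5
    emg_tone_high: float = 60.0
    emg_tone_low: float = 8.0
    spike_rate_per_h: float = 10.0
    spike_amp_sd: float = 6.0
    spindle_rate_per_min_sws: float = 1.0
    spindle_freq: float = 11.0
    spindle_dur_s: tuple[float, float] = (0.6, 2.0)
    spindle_amp_mult: float = 5.0  # x in-band background RMS
    sigma_uv: float = 7.0  # stage-constant 9-16 Hz background RMS
    hf_noise_frac: float = 0.4  # wideband sensor noise, fraction of stage RMS
    paradoxical_entry_bias: float = 1.0  # multiplier on sws->paradoxical weight
    # paradoxical-sleep deficit controls: a drawn paradoxical bout keeps its
    # dwell draw but is scaled by dwell_factor, and with block_frac the
    # attempt fails entirely and wake of the drawn dwell is emitted instead
    # (fragmentation), leaving cycle structure and sws time unchanged
    paradoxical_dwell_factor: float = 1.0
    paradoxical_block_frac: float = 0.0
    seed: int = 0
    allowed_stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        if self.duration_h <= 0:
            raise ConfigurationError("duration_h must be > 0")
        for name in ("eeg_fs", "emg_fs", "activity_fs"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in (
            "stage_dwell_bias_dark",
            "amp_sws",
            "amp_wake",
            "delta_gain",
            "theta_gain",
            "emg_tone_high",
            "emg_tone_low",
            "spindle_freq",
            "spindle_amp_mult",
            "sigma_uv",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("spike_rate_per_h", "spindle_rate_per_min_sws", "hf_noise_frac"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if any(v <= 0 for v in self.stage_mean_bout_s.values()):
            raise ConfigurationError("stage mean bout durations must be > 0")
        if self.lights_on_h % 24 == self.lights_off_h % 24:
            raise ConfigurationError("lights_on_h must differ from lights_off_h")
        if not (10.0 <= self.spindle_freq <= 15.0):
            raise ConfigurationError("spindle_freq must lie in the 10-15 Hz band")
        if not self.allowed_stages or any(
            s not in STAGES for s in self.allowed_stages
        ):
            raise ConfigurationError(f"allowed_stages must be a subset of {STAGES}")
        lo, hi = self.spindle_dur_s
        if not (0 < lo <= hi):
            raise ConfigurationError("spindle_dur_s must satisfy 0 < min <= max")

    @property
    def duration_s(self) -> int:
        return int(round(self.duration_h * 3600))

    def light_dark(self) -> LightDarkScheme:
        return LightDarkScheme(self.lights_on_h, self.lights_off_h)


@dataclass
class GroundTruth:
    """Hidden state of one simulated recording."""

    stage_per_second: np.ndarray  # array of stage-name strings, one per second
    spike_times_s: np.ndarray  # sorted, seconds from start
    spindle_intervals_s: list[tuple[float, float]]  # sorted, disjoint
    group_label: str = ""

    def stage_seconds(self, stage: str) -> np.ndarray:
        """Indices of seconds spent in ``stage``."""
        return np.flatnonzero(self.stage_per_second == stage)


# ---------------------------------------------------------------------------
# stage schedule


def _dwell(rng: np.random.Generator, mean_s: float, min_s: float = 10.0) -> float:
    """Truncated-exponential bout dwell: ``min_s`` floor keeps bouts scorable."""
    return min_s + rng.exponential(max(mean_s - min_s, 1e-6))


def simulate_stage_schedule(config: SimConfig, rng_seed: int | None = None) -> np.ndarray:
    """Semi-Markov alternation of the four stages, one label per second.

    Paradoxical sleep is entered only from slow-wave sleep; wake dwell is
    inflated by ``stage_dwell_bias_dark`` while the clock is in the dark
    interval.  Bout dwells are truncated-exponential with a 10-s floor.
    """
    if config.duration_s <= 0:
        raise ConfigurationError("non-positive duration")
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    n = config.duration_s
    allowed = list(config.allowed_stages)
    if len(allowed) == 1:
        return np.array([allowed[0]] * n, dtype=object)

    scheme = config.light_dark()
    labels = np.empty(n, dtype=object)

    def next_stage(current: str) -> str:
        # paradoxical only reachable from sws; sws only from wake states
        if current == "sws":
            choices = [s for s in ("paradoxical", "wake", "active_wake") if s in allowed]
            weights = {
                "paradoxical": 0.45 * config.paradoxical_entry_bias,
                "wake": 0.35,
                "active_wake": 0.2,
            }
        elif current == "paradoxical":
            choices = [s for s in ("wake", "active_wake", "sws") if s in allowed]
            weights = {"wake": 0.45, "active_wake": 0.25, "sws": 0.3}
        else:  # wake or active_wake
            other_wake = "active_wake" if current == "wake" else "wake"
            choices = [s for s in ("sws", other_wake) if s in allowed]
            weights = {"sws": 0.6, other_wake: 0.4}
        if not choices:
            return current
        w = np.array([weights[c] for c in choices])
        return choices[rng.choice(len(choices), p=w / w.sum())]

    stage = "wake" if "wake" in allowed else allowed[0]
    t = 0
    while t < n:
        emit = stage
        mean = config.stage_mean_bout_s[stage]
        if stage in ("wake", "active_wake") and not scheme.is_light(
            clock_hour_of(float(t), config.start_clock_h)
        ):
            mean *= config.stage_dwell_bias_dark
        dwell = _dwell(rng, mean)
        if stage == "paradoxical":
            if rng.random() < config.paradoxical_block_frac and "wake" in allowed:
                emit = "wake"  # failed attempt: fragmentation instead of sleep
            else:
                dwell = max(dwell * config.paradoxical_dwell_factor, 10.0)
        dur = int(round(dwell))
        labels[t : t + dur] = emit
        t += dur
        stage = next_stage(stage)
    return labels[:n]


# ---------------------------------------------------------------------------
# signal synthesis

#: frequency of the steady background rhythm in the spindle range; kept
#: away from the 11 Hz spindle default so bursts stand out from it
SIGMA_BG_FREQ_HZ = 13.5

_BANDS = {  # component band edges (Hz) used to colour the EEG noise
    "delta": (0.5, 4.0),
    "theta": (5.0, 9.0),
    "sigma": (9.0, 16.0),  # spindle-range background, stage-constant rhythm
    "broad": (16.0, 100.0),  # up to the acquisition chain's hardware low-pass
    "hf": (100.0, 240.0),  # optional wideband sensor noise
}


def _component_weights(config: SimConfig) -> dict[str, dict[str, float]]:
    """Per-stage RMS weight of each noise component, in microvolts.

    The sigma (spindle-range) background is the same in every stage so the
    spindle detector sees a homogeneous in-band noise floor; the hf sensor
    noise scales with the stage RMS and lies entirely above the 50 Hz
    analysis band.
    """
    a_s, a_w = config.amp_sws, config.amp_wake
    s0 = config.sigma_uv
    w = {
        "sws": {
            "delta": a_s * config.delta_gain,
            "theta": 0.1 * a_s,
            "sigma": s0,
            "broad": 0.3 * a_s,
        },
        "paradoxical": {
            "delta": 0.25 * a_w,
            "theta": 0.7 * a_w * config.theta_gain,
            "sigma": s0,
            "broad": 0.3 * a_w,
        },
        "wake": {"delta": 0.25 * a_w, "theta": 0.25 * a_w, "sigma": s0, "broad": a_w},
        "active_wake": {"delta": 0.25 * a_w, "theta": 0.25 * a_w, "sigma": s0, "broad": a_w},
    }
    for stage, ws in w.items():
        ws["hf"] = config.hf_noise_frac * float(np.sqrt(sum(v**2 for v in ws.values())))
    # wake EEG is rough: a strong near-Nyquist component dominates
    # sample-to-sample differences, as in high-frequency desynchronized wake
    for stage in ("wake", "active_wake"):
        w[stage]["hf"] = max(w[stage]["hf"], 2.5 * config.hf_noise_frac * a_w)
    return w


def _stage_rms(config: SimConfig) -> dict[str, float]:
    w = _component_weights(config)
    return {s: float(np.sqrt(sum(v**2 for v in w[s].values()))) for s in w}


def _spike_waveform(fs: float, amp: float) -> np.ndarray:
    """40-ms biphasic transient: steep tent peak, then a shallow rebound.

    The piecewise-linear rise/fall gives strictly monotone 3-sample flanks
    around the peak with per-sample steps of amp/4, large against any
    background, so the detector's confirmation rule holds by construction.
    """
    n = max(int(round(0.04 * fs)), 16)
    peak = max(int(round(n * 0.15)), 3)  # steep rise
    trough = peak + max(int(round(n * 0.2)), 3)  # steep fall past baseline
    shape = np.zeros(n)
    shape[: peak + 1] = np.linspace(0.0, 1.0, peak + 1)
    shape[peak : trough + 1] = np.linspace(1.0, -0.5, trough - peak + 1)
    shape[trough:] = np.linspace(-0.5, 0.0, n - trough)
    return amp * shape


def synthesize_signals(
    schedule: np.ndarray, config: SimConfig, rng_seed: int | None = None
) -> tuple[Recording, GroundTruth]:
    """Render EEG/EMG/activity from a per-second stage schedule.

    EEG is a sum of band-limited Gaussian noise components whose weights
    depend on the current stage; EMG is white noise at the high tone during
    active wake and the low tone otherwise; activity counts are nonzero
    exactly during active-wake seconds.  Spikes and spindles are injected on
    top and recorded in the returned :class:`GroundTruth`.
    """
    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    n_sec = len(schedule)
    fs = config.eeg_fs
    spf = int(round(fs))  # samples per second

    weights = _component_weights(config)
    stage_rms = _stage_rms(config)

    # per-second weight lookup for each component
    wsec = {
        comp: np.array([weights[s][comp] for s in schedule], dtype=float)
        for comp in _BANDS
    }

    # band-limited unit-RMS noise via FFT brick-wall masking of white noise,
    # generated in hour-long chunks; exact band edges keep the components
    # from leaking into each other's bands
    eeg = np.empty(n_sec * spf)
    chunk_sec = 3600
    for s0 in range(0, n_sec, chunk_sec):
        s1 = min(s0 + chunk_sec, n_sec)
        m = (s1 - s0) * spf
        freqs = np.fft.rfftfreq(m, d=1.0 / fs)
        acc = np.zeros(m)
        for comp, (lo, hi) in _BANDS.items():
            if comp == "sigma":
                # steady spindle-range rhythm: constant envelope, so the
                # detector's in-band noise floor is flat and its
                # mean-relative thresholds are stable across recordings
                tt = (np.arange(s0 * spf, s1 * spf)) / fs
                band = np.sqrt(2.0) * np.sin(2 * np.pi * SIGMA_BG_FREQ_HZ * tt)
            else:
                white = rng.standard_normal(m)
                spec = np.fft.rfft(white)
                hi_eff = min(hi, fs / 2.0)
                if hi_eff <= lo:
                    continue
                mask = (freqs >= lo) & (freqs < hi_eff)
                band = np.fft.irfft(spec * mask, n=m)
                band /= np.sqrt((hi_eff - lo) / (fs / 2.0))  # back to unit RMS
            acc += band * np.repeat(wsec[comp][s0:s1], spf)
        eeg[s0 * spf : s1 * spf] = acc

    # EMG: white noise, tone set per second
    emg_spf = int(round(config.emg_fs))
    is_active = schedule == "active_wake"
    emg_tone = np.where(is_active, config.emg_tone_high, config.emg_tone_low)
    emg = rng.standard_normal(n_sec * emg_spf) * np.repeat(emg_tone, emg_spf)

    # activity: integer counts, nonzero iff active wake; first sample of each
    # active second forced >= 1 so the exclusion rule sees every such second
    act_spf = int(round(config.activity_fs))
    activity = np.zeros(n_sec * act_spf)
    if np.any(is_active):
        active_idx = np.flatnonzero(is_active)
        counts = rng.poisson(0.5, size=(active_idx.size, act_spf)).astype(float)
        counts[:, 0] = np.maximum(counts[:, 0], 1.0)  # every active second is flagged
        sample_idx = (active_idx[:, None] * act_spf + np.arange(act_spf)).ravel()
        activity[sample_idx] = counts.ravel()

    # --- spikes: Poisson times restricted to non-active-wake seconds.
    # The spike contribution is accumulated separately and its spindle-range
    # (7-25 Hz) content removed (zero-phase) before mixing, so injected spikes and
    # injected spindles remain orthogonal event types.
    spike_times: list[float] = []
    if config.spike_rate_per_h > 0:
        eligible = np.flatnonzero(~is_active)
        if eligible.size:
            n_spikes = rng.poisson(config.spike_rate_per_h * n_sec / 3600.0)
            if n_spikes > 0:
                secs = np.sort(
                    rng.choice(eligible, size=min(n_spikes, eligible.size), replace=False)
                )
                spike_buf = np.zeros_like(eeg)
                for sec in secs:
                    t = float(sec) + float(rng.uniform(0.1, 0.9))
                    i0 = int(round(t * fs))
                    amp = config.spike_amp_sd * stage_rms[schedule[sec]]
                    w = _spike_waveform(fs, amp)
                    if i0 + w.size <= eeg.size:
                        spike_buf[i0 : i0 + w.size] += w
                        spike_times.append(t)
                if spike_times:
                    # exact brick-wall notch of the spindle detection range
                    spec = np.fft.rfft(spike_buf)
                    f_axis = np.fft.rfftfreq(spike_buf.size, d=1.0 / fs)
                    spec[(f_axis >= 7.0) & (f_axis <= 25.0)] = 0.0
                    eeg += np.fft.irfft(spec, n=spike_buf.size)

    # --- spindles: Hann-windowed sinusoid bursts inside slow-wave runs
    spindle_intervals: list[tuple[float, float]] = []
    if config.spindle_rate_per_min_sws > 0 and "sws" in schedule:
        sws_runs = _runs_of(schedule == "sws")
        # in-band (10-15 Hz) background RMS: the steady sigma rhythm passes
        # the detection band in full
        inband_rms = weights["sws"]["sigma"]
        amp = config.spindle_amp_mult * inband_rms * np.sqrt(2.0)  # sine peak amp
        lo_d, hi_d = config.spindle_dur_s
        for run_start, run_end in sws_runs:
            run_len = run_end - run_start
            lam = config.spindle_rate_per_min_sws * run_len / 60.0
            k = rng.poisson(lam)
            if k == 0:
                continue
            starts = np.sort(rng.uniform(run_start, run_end, size=k))
            last_end = -np.inf
            for st in starts:
                dur = rng.uniform(lo_d, hi_d)
                if st < last_end:  # keep intervals disjoint
                    st = last_end + 0.05
                end = min(st + dur, float(run_end))  # shorten to fit the bout
                if end - st < lo_d or st >= run_end:
                    continue
                i0, i1 = int(round(st * fs)), int(round(end * fs))
                if i1 > eeg.size:
                    break
                m = i1 - i0
                tt = np.arange(m) / fs
                burst = amp * np.hanning(m) * np.sin(2 * np.pi * config.spindle_freq * tt)
                eeg[i0:i1] += burst
                spindle_intervals.append((float(st), float(end)))
                last_end = end

    rec = Recording(
        eeg=eeg,
        emg=emg,
        activity=activity,
        eeg_fs=config.eeg_fs,
        emg_fs=config.emg_fs,
        activity_fs=config.activity_fs,
        start_clock_h=config.start_clock_h,
    )
    truth = GroundTruth(
        stage_per_second=np.asarray(schedule, dtype=object),
        spike_times_s=np.array(sorted(spike_times)),
        spindle_intervals_s=sorted(spindle_intervals),
    )
    return rec, truth


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean vector, as half-open (start, end)."""
    if not np.any(mask):
        return []
    d = np.diff(mask.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def simulate_recording(
    config: SimConfig, rng_seed: int | None = None
) -> tuple[Recording, GroundTruth]:
    """Schedule + synthesis in one call, sharing a single seed."""
    seed = config.seed if rng_seed is None else rng_seed
    schedule = simulate_stage_schedule(config, rng_seed=seed)
    return synthesize_signals(schedule, config, rng_seed=seed + 104729)


# ---------------------------------------------------------------------------
# cohorts

#: multipliers applied to the affected group, mirroring the reported
#: phenotype: elevated delta, shorter paradoxical bouts, fewer spindles,
#: more spikes
DEFAULT_AFFECTED_EFFECTS = {
    "delta_gain": 2.0,
    "paradoxical_dwell": 0.5,
    "spindle_rate": 0.5,
    "spike_rate": 3.0,
}

IDENTITY_EFFECTS = {
    "delta_gain": 1.0,
    "paradoxical_dwell": 1.0,
    "spindle_rate": 1.0,
    "spike_rate": 1.0,
}


def _apply_effects(config: SimConfig, effects: dict) -> SimConfig:
    # the paradoxical-dwell effect models the animal's paradoxical-sleep
    # propensity: drawn bouts are shortened by the factor and attempts fail
    # (emitting wake instead) with the complementary probability, so bout
    # time, bout counts and paradoxical latency all shift while the rest of
    # the cycle structure stays distribution-identical to control
    dwell = effects.get("paradoxical_dwell", 1.0)
    return replace(
        config,
        paradoxical_dwell_factor=config.paradoxical_dwell_factor * dwell,
        paradoxical_block_frac=1.0 - (1.0 - config.paradoxical_block_frac) * dwell,
        delta_gain=config.delta_gain * effects.get("delta_gain", 1.0),
        spindle_rate_per_min_sws=config.spindle_rate_per_min_sws
        * effects.get("spindle_rate", 1.0),
        spike_rate_per_h=config.spike_rate_per_h * effects.get("spike_rate", 1.0),
    )


def generate_cohort(
    config_base: SimConfig,
    n_per_group: int | Sequence[int],
    group_effects: dict[str, dict] | None = None,
    rng_seed: int = 0,
) -> list[tuple[Recording, GroundTruth]]:
    """Simulate a two-group cohort with per-animal derived seeds.

    ``n_per_group`` may be an int (both groups equal) or a ``(n_affected,
    n_control)`` pair.  Animal ``i`` uses seed ``rng_seed + i`` so cohorts
    are reproducible yet animals independent.  Group labels are ``control``
    and ``affected``.
    """
    if group_effects is None:
        group_effects = {"control": IDENTITY_EFFECTS, "affected": DEFAULT_AFFECTED_EFFECTS}
    if isinstance(n_per_group, int):
        sizes = {g: n_per_group for g in group_effects}
    else:
        sizes = dict(zip(group_effects, n_per_group))
    if any(n < 1 for n in sizes.values()):
        raise ConfigurationError("n_per_group must be >= 1")

    out: list[tuple[Recording, GroundTruth]] = []
    i = 0
    for group, effects in group_effects.items():
        cfg = _apply_effects(config_base, effects)
        for j in range(sizes[group]):
            rec, truth = simulate_recording(cfg, rng_seed=rng_seed + i)
            rec.subject_id = f"{group}_{j:02d}"
            rec.group_label = group
            truth.group_label = group
            out.append((rec, truth))
            i += 1
    return out
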