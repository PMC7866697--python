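import numpy as np
import pytest

from sleepeeg.simulate import (
    DEFAULT_AFFECTED_EFFECTS,
    IDENTITY_EFFECTS,
    ConfigurationError,
    GroundTruth,
    SimConfig,
    generate_cohort,
    simulate_recording,
    simulate_stage_schedule,
    synthesize_signals,
)
from sleepeeg.spectral import band_power, welch_psd
from sleepeeg.stats import two_sample_t


def _bout_lengths(schedule, stage):
    out, run = [], 0
    for s in schedule:
        if s == stage:
            run += 1
        elif run:
            out.append(run)
            run = 0
    if run:
        out.append(run)
    return out


class TestSchedule:
    def test_mean_wake_bout_recovered(self):
        cfg = SimConfig(
            duration_h=24.0,
            seed=2,
            stage_mean_bout_s={
                "active_wake": 240.0,
                "wake": 600.0,
                "sws": 420.0,
                "paradoxical": 90.0,
            },
            stage_dwell_bias_dark=1.0,  # isolate the dwell mean
        )
        sched = simulate_stage_schedule(cfg)
        bouts = _bout_lengths(sched, "wake")
        # drop first/last potentially truncated bouts
        bouts = bouts[1:-1]
        assert len(bouts) >= 50
        assert np.mean(bouts) == pytest.approx(600.0, rel=0.2)

    def test_single_stage_degenerate(self):
        cfg = SimConfig(duration_h=10 / 3600, allowed_stages=("sws",))
        sched = simulate_stage_schedule(cfg)
        assert len(sched) == 10
        assert all(s == "sws" for s in sched)

    def test_same_seed_identical(self):
        cfg = SimConfig(duration_h=1.0, seed=7)
        a = simulate_stage_schedule(cfg)
        b = simulate_stage_schedule(cfg)
        assert np.array_equal(a, b)

    def test_paradoxical_only_from_sws(self):
        cfg = SimConfig(duration_h=6.0, seed=3)
        sched = simulate_stage_schedule(cfg)
        prev = sched[0]
        for s in sched[1:]:
            if s == "paradoxical" and prev != "paradoxical":
                assert prev == "sws"
            prev = s

    def test_dark_wake_dwell_inflated(self):
        bouts_cfg = {
            "active_wake": 120.0,
            "wake": 200.0,
            "sws": 200.0,
            "paradoxical": 60.0,
        }
        light = SimConfig(
            duration_h=12.0, seed=4, start_clock_h=7.0, stage_mean_bout_s=bouts_cfg,
            stage_dwell_bias_dark=3.0,
        )
        dark = SimConfig(
            duration_h=12.0, seed=4, start_clock_h=19.0, stage_mean_bout_s=bouts_cfg,
            stage_dwell_bias_dark=3.0,
        )
        wl = np.mean(_bout_lengths(simulate_stage_schedule(light), "wake")[1:-1])
        wd = np.mean(_bout_lengths(simulate_stage_schedule(dark), "wake")[1:-1])
        assert wd > 1.5 * wl

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(duration_h=-1.0)
        with pytest.raises(ConfigurationError):
            SimConfig(spindle_freq=20.0)
        with pytest.raises(ConfigurationError):
            SimConfig(lights_on_h=7.0, lights_off_h=7.0)


class TestSynthesis:
    def test_delta_gain_raises_delta_power(self):
        base = dict(
            duration_h=0.25,
            seed=5,
            spike_rate_per_h=0.0,
            spindle_rate_per_min_sws=0.0,
            allowed_stages=("sws",),
        )
        rec1, _ = simulate_recording(SimConfig(**base, delta_gain=1.0))
        rec2, _ = simulate_recording(SimConfig(**base, delta_gain=2.0))
        p1 = band_power(welch_psd(rec1.eeg, rec1.eeg_fs), "delta")
        p2 = band_power(welch_psd(rec2.eeg, rec2.eeg_fs), "delta")
        assert p2 > p1

    def test_zero_spike_rate_no_spikes(self):
        cfg = SimConfig(duration_h=0.1, seed=1, spike_rate_per_h=0.0)
        _, truth = simulate_recording(cfg)
        assert truth.spike_times_s.size == 0

    def test_spindle_count_poisson_consistent(self):
        # pure sws, 2/min over 10 min -> mean ~20 across seeds
        counts = []
        for seed in range(8):
            cfg = SimConfig(
                duration_h=10 / 60,
                seed=seed,
                spike_rate_per_h=0.0,
                spindle_rate_per_min_sws=2.0,
                allowed_stages=("sws",),
            )
            _, truth = simulate_recording(cfg)
            counts.append(len(truth.spindle_intervals_s))
        mean = np.mean(counts)
        # Poisson(20): mean of 8 draws within ~3.3 SE
        assert abs(mean - 20.0) < 3.3 * np.sqrt(20.0 / len(counts)) + 1.5

    def test_determinism_bit_identical(self):
        cfg = SimConfig(duration_h=0.1, seed=9)
        r1, t1 = simulate_recording(cfg)
        r2, t2 = simulate_recording(cfg)
        assert np.array_equal(r1.eeg, r2.eeg)
        assert np.array_equal(r1.emg, r2.emg)
        assert np.array_equal(r1.activity, r2.activity)
        assert np.array_equal(t1.spike_times_s, t2.spike_times_s)
        assert t1.spindle_intervals_s == t2.spindle_intervals_s

    def test_stage_counts_conserved(self, default_sim):
        cfg, rec, truth = default_sim
        assert len(truth.stage_per_second) == cfg.duration_s

    def test_spindles_inside_sws(self, default_sim):
        _, _, truth = default_sim
        stages = truth.stage_per_second
        for start, end in truth.spindle_intervals_s:
            secs = range(int(np.floor(start)), int(np.ceil(end)))
            assert all(stages[s] == "sws" for s in secs)

    def test_spike_times_in_range(self, default_sim):
        cfg, _, truth = default_sim
        assert np.all(truth.spike_times_s >= 0)
        assert np.all(truth.spike_times_s < cfg.duration_s)

    def test_activity_nonzero_iff_active_wake(self, default_sim):
        cfg, rec, truth = default_sim
        spf = int(cfg.activity_fs)
        act = rec.activity.reshape(-1, spf)
        active = truth.stage_per_second == "active_wake"
        has_activity = act.max(axis=1) > 0
        assert np.array_equal(has_activity, active)

    def test_spectral_fidelity_sws(self, quiet_sws_sim):
        _, rec, _ = quiet_sws_sim
        ps = welch_psd(rec.eeg, rec.eeg_fs)
        delta = band_power(ps, "delta")
        total = band_power(ps, (0.5, 50.0))
        assert delta > 0.5 * total

    def test_spectral_fidelity_paradoxical(self):
        cfg = SimConfig(
            duration_h=0.25,
            seed=6,
            spike_rate_per_h=0.0,
            spindle_rate_per_min_sws=0.0,
            allowed_stages=("paradoxical",),
        )
        rec, _ = simulate_recording(cfg)
        ps = welch_psd(rec.eeg, rec.eeg_fs)
        assert band_power(ps, "theta") > band_power(ps, "delta")

    def test_emg_tone_follows_active_wake(self, default_sim):
        cfg, rec, truth = default_sim
        spf = int(cfg.emg_fs)
        n_sec = len(truth.stage_per_second)
        rms = np.sqrt(np.mean(rec.emg[: n_sec * spf].reshape(n_sec, spf) ** 2, axis=1))
        active = truth.stage_per_second == "active_wake"
        if active.any() and (~active).any():
            assert rms[active].mean() > 3 * rms[~active].mean()


class TestCohort:
    def test_zero_n_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_cohort(SimConfig(duration_h=0.1), 0)

    def test_identity_effects_indistinguishable(self):
        # small fast cohorts; expect p > 0.05 in >= 90% of replicates
        base = SimConfig(
            duration_h=0.5,
            eeg_fs=200.0,
            emg_fs=200.0,
            spike_rate_per_h=0.0,
            spindle_rate_per_min_sws=0.0,
        )
        hits = 0
        reps = 10
        for rep in range(reps):
            cohort = generate_cohort(
                base,
                3,
                {"a": IDENTITY_EFFECTS, "b": IDENTITY_EFFECTS},
                rng_seed=100 * rep,
            )
            assert len(cohort) == 6
            deltas = {"a": [], "b": []}
            for rec, truth in cohort:
                ps = welch_psd(rec.eeg, rec.eeg_fs)
                deltas[truth.group_label].append(band_power(ps, "delta"))
            r = two_sample_t(deltas["a"], deltas["b"])
            hits += r.p_value > 0.05
        assert hits >= 9

    def test_affected_has_higher_delta_downstream(self):
        base = SimConfig(
            duration_h=0.5,
            eeg_fs=200.0,
            emg_fs=200.0,
            seed=0,
            spike_rate_per_h=0.0,
            spindle_rate_per_min_sws=0.0,
        )
        cohort = generate_cohort(
            base,
            (7, 5),
            {"affected": DEFAULT_AFFECTED_EFFECTS, "control": IDENTITY_EFFECTS},
            rng_seed=42,
        )
        assert len(cohort) == 12
        means = {"affected": [], "control": []}
        for rec, truth in cohort:
            ps = welch_psd(rec.eeg, rec.eeg_fs)
            means[truth.group_label].append(band_power(ps, "delta"))
        assert np.mean(means["affected"]) > np.mean(means["control"])

    def test_per_animal_seeds_differ(self):
        base = SimConfig(duration_h=0.05, spike_rate_per_h=0.0)
        cohort = generate_cohort(base, 2, rng_seed=1)
        eegs = [rec.eeg for rec, _ in cohort]
        assert not np.array_equal(eegs[0], eegs[1])
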