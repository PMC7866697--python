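import numpy as np
import pytest

from sleepeeg.recording import LightDarkScheme
from sleepeeg.staging import (
    Hypnogram,
    StageRuleParams,
    aggregate_cycles,
    bin_2h,
    extract_bouts,
    score_epochs,
    sleep_metrics,
    stage_recording,
    stage_second,
)

P = StageRuleParams()


def _hyp(labels, start_clock_h=0.0):
    return Hypnogram(np.array(labels, dtype=object), start_clock_h=start_clock_h)


class TestStageSecond:
    def test_high_emg_wins(self):
        lab = stage_second(100.0, 90.0, 1.0, 100.0, 50.0, P, amp_ref=20.0, emg_ref=8.0)
        assert lab == "active_wake"

    def test_sws_signature(self):
        lab = stage_second(80.0, 90.0, 2.0, 100.0, 8.0, P, amp_ref=20.0, emg_ref=8.0)
        assert lab == "sws"

    def test_paradoxical_signature(self):
        lab = stage_second(22.0, 5.0, 80.0, 100.0, 8.0, P, amp_ref=20.0, emg_ref=8.0)
        assert lab == "paradoxical"

    def test_wake_default(self):
        lab = stage_second(20.0, 10.0, 12.0, 100.0, 8.0, P, amp_ref=20.0, emg_ref=8.0)
        assert lab == "wake"

    def test_zero_features_unscored(self):
        lab = stage_second(0.0, 0.0, 0.0, 0.0, 0.0, P, amp_ref=20.0, emg_ref=8.0)
        assert lab == "unscored"


class TestScoreEpochs:
    def test_majority_six_of_ten(self):
        labels = ["sws"] * 6 + ["wake"] * 4
        hyp = score_epochs(np.array(labels, dtype=object))
        assert hyp.labels[0] == "sws"

    def test_five_five_tie_unscored(self):
        labels = ["sws"] * 5 + ["paradoxical"] * 5
        hyp = score_epochs(np.array(labels, dtype=object))
        assert hyp.labels[0] == "unscored"

    def test_uniform_epoch(self):
        hyp = score_epochs(np.array(["wake"] * 10, dtype=object))
        assert hyp.labels[0] == "wake"

    def test_exactly_half_with_unique_mode_scored(self):
        labels = ["sws"] * 5 + ["wake"] * 3 + ["paradoxical"] * 2
        hyp = score_epochs(np.array(labels, dtype=object))
        assert hyp.labels[0] == "sws"

    def test_trailing_partial_epoch_dropped(self):
        hyp = score_epochs(np.array(["wake"] * 25, dtype=object))
        assert len(hyp) == 2

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            score_epochs(np.array(["wake"] * 5, dtype=object))

    def test_each_epoch_single_label(self, default_sim):
        _, rec, _ = default_sim
        hyp = score_epochs(stage_recording(rec))
        valid = {"active_wake", "wake", "sws", "paradoxical", "unscored"}
        assert set(hyp.labels) <= valid


class TestBouts:
    def test_simple_run(self):
        hyp = _hyp(["wake", "wake", "sws", "sws", "sws", "wake"])
        bouts = extract_bouts(hyp)
        assert bouts["sws"] == [(20.0, 50.0)]

    def test_all_unscored(self):
        bouts = extract_bouts(_hyp(["unscored"] * 5))
        assert all(len(v) == 0 for v in bouts.values())

    def test_unscored_terminates_bout(self):
        hyp = _hyp(["sws", "sws", "unscored", "sws"])
        assert extract_bouts(hyp)["sws"] == [(0.0, 20.0), (30.0, 40.0)]

    def test_boundaries_match_ground_truth(self, default_sim):
        _, rec, truth = default_sim
        hyp = score_epochs(stage_recording(rec))
        bouts = extract_bouts(hyp)
        true_sched = truth.stage_per_second
        # for each detected long sws bout, the true schedule at its
        # midpoint should be sws and the onset within +/-10 s of a true
        # transition into sws
        for start, end in bouts["sws"]:
            if end - start < 60:
                continue
            assert true_sched[int((start + end) // 2)] == "sws"
            lo = max(int(start) - 10, 0)
            hi = min(int(start) + 11, len(true_sched))
            assert any(
                true_sched[s] == "sws" and (s == 0 or true_sched[s - 1] != "sws")
                for s in range(lo, hi)
            )


class TestSleepMetrics:
    def test_latency_and_total_sleep_arithmetic(self):
        hyp = _hyp(["wake"] * 60 + ["sws"] * 30)
        m = sleep_metrics(hyp)
        assert m.latency_s == pytest.approx(600.0)
        assert m.total_sleep_s == pytest.approx(300.0)
        assert m.mean_bout_s["sws"] == pytest.approx(300.0)

    def test_all_wake(self):
        m = sleep_metrics(_hyp(["wake"] * 30))
        assert m.total_sleep_s == 0.0
        assert np.isnan(m.latency_s)

    def test_latency_missing_not_zero(self):
        m = sleep_metrics(_hyp(["sws"] * 10))
        assert np.isnan(m.latency_s)

    def test_paradoxical_latency(self):
        hyp = _hyp(["wake"] * 30 + ["sws"] * 30 + ["paradoxical"] * 6)
        m = sleep_metrics(hyp)
        assert m.latency_paradoxical_s == pytest.approx(600.0)

    def test_both_wake_states_start_latency_runs(self):
        hyp = _hyp(["active_wake"] * 6 + ["wake"] * 6 + ["sws"] * 12)
        m = sleep_metrics(hyp)
        assert m.latency_s == pytest.approx(120.0)


class TestBins:
    def test_complete_bin_all_sws(self):
        hyp = _hyp(["sws"] * 720)
        bins = bin_2h(hyp)
        assert len(bins) == 1
        assert bins[0].possible == 720
        assert bins[0].counts["sws"] == 720
        assert bins[0].percent["sws"] == pytest.approx(100.0)

    def test_24h_gives_12_bins(self):
        hyp = _hyp(["wake"] * (720 * 12))
        assert len(bin_2h(hyp)) == 12

    def test_cycle_labels(self):
        hyp = _hyp(["wake"] * (720 * 12))
        bins = bin_2h(hyp)
        for b in bins:
            expect = "light" if 7 <= b.bin_start_clock_h < 19 else "dark"
            assert b.cycle == expect

    def test_partial_first_bin_flagged(self):
        hyp = _hyp(["wake"] * 720, start_clock_h=1.0)  # starts mid-bin
        bins = bin_2h(hyp)
        assert not bins[0].complete
        assert bins[0].n_epochs == 360

    def test_percent_conservation(self, default_sim):
        _, rec, _ = default_sim
        hyp = score_epochs(stage_recording(rec), start_clock_h=rec.start_clock_h)
        for b in bin_2h(hyp):
            states_plus_artifact = (
                sum(b.percent[s] for s in ("active_wake", "wake", "sws", "paradoxical"))
                + b.percent["unscored"]
            )
            assert states_plus_artifact == pytest.approx(100.0, abs=1e-9)

    def test_awake_combines_wake_states(self):
        hyp = _hyp(["wake"] * 360 + ["active_wake"] * 360)
        b = bin_2h(hyp)[0]
        assert b.counts["awake"] == 720


class TestAggregate:
    def test_uniform_half_sws(self):
        labels = (["sws"] * 5 + ["wake"] * 5) * (720 * 12 // 10)
        bins = bin_2h(_hyp(labels))
        agg = aggregate_cycles(bins)
        for cycle in ("light", "dark"):
            assert agg[cycle]["percent"]["sws"] == pytest.approx(50.0)

    def test_counts_conservation(self, default_sim):
        _, rec, _ = default_sim
        hyp = score_epochs(stage_recording(rec), start_clock_h=rec.start_clock_h)
        bins = bin_2h(hyp)
        agg = aggregate_cycles(bins)
        total = sum(b.counts["sws"] for b in bins)
        by_cycle = sum(agg[c]["counts"]["sws"] for c in agg)
        assert by_cycle == total

    def test_dark_biased_wake(self):
        from sleepeeg.simulate import SimConfig, simulate_recording

        cfg = SimConfig(
            duration_h=4.0,
            seed=17,
            eeg_fs=200.0,
            emg_fs=200.0,
            start_clock_h=17.0,  # spans 17-19 light, 19-21 dark
            stage_dwell_bias_dark=3.0,
            spike_rate_per_h=0.0,
            spindle_rate_per_min_sws=0.0,
        )
        rec, _ = simulate_recording(cfg)
        hyp = score_epochs(stage_recording(rec), start_clock_h=rec.start_clock_h)
        agg = aggregate_cycles(bin_2h(hyp))
        assert agg["dark"]["percent"]["awake"] > agg["light"]["percent"]["awake"]
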