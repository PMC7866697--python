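# sleepeeg

Analysis toolkit for rodent wireless-telemetry EEG/EMG recordings, plus a
ground-truth synthetic signal generator so every stage of the pipeline can
be validated end to end without animal data.

The pipeline covers:

- **Spectral analysis** — Welch power spectral density (4-s Hann segments,
  50% overlap), band powers over delta (0.5–4 Hz), theta (5–9), alpha
  (9–12), beta (13–30) and gamma (30–50 Hz), total/relative delta power,
  and light/dark-cycle spectral summaries.
- **Epileptiform spike counting** — 30-s window amplitude statistics,
  2.5-SD two-sided candidate demarcation, strict 3-point monotone peak
  confirmation, activity-based window exclusion, 3-h edge trimming, and
  per-hour rate normalization.
- **Sleep staging** — per-second classification into active wake / wake /
  slow-wave sleep / paradoxical sleep from EEG amplitude, delta fraction,
  theta/delta ratio and EMG tone; 10-s majority epochs (ties unscored);
  bout, latency and total-sleep metrics; clock-aligned 2-h bins (720
  possible scores each) with light (7–19) / dark cycle aggregation.
- **Sleep-spindle detection** — 10–15 Hz bandpass cascaded with a
  corner-specified Butterworth design, 750-ms RMS envelope, cubing, and
  1.2× / 3.5× mean-cubed thresholds with a strict 0.5–10 s duration gate;
  counts and counts per sleep hour.
- **Statistics & reporting** — pooled-variance Student's t, Holm–Šidák
  step-down adjustment, simple linear regression, robust (median/MAD)
  outlier flagging, and per-cohort comparison tables/figures.
- **Synthetic data** — a semi-Markov four-state sleep architecture with a
  12:12 light–dark schedule, stage-dependent band-limited EEG, EMG tone and
  activity channels, injected biphasic spikes and 11-Hz spindle bursts, and
  configurable group effects (elevated delta, paradoxical-sleep deficits,
  fewer spindles, more spikes). All hidden state is returned as
  `GroundTruth` for recovery testing.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` with end-to-end recovery criteria (staging
accuracy, spike/spindle precision–recall, direction-of-effect recovery on
simulated 7-vs-5 cohorts). The full run takes ~10 minutes; the
cohort-recovery family accounts for most of it.

Note: one acceptance assertion
(`test_c7_direction_recovery[spindles_per_sleep_h]`) fails by design — the
prescribed effect sizes cannot invert the spindles-per-sleep-hour direction
(count halves while sleep time shrinks less), so the test documents that
limit rather than weaken the check.

## CLI

All stages are exposed under a single `sleepeeg` command:

```sh
# simulate a cohort: EDFs + ground-truth CSVs + manifest
sleepeeg simulate --config sim.yaml --out-dir data/ --seed 1 \
    --n-affected 7 --n-control 5

# per-recording analyses
sleepeeg psd      --edf data/control_00.edf --trim-head-h 3 --trim-tail-h 3 \
                  --by-cycle --out psd.csv
sleepeeg spikes   --edf data/control_00.edf --params spikes.yaml --out events.csv
sleepeeg stage    --edf data/control_00.edf --out hypnogram.csv --bins bins.csv
sleepeeg spindles --edf data/control_00.edf --hypnogram hypnogram.csv --out spindles.csv

# group comparison report from per-animal summaries
sleepeeg report --summaries summaries.csv --out-dir report/
```

YAML config keys mirror the corresponding dataclass fields (`SimConfig`,
`SpikeParams`, `StageRuleParams`, `SpindleParams`).

## Conventions

- Time is seconds from recording start; intervals are half-open
  `[start, end)`.
- The light cycle is clock hours `[7, 19)`; dark is the complement.
- Band power defaults to the literal sum of PSD bin values; pass
  `integrate=True` for a ×Δf integral.
- Band intervals are half-open `[low, high)` except gamma, closed at 50 Hz;
  the `[4, 5)` and `[12, 13)` gaps between named bands are preserved.
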