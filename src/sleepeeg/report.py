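"""Per-animal summaries and group-comparison report generation.

``summarize_recording`` runs the whole analysis stack (spectral, spikes,
staging, spindles) on one recording and returns a flat per-animal record;
``build_report`` turns a table of such records into group-comparison CSVs
and figures.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict

import numpy as np
import pandas as pd

from .recording import LightDarkScheme, Recording, preprocess_eeg, trim_edges
from .spectral import BandScheme, band_power, delta_summary, welch_psd
from .spikes import SpikeParams, count_spikes
from .spindles import SpindleParams, detect_spindles_in_eeg, spindle_metrics
from .staging import (
    StageRuleParams,
    aggregate_cycles,
    bin_2h,
    score_epochs,
    sleep_metrics,
    stage_recording,
)
from .stats import holm_sidak_adjust, simple_regression, two_sample_t

logger = logging.getLogger(__name__)

__all__ = ["summarize_recording", "summarize_cohort", "build_report"]


def summarize_recording(
    rec: Recording,
    trim_head_h: float = 0.0,
    trim_tail_h: float = 0.0,
    spike_params: SpikeParams | None = None,
    spindle_params: SpindleParams | None = None,
    stage_params: StageRuleParams | None = None,
    scheme: LightDarkScheme | None = None,
    bands: BandScheme | None = None,
) -> dict:
    """Run every analysis stage on one recording; returns one flat record.

    Edge trimming for the spectral/staging/spindle stages is applied here;
    the spike stage applies its own (its params carry the trim hours).
    """
    scheme = scheme or LightDarkScheme()
    bands = bands or BandScheme()
    spike_params = spike_params or SpikeParams(
        trim_head_h=trim_head_h, trim_tail_h=trim_tail_h
    )

    spikes = count_spikes(rec, spike_params)

    analysis = rec
    if trim_head_h or trim_tail_h:
        analysis = trim_edges(rec, trim_head_h, trim_tail_h)
    eeg = preprocess_eeg(analysis)

    spectrum = welch_psd(eeg, analysis.eeg_fs)
    ds = delta_summary(spectrum, bands)
    row: dict = {
        "subject_id": rec.subject_id,
        "group_label": rec.group_label,
        "total_delta": ds.total_delta,
        "relative_delta": ds.relative_delta,
        "total_power": ds.total_power,
        "spike_count": spikes.total_count,
        "spike_rate_per_h": spikes.rate_per_h,
    }
    for name in bands.bands:
        row[f"band_{name}"] = band_power(spectrum, name, bands)

    labels = stage_recording(analysis, stage_params)
    hyp = score_epochs(labels, start_clock_h=analysis.start_clock_h)
    sm = sleep_metrics(hyp)
    row["latency_s"] = sm.latency_s
    row["latency_paradoxical_s"] = sm.latency_paradoxical_s
    row["total_sleep_s"] = sm.total_sleep_s
    for stage, mean in sm.mean_bout_s.items():
        row[f"mean_bout_{stage}_s"] = mean

    cycles = aggregate_cycles(bin_2h(hyp, scheme))
    for cycle, agg in cycles.items():
        for key in ("awake", "sws", "paradoxical"):
            row[f"{cycle}_percent_{key}"] = agg["percent"][key]

    spindles = detect_spindles_in_eeg(eeg, analysis.eeg_fs, spindle_params)
    sp = spindle_metrics(spindles, sm.total_sleep_s)
    row["spindle_count"] = sp["count"]
    row["spindles_per_sleep_h"] = sp["count_per_sleep_hour"]
    return row


def summarize_cohort(recordings, **kwargs) -> pd.DataFrame:
    """Summaries for a list of Recording (or (Recording, GroundTruth))."""
    rows = []
    for item in recordings:
        rec = item[0] if isinstance(item, tuple) else item
        rows.append(summarize_recording(rec, **kwargs))
    return pd.DataFrame(rows)


_COMPARISON_METRICS = [
    "total_delta",
    "relative_delta",
    "total_power",
    "spike_count",
    "spike_rate_per_h",
    "mean_bout_paradoxical_s",
    "mean_bout_sws_s",
    "latency_s",
    "latency_paradoxical_s",
    "total_sleep_s",
    "spindle_count",
    "spindles_per_sleep_h",
]


def build_report(
    summaries: pd.DataFrame,
    out_dir: str | os.PathLike | None = None,
    alpha: float = 0.05,
    make_figures: bool = False,
) -> dict:
    """Group descriptives, per-metric t tests, per-band tests with Holm-Sidak
    adjustment, and the delta/spindle regression.

    Returns a dict of DataFrames; writes CSVs (and optionally PNG figures)
    when ``out_dir`` is given.
    """
    groups = sorted(summaries["group_label"].unique())
    out: dict[str, pd.DataFrame] = {}

    numeric = summaries.select_dtypes("number").columns
    desc = summaries.groupby("group_label")[list(numeric)].agg(["mean", "sem", "count"])
    out["descriptives"] = desc

    tests = pd.DataFrame()
    band_tests = pd.DataFrame()
    if len(groups) >= 2:
        ga, gb = groups[0], groups[1]
        a_df = summaries[summaries["group_label"] == ga]
        b_df = summaries[summaries["group_label"] == gb]

        rows = []
        for metric in _COMPARISON_METRICS:
            if metric not in summaries.columns:
                logger.warning("metric %s missing; skipped in report", metric)
                continue
            a = a_df[metric].dropna().to_numpy()
            b = b_df[metric].dropna().to_numpy()
            if a.size < 2 or b.size < 2:
                continue
            r = two_sample_t(a, b)
            rows.append(
                {
                    "metric": metric,
                    "group_a": ga,
                    "group_b": gb,
                    "t": r.statistic,
                    "df": r.df,
                    "p": r.p_value,
                    "mean_a": r.mean_a,
                    "sem_a": r.sem_a,
                    "mean_b": r.mean_b,
                    "sem_b": r.sem_b,
                    "significant": r.p_value < alpha,
                }
            )
        tests = pd.DataFrame(rows)
        out["group_tests"] = tests

        band_cols = [c for c in summaries.columns if c.startswith("band_")]
        rows = []
        for col in band_cols:
            r = two_sample_t(
                a_df[col].dropna().to_numpy(), b_df[col].dropna().to_numpy()
            )
            rows.append({"band": col.removeprefix("band_"), "t": r.statistic, "df": r.df, "p": r.p_value})
        if rows:
            band_tests = pd.DataFrame(rows)
            band_tests["p_adj"] = holm_sidak_adjust(band_tests["p"].to_numpy())
            band_tests["significant"] = band_tests["p_adj"] < alpha
            out["band_tests"] = band_tests
    else:
        logger.warning("single group: comparison tables empty")
        out["group_tests"] = tests

    # delta vs spindle-count correlation across all animals
    if {"total_delta", "spindle_count"} <= set(summaries.columns) and len(summaries) >= 3:
        x = summaries["total_delta"].to_numpy(dtype=float)
        y = summaries["spindle_count"].to_numpy(dtype=float)
        if np.ptp(x) > 0:
            reg = simple_regression(x, y)
            out["delta_spindle_regression"] = pd.DataFrame([asdict(reg)])

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for name, df in out.items():
            df.to_csv(os.path.join(out_dir, f"{name}.csv"))
        if make_figures:
            _figures(summaries, out, out_dir)
    return out


def _figures(summaries: pd.DataFrame, tables: dict, out_dir) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric in ("total_delta", "spike_count", "spindle_count", "total_sleep_s"):
        if metric not in summaries.columns:
            continue
        fig, ax = plt.subplots(figsize=(3.5, 3))
        for i, (group, sub) in enumerate(summaries.groupby("group_label")):
            vals = sub[metric].dropna()
            ax.scatter(np.full(len(vals), i), vals, alpha=0.7)
            ax.errorbar(i, vals.mean(), yerr=vals.sem(), fmt="_", color="k", capsize=4)
        ax.set_xticks(range(summaries["group_label"].nunique()))
        ax.set_xticklabels(sorted(summaries["group_label"].unique()))
        ax.set_ylabel(metric)
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, f"fig_{metric}.png"), dpi=120)
        plt.close(fig)
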