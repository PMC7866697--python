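"""Shared fixtures: synthetic recordings generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from sleepeeg.simulate import SimConfig, simulate_recording


@pytest.fixture(scope="session")
def default_sim():
    """A 2-h mixed-stage recording with spikes and spindles, plus truth."""
    cfg = SimConfig(
        duration_h=2.0,
        seed=11,
        start_clock_h=7.0,
        spike_rate_per_h=20.0,
        spindle_rate_per_min_sws=1.0,
    )
    rec, truth = simulate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def quiet_sws_sim():
    """A 1-h slow-wave-only recording without injected events."""
    cfg = SimConfig(
        duration_h=1.0,
        seed=5,
        spike_rate_per_h=0.0,
        spindle_rate_per_min_sws=0.0,
        allowed_stages=("sws",),
    )
    rec, truth = simulate_recording(cfg)
    return cfg, rec, truth


def overlap(a: tuple[float, float], b: tuple[float, float]) -> float:
    return max(0.0, min(a[1], b[1]) - max(a[0], b[0]))


def interval_match(x, candidates, frac: float = 0.5) -> bool:
    """True if any candidate overlaps x by >= frac of the shorter interval."""
    return any(
        overlap(x, c) >= frac * min(x[1] - x[0], c[1] - c[0]) for c in candidates
    )


@pytest.fixture(scope="session")
def matchers():
    return overlap, interval_match
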