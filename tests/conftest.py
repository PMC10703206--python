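"""Shared fixtures: small synthetic cohorts and day-set oracle helpers."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pytest

from pipcox.ehr_model import DateInterval
from pipcox.synthetic_data import SimulationConfig, generate_cohort


def interval_dayset(intervals) -> set:
    """Brute-force expansion of intervals into explicit sets of dates."""
    days = set()
    for iv in intervals:
        d = iv.start
        while d <= iv.end:
            days.add(d)
            d += timedelta(days=1)
    return days


def random_intervals(rng, n, lo=date(2007, 1, 1), span=800, max_len=60):
    """n random DateIntervals inside [lo, lo+span]."""
    out = []
    for _ in range(n):
        a = int(rng.integers(0, span))
        ln = int(rng.integers(1, max_len + 1))
        out.append(DateInterval(lo + timedelta(days=a), lo + timedelta(days=a + ln - 1)))
    return out


@pytest.fixture(scope="session")
def small_cohort():
    """A 200-patient default-parameter cohort with ground truth."""
    cfg = SimulationConfig(n_patients=200, seed=7)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_cohort():
    """A 400-patient cohort with a planted exposure effect."""
    cfg = SimulationConfig(n_patients=400, seed=11)
    return generate_cohort(cfg)
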