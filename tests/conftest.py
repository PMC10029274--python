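"""Shared fixtures and helpers for the darshape test suite.

All trajectory fixtures are generated programmatically from the synthetic
archetype generator; nothing is read from disk.
"""

from __future__ import annotations

from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd
import pytest

import darshape as ds


def make_track(individual_id: str, times_s, x, y, std=None,
               t0: datetime | None = None) -> ds.Track:
    """Build a Track from offsets in seconds and meter coordinates."""
    t0 = t0 or datetime(2021, 3, 1, 12, 0, tzinfo=timezone.utc)
    stamps = pd.to_datetime([t0 + timedelta(seconds=float(s)) for s in times_s],
                            utc=True)
    n = len(stamps)
    return ds.Track(individual_id, pd.DataFrame({
        "timestamp": stamps,
        "x": np.asarray(x, dtype=float),
        "y": np.asarray(y, dtype=float),
        "accuracy_std": np.full(n, 5.0) if std is None
        else np.asarray(std, dtype=float),
    }))


def night_to_metrics(spec: ds.ArchetypeSpec, night_date: date,
                     roost, rng: np.random.Generator,
                     subsample_s: float = 300.0) -> ds.DarMetrics:
    """Run one generated night through segmentation, endpoint extraction,
    subsampling and the metric computation (bypassing cohort-level rules)."""
    frame = ds.generate_night(spec, night_date, roost, rng)
    track = ds.Track("t", frame)
    night = ds.segment_nights(track)[0]
    segments = ds.detect_flight_segments(night)
    start, end, no_flight = ds.extract_endpoints(night, segments)
    points = ds.subsample(night, subsample_s)
    dar = ds.DAR("t_0", "t", night.night_date, points, start, end,
                 {"no_flight": no_flight})
    return ds.compute_metrics(dar)


@pytest.fixture(scope="session")
def archetype_specs():
    return ds.owl_archetype_specs()


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny 2-individual cohort (5 nights each) at raw cadence, with a
    permissive config so the >30-night rule does not empty it."""
    spec = ds.owl_cohort(n_individuals=2, nights_per_individual=5, seed=42)
    tracks, meta, truth = ds.generate_cohort(spec)
    cfg = ds.RunConfig(min_nights=3)
    return tracks, meta, truth, cfg
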