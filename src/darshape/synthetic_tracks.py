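"""Synthetic multi-night trajectory generator.

Generates labeled cohorts emulating the seven DAR archetypes (closed local,
closed small, partially open, transverse, closed medium, closed large, wide
open) and a reverse-GPS sampling regime (seconds-scale fix cadence, meter
accuracy estimates), so every pipeline stage is testable without field data.

Geometry-only emulation: each night is a stationary roost phase, a sequence
of waypoint flights with foraging dwells (out via one lateral flank of the
excursion axis, a long dwell at the far point, back via the other flank),
and a final roost phase. The waypoint layout directly targets the four
whole-path metrics: far-point distance = max diameter, flank offsets = max
width, final-roost displacement = net displacement (openness). Dwells at
the geometric extremes make the metrics insensitive to subsampling, as the
field protocol assumes. Not a behavioral simulator: no foraging rules,
memory, or landscape.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .errors import DataError
from .track_io import IndividualMeta

ARCHETYPES = (
    "closed_local", "closed_small", "partially_open", "transverse",
    "closed_medium", "closed_large", "wide_open",
)
OPEN_ARCHETYPES = {"partially_open", "wide_open"}


@dataclass
class ArchetypeSpec:
    """Target metric regime for one DAR archetype.

    scale_km targets the max diameter, width_ratio the width/diameter
    ratio, openness_km the net displacement. Per-night multiplicative
    jitter (sd fractions) creates within-archetype variation.
    """
    archetype: str
    scale_km: float
    width_ratio: float
    openness_km: float = 0.0
    fix_interval_s: float = 8.0
    noise_sd_m: float = 5.0
    flight_speed_ms: float = 6.0
    night_start_hour: float = 18.0     # local; before the 21:00 quality cutoff
    night_end_hour: float = 4.0        # next day; after the 02:00 cutoff
    excursion_start_hour: float = 19.5
    excursion_end_hour: float = 3.0
    # within-archetype night-to-night variation; small enough that
    # archetype centroids stay >= 3 within-archetype SDs apart in z-scored
    # metric space (the generator's separability contract)
    scale_jitter: float = 0.05
    ratio_jitter: float = 0.05
    openness_jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise DataError(f"unknown archetype {self.archetype!r}")
        if self.scale_km <= 0:
            raise DataError("scale_km must be positive")
        if not 0 <= self.width_ratio <= 1:
            raise DataError("width_ratio must be in [0, 1]")
        if self.openness_km < 0:
            raise DataError("openness_km must be >= 0")
        if self.archetype in OPEN_ARCHETYPES and self.openness_km == 0:
            raise DataError(f"{self.archetype} requires openness_km > 0")
        if self.archetype not in OPEN_ARCHETYPES \
                and self.openness_km >= self.scale_km / 4:
            raise DataError(f"{self.archetype} is a closed shape; openness_km "
                            "must stay below scale_km / 4")
        if self.archetype == "wide_open" and self.openness_km >= self.scale_km:
            raise DataError("wide_open needs openness_km < scale_km")


def owl_archetype_specs(fix_interval_s: float = 8.0,
                           noise_sd_m: float = 5.0) -> dict[str, ArchetypeSpec]:
    """Default presets targeting the published per-category metric means
    (max diameter, width/diameter ratio, net displacement, all km)."""
    regimes = {
        # (max diameter km, width/diameter, net displacement km)
        "closed_local":   (0.79, 0.32 / 0.79, 0.11),
        "closed_small":   (1.7, 0.71 / 1.7, 0.10),
        "partially_open": (2.4, 1.2 / 2.4, 0.41),
        "transverse":     (3.6, 0.70 / 3.6, 0.07),
        "closed_medium":  (3.5, 1.9 / 3.5, 0.09),
        "closed_large":   (6.1, 2.0 / 6.1, 0.13),
        "wide_open":      (4.8, 1.7 / 4.8, 4.1),
    }
    return {
        name: ArchetypeSpec(name, scale, ratio, openness,
                            fix_interval_s=fix_interval_s, noise_sd_m=noise_sd_m)
        for name, (scale, ratio, openness) in regimes.items()
    }


def owl_mixture() -> dict[str, float]:
    """Published cohort-wide archetype proportions."""
    return {
        "closed_local": 0.27, "closed_small": 0.28, "partially_open": 0.16,
        "transverse": 0.08, "closed_medium": 0.10, "closed_large": 0.08,
        "wide_open": 0.03,
    }


def generate_night(spec: ArchetypeSpec, night_date: date,
                   roost: tuple[float, float], rng: np.random.Generator,
                   timezone: str = "Asia/Jerusalem") -> pd.DataFrame:
    """One night of raw-cadence fixes (timestamp UTC, x, y, accuracy_std).

    The night starts and ends with stationary roost phases and passes the
    complete-night rules by construction (first fix before 21:00, last
    after 02:00, > 1000 fixes at the default cadence).
    """
    tz = ZoneInfo(timezone)
    d_m = spec.scale_km * 1000.0 * max(0.7, 1.0 + rng.normal(0, spec.scale_jitter))
    ratio = float(np.clip(spec.width_ratio * (1.0 + rng.normal(0, spec.ratio_jitter)),
                          0.01, 0.95))
    w_m = ratio * d_m
    # openness scales with the night's realized extent: a bigger excursion
    # ends proportionally farther from its start
    open_m = (spec.openness_km / spec.scale_km) * d_m * max(
        0.2, 1.0 + rng.normal(0, spec.openness_jitter))
    open_m = min(open_m, 0.95 * d_m)

    # waypoints in the excursion frame: roost -> flank A -> far point ->
    # flank C -> final roost
    p0 = np.array([0.0, 0.0])
    a = np.array([d_m / 2.0, w_m / 2.0])
    b = np.array([d_m, 0.0])
    c = np.array([d_m / 2.0, -w_m / 2.0])
    e = np.array([open_m, 0.0])
    waypoints = [p0, a, b, c, e]

    start_local = datetime.combine(night_date, time(0)) + timedelta(
        hours=spec.night_start_hour)
    end_local = datetime.combine(night_date, time(0)) + timedelta(
        hours=(spec.night_end_hour if spec.night_end_hour > spec.night_start_hour
               else spec.night_end_hour + 24.0))
    exc_start = (spec.excursion_start_hour - spec.night_start_hour) * 3600.0
    exc_end = ((spec.excursion_end_hour + (24.0 if spec.excursion_end_hour
                                           < spec.night_start_hour else 0.0)
                - spec.night_start_hour) * 3600.0)
    total_s = (end_local - start_local).total_seconds()

    # short hops are flown slower, so every leg lasts long enough to
    # register as a move run in the segmentation downstream of any realistic
    # sliding-window smoother
    leg_d = [np.linalg.norm(waypoints[i + 1] - waypoints[i]) for i in range(4)]
    leg_t = [max(d / spec.flight_speed_ms, min(150.0, d / 2.5))
             for d in leg_d]
    flight_s = sum(leg_t)
    dwell_total = (exc_end - exc_start) - flight_s
    if dwell_total <= 600:
        raise DataError(
            f"{spec.archetype}: excursion window too short for scale "
            f"{spec.scale_km} km at {spec.flight_speed_ms} m/s")
    dwell = [0.2 * dwell_total, 0.6 * dwell_total, 0.2 * dwell_total]

    # keyframes (time offset s, position)
    key_t = [0.0, exc_start]
    key_p = [p0, p0]
    t = exc_start
    for i in range(4):
        t += leg_t[i]
        key_t.append(t)
        key_p.append(waypoints[i + 1])
        if i < 3:
            t += dwell[i]
            key_t.append(t)
            key_p.append(waypoints[i + 1])
    key_t.append(total_s)
    key_p.append(e)

    n = int(total_s // spec.fix_interval_s) + 1
    ts = np.arange(n) * spec.fix_interval_s
    key_p = np.array(key_p)
    x = np.interp(ts, key_t, key_p[:, 0])
    y = np.interp(ts, key_t, key_p[:, 1])

    theta = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    xy = np.column_stack([x, y]) @ rot.T
    xy += np.asarray(roost, dtype=float)
    xy += rng.normal(0, spec.noise_sd_m, xy.shape)

    stamps = (pd.Timestamp(start_local, tz=tz)
              + pd.to_timedelta(ts, unit="s")).tz_convert("UTC")
    return pd.DataFrame({
        "timestamp": stamps,
        "x": xy[:, 0],
        "y": xy[:, 1],
        "accuracy_std": rng.uniform(1.0, 20.0, n),
    })


@dataclass
class IndividualSpec:
    """One synthetic individual: metadata, home (roost) center, number of
    consecutive nights, and an archetype mixture (optionally keyed by
    quadrimester: {1: {...}, 2: {...}, 3: {...}})."""
    meta: IndividualMeta
    home: tuple[float, float]
    n_nights: int
    mixture: dict

    def mixture_for(self, quad: int) -> dict[str, float]:
        mix = self.mixture
        if mix and isinstance(next(iter(mix.values())), dict):
            mix = mix[quad]
        total = sum(mix.values())
        if not np.isclose(total, 1.0):
            raise DataError(f"{self.meta.individual_id}: mixture weights sum "
                            f"to {total}, expected 1")
        return mix


@dataclass
class CohortSpec:
    individuals: list[IndividualSpec]
    seed: int = 0
    archetype_specs: dict[str, ArchetypeSpec] = field(
        default_factory=owl_archetype_specs)
    start_date: date = date(2021, 2, 1)
    timezone: str = "Asia/Jerusalem"


def generate_cohort(spec: CohortSpec
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full multi-individual dataset at raw cadence.

    Returns (tracks, metadata, truth) frames; truth holds the generated
    archetype per individual-night. Deterministic under ``spec.seed``.
    """
    from .cohort_analysis import assign_quadrimester

    track_frames, truth_rows, meta_rows = [], [], []
    for idx, ind in enumerate(spec.individuals):
        rng = np.random.default_rng([spec.seed, idx])
        for night_i in range(ind.n_nights):
            nd = spec.start_date + timedelta(days=night_i)
            quad, _ = assign_quadrimester(nd)
            mix = ind.mixture_for(quad)
            names = sorted(mix)
            arch = rng.choice(names, p=[mix[a] for a in names])
            frame = generate_night(spec.archetype_specs[arch], nd, ind.home,
                                   rng, spec.timezone)
            frame.insert(0, "individual_id", ind.meta.individual_id)
            track_frames.append(frame)
            truth_rows.append({
                "individual_id": ind.meta.individual_id,
                "night_date": nd,
                "archetype": arch,
            })
        m = ind.meta
        meta_rows.append({
            "individual_id": m.individual_id, "sex": m.sex,
            "age_class": m.age_class,
            "birth_or_assignment_date": m.birth_or_assignment_date,
            "family_id": m.family_id,
        })
    tracks = pd.concat(track_frames, ignore_index=True)
    tracks = tracks.sort_values(["individual_id", "timestamp"],
                                kind="mergesort").reset_index(drop=True)
    return tracks, pd.DataFrame(meta_rows), pd.DataFrame(truth_rows)


def inject_defects(tracks: pd.DataFrame,
                   rates: dict[str, float] | None = None,
                   seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Corrupt a relocation table with accuracy outliers (STD 60 fixes),
    speed outliers (2 km jumps 1 s after an existing fix), and data gaps
    (dropped 50-fix stretches), at the given per-fix rates.

    Returns the corrupted table and the injected fix timestamps / dropped
    counts so tests can verify the cleaning filters.
    """
    rates = {"outlier_speed": 0.0, "low_accuracy": 0.0, "gap": 0.0,
             **(rates or {})}
    for k, v in rates.items():
        if not 0 <= v <= 1:
            raise DataError(f"rate {k}={v} outside [0, 1]")
    rng = np.random.default_rng(seed)
    df = tracks.reset_index(drop=True)
    n = len(df)
    info: dict = {"speed_timestamps": [], "std_timestamps": [], "gap_dropped": 0}

    inserts = []
    for kind, rate in (("outlier_speed", rates["outlier_speed"]),
                       ("low_accuracy", rates["low_accuracy"])):
        if rate == 0:
            continue
        k = rng.binomial(n, rate)
        rows = rng.choice(n, size=k, replace=False)
        for r in rows:
            base = df.iloc[r]
            stamp = base["timestamp"] + pd.Timedelta(seconds=1)
            if kind == "outlier_speed":
                inserts.append({
                    "individual_id": base["individual_id"], "timestamp": stamp,
                    "x": base["x"] + 2000.0, "y": base["y"],
                    "accuracy_std": 10.0})
                info["speed_timestamps"].append(stamp)
            else:
                inserts.append({
                    "individual_id": base["individual_id"], "timestamp": stamp,
                    "x": base["x"] + rng.normal(0, 5),
                    "y": base["y"] + rng.normal(0, 5),
                    "accuracy_std": 60.0})
                info["std_timestamps"].append(stamp)

    if rates["gap"] > 0:
        gap_len = 50
        n_gaps = int(round(n * rates["gap"] / gap_len))
        drop = np.zeros(n, dtype=bool)
        for start in rng.choice(max(n - gap_len, 1), size=n_gaps, replace=False):
            drop[start:start + gap_len] = True
        info["gap_dropped"] = int(drop.sum())
        df = df[~drop]

    if inserts:
        df = pd.concat([df, pd.DataFrame(inserts)], ignore_index=True)
    df = df.sort_values(["individual_id", "timestamp"],
                        kind="mergesort").reset_index(drop=True)
    return df, info


# ---------------------------------------------------------------------------
# cohort presets
# ---------------------------------------------------------------------------

_HOMES = [(0.0, 0.0), (10000.0, 2500.0), (20000.0, -1500.0)]


def pure_archetype_cohort(nights_per_individual: int = 50, seed: int = 0,
                          archetypes: tuple[str, ...] = ARCHETYPES,
                          fix_interval_s: float = 8.0) -> CohortSpec:
    """One individual per archetype, every night drawn from that archetype;
    ground truth is then exactly recoverable by clustering."""
    individuals = []
    for i, arch in enumerate(archetypes):
        meta = IndividualMeta(
            f"owl{i + 1:02d}", "female" if i % 2 == 0 else "male",
            "adult" if i % 3 else "young")
        individuals.append(IndividualSpec(
            meta, _HOMES[i % len(_HOMES)], nights_per_individual,
            {arch: 1.0}))
    return CohortSpec(individuals, seed=seed,
                      archetype_specs=owl_archetype_specs(fix_interval_s))


def owl_cohort(n_individuals: int = 8, nights_per_individual: int = 45,
                  seed: int = 0, fix_interval_s: float = 8.0) -> CohortSpec:
    """Mixed cohort with the published archetype proportions, modulated by
    sex and age the way the study reports: males do relatively more medium
    and large excursions, young do relatively more large excursions."""
    base = owl_mixture()
    individuals = []
    for i in range(n_individuals):
        sex = "male" if i % 2 else "female"
        age = "young" if i % 4 < 2 else "adult"
        mix = dict(base)
        if sex == "male":
            shift = 0.04
            mix["closed_local"] -= shift
            mix["closed_small"] -= shift
            mix["closed_medium"] += shift
            mix["closed_large"] += shift
        if age == "young":
            shift = 0.05
            mix["closed_local"] -= shift
            mix["closed_large"] += shift
        meta = IndividualMeta(f"owl{i + 1:02d}", sex, age)
        individuals.append(IndividualSpec(
            meta, _HOMES[i % len(_HOMES)], nights_per_individual, mix))
    return CohortSpec(individuals, seed=seed,
                      archetype_specs=owl_archetype_specs(fix_interval_s))
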