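"""From raw tracks to quality-filtered, diel-segmented, subsampled DARs.

A DAR (diel activity routine) is the movement path of one individual over
one diel window, here boundary_hour (10:00) local time to the same hour the
next day. The stage order is: accuracy/speed fix filtering -> diel
segmentation -> night-quality rules -> individual inclusion -> flight/stop
segmentation -> endpoint averaging -> temporal subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from zoneinfo import ZoneInfo

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import DataError
from .track_io import Track, IndividualMeta

MOVE = "move"
STOP = "stop"


@dataclass
class NightSegment:
    """All fixes of one individual within one diel window.

    ``night_date`` is the local calendar date of the boundary hour that
    opens the window.
    """
    individual_id: str
    night_date: date
    fixes: pd.DataFrame          # timestamp (UTC), x, y, accuracy_std
    local_time: pd.Series        # timestamps converted to the local zone

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class FlightSegment:
    seg_id: int
    first_index: int
    last_index: int              # inclusive
    label: str                   # move | stop


@dataclass
class DAR:
    dar_id: str
    individual_id: str
    night_date: date
    points: pd.DataFrame         # subsampled timestamp, x, y
    start_point: tuple[float, float] | None
    end_point: tuple[float, float] | None
    quality: dict = field(default_factory=dict)


def filter_fixes(track: Track, max_std: float = 50.0, max_speed: float = 15.0
                 ) -> tuple[Track, dict]:
    """Drop low-accuracy fixes (STD > max_std), then any fix implying a
    movement speed > max_speed m/s from the previously *retained* fix.

    The speed rule is a sequential forward pass, the standard telemetry
    cleaning behavior. Returns the filtered track and removal counts.
    """
    df = track.fixes
    counts = {"std": 0, "speed": 0}
    if len(df) == 0:
        return Track(track.individual_id, df.copy()), counts

    keep_std = ~(df["accuracy_std"] > max_std)
    counts["std"] = int((~keep_std).sum())
    df = df[keep_std]
    if len(df) == 0:
        return Track(track.individual_id, df.reset_index(drop=True)), counts

    t = df["timestamp"].astype("int64").to_numpy() / 1e9
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    n = len(df)
    keep = np.ones(n, dtype=bool)
    last = 0
    for i in range(1, n):
        dt = t[i] - t[last]
        if dt <= 0:
            keep[i] = False
            continue
        dist = np.hypot(x[i] - x[last], y[i] - y[last])
        if dist / dt > max_speed:
            keep[i] = False
        else:
            last = i
    counts["speed"] = int((~keep).sum())
    return Track(track.individual_id, df[keep].reset_index(drop=True)), counts


def segment_nights(track: Track, timezone: str = "Asia/Jerusalem",
                   boundary_hour: int = 10) -> list[NightSegment]:
    """Partition a track into diel windows [boundary d, boundary d+1).

    A fix before the boundary hour belongs to the night opened the previous
    day; a fix exactly at the boundary opens a new night (left-closed).
    Empty windows are omitted.
    """
    if len(track) == 0:
        return []
    local = track.fixes["timestamp"].dt.tz_convert(ZoneInfo(timezone))
    night_date = local.dt.normalize().dt.date.copy()
    before = local.dt.hour < boundary_hour
    night_date[before] = (local[before] - pd.Timedelta(days=1)).dt.date

    segments = []
    for nd, idx in pd.Series(range(len(track)), index=track.fixes.index).groupby(night_date):
        rows = idx.to_numpy()
        segments.append(NightSegment(
            track.individual_id, nd,
            track.fixes.iloc[rows].reset_index(drop=True),
            local.iloc[rows].reset_index(drop=True)))
    segments.sort(key=lambda s: s.night_date)
    return segments


def night_is_complete(night: NightSegment, min_fixes: int = 1000,
                      latest_start_hour: float = 21.0,
                      earliest_end_hour: float = 2.0) -> tuple[bool, list[str]]:
    """Complete night: > min_fixes localizations, data collection started
    before latest_start (local, opening day) and ended after earliest_end
    (local, next calendar day). All comparisons strict.
    """
    reasons = []
    if len(night) <= min_fixes:
        reasons.append(f"count {len(night)} <= {min_fixes}")
    tz = night.local_time.dt.tz
    d0 = night.night_date

    def at(day: date, hour: float) -> pd.Timestamp:
        h = int(hour)
        m = int(round((hour - h) * 60))
        return pd.Timestamp(datetime.combine(day, time(h, m)), tz=tz)

    if len(night) > 0:
        if not night.local_time.iloc[0] < at(d0, latest_start_hour):
            reasons.append("started at or after latest allowed start")
        if not night.local_time.iloc[-1] > at(d0 + timedelta(days=1), earliest_end_hour):
            reasons.append("ended at or before earliest allowed end")
    else:
        reasons.append("empty night")
    return (len(reasons) == 0), reasons


def select_individuals(night_counts: dict[str, int], min_nights: int = 30) -> set[str]:
    """Individuals with strictly more than min_nights complete nights."""
    return {ind for ind, c in night_counts.items() if c > min_nights}


def _run_lengths(labels: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs of equal values as (start, stop-exclusive) pairs."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i))
            start = i
    return runs


def detect_flight_segments(night: NightSegment, window_s: float = 60.0,
                           speed_threshold: float = 2.0,
                           min_run_s: float = 60.0) -> list[FlightSegment]:
    """Partition a night into alternating move/stop runs.

    A fix is provisionally "move" when the median speed over a centered
    sliding time window exceeds the threshold; provisional runs shorter than
    the minimum duration are merged into their neighbors (shortest first),
    which is deterministic for fixed input and parameters.
    """
    n = len(night)
    if n < 2:
        return [FlightSegment(0, 0, max(n - 1, 0), STOP)]

    t = night.fixes["timestamp"].astype("int64").to_numpy() / 1e9
    x = night.fixes["x"].to_numpy()
    y = night.fixes["y"].to_numpy()
    dt = np.diff(t)
    dt[dt <= 0] = np.nan
    speed = np.hypot(np.diff(x), np.diff(y)) / dt
    speed = np.concatenate([[speed[0] if np.isfinite(speed[0]) else 0.0], speed])
    speed = np.nan_to_num(speed, nan=0.0)

    med = (pd.Series(speed, index=pd.to_datetime(t, unit="s"))
           .rolling(f"{int(window_s)}s", center=True, min_periods=1)
           .median()
           .to_numpy())
    moving = med > speed_threshold

    # merge runs shorter than min_run_s into their neighbors, shortest first
    while True:
        runs = _run_lengths(moving)
        if len(runs) == 1:
            break
        durations = [t[b - 1] - t[a] for a, b in runs]
        order = sorted(range(len(runs)), key=lambda i: (durations[i], i))
        flipped = False
        for i in order:
            if durations[i] < min_run_s:
                a, b = runs[i]
                moving[a:b] = ~moving[a:b]
                flipped = True
                break
        if not flipped:
            break

    segments = []
    for seg_id, (a, b) in enumerate(_run_lengths(moving)):
        segments.append(FlightSegment(seg_id, a, b - 1, MOVE if moving[a] else STOP))
    return segments


def extract_endpoints(night: NightSegment, segments: list[FlightSegment],
                      n: int = 20) -> tuple[tuple[float, float] | None,
                                            tuple[float, float] | None, bool]:
    """Average the n fixes immediately before the first flight segment
    (start point) and after the last flight segment (end point).

    An endpoint is missing when fewer than n such fixes exist; this is the
    source of NA rows later dropped before clustering. With no flight
    segment at all, the first/last n fixes are used and the night is
    flagged no-flight. Returns (start, end, no_flight).
    """
    xy = night.fixes[["x", "y"]].to_numpy()
    moves = [s for s in segments if s.label == MOVE]

    def mean_of(sl: slice) -> tuple[float, float] | None:
        pts = xy[sl]
        if len(pts) < n:
            return None
        return (float(pts[:, 0].mean()), float(pts[:, 1].mean()))

    if not moves:
        start = mean_of(slice(0, n))
        end = mean_of(slice(max(len(xy) - n, 0), len(xy)))
        return start, end, True

    first, last = moves[0], moves[-1]
    start = mean_of(slice(max(first.first_index - n, 0), first.first_index)) \
        if first.first_index >= n else None
    after = last.last_index + 1
    end = mean_of(slice(after, after + n)) if len(xy) - after >= n else None
    return start, end, False


def subsample(night: NightSegment, interval_s: float = 300.0) -> pd.DataFrame:
    """Keep the first fix in each interval bin of a grid anchored at the
    night's first fix; output is a subsequence of the input."""
    if len(night) == 0:
        raise DataError("cannot subsample an empty night")
    t = night.fixes["timestamp"].astype("int64").to_numpy() / 1e9
    bins = np.floor((t - t[0]) / interval_s).astype(int)
    first_in_bin = np.ones(len(t), dtype=bool)
    first_in_bin[1:] = bins[1:] != bins[:-1]
    return night.fixes.loc[first_in_bin, ["timestamp", "x", "y"]].reset_index(drop=True)


def build_dars(tracks: list[Track], metadata: list[IndividualMeta] | None,
               config: RunConfig | None = None) -> tuple[list[DAR], dict]:
    """Run the whole extraction pipeline and return DARs plus a stage report.

    The report records fix/night/individual attrition at each stage and the
    dates of incomplete nights (used downstream as NA markers in temporal
    sequences).
    """
    cfg = config or RunConfig()
    report: dict = {
        "n_tracks": len(tracks),
        "fixes_in": int(sum(len(t) for t in tracks)),
        "removed_std": 0, "removed_speed": 0,
        "nights_seen": 0, "nights_complete": 0,
        "incomplete_nights": [],
        "individuals_selected": [],
        "dars": 0,
    }

    per_individual_nights: dict[str, list[NightSegment]] = {}
    complete_counts: dict[str, int] = {}
    for track in tracks:
        if cfg.count_after_filtering:
            track, counts = filter_fixes(track, cfg.max_std, cfg.max_speed)
            report["removed_std"] += counts["std"]
            report["removed_speed"] += counts["speed"]
        nights = segment_nights(track, cfg.timezone, cfg.boundary_hour)
        if not cfg.count_after_filtering:
            # completeness judged on raw counts; filtering applied per night after
            raise NotImplementedError("count_after_filtering=False not supported")
        report["nights_seen"] += len(nights)
        kept = []
        for night in nights:
            ok, reasons = night_is_complete(
                night, cfg.min_fixes, cfg.latest_start_hour, cfg.earliest_end_hour)
            if ok:
                kept.append(night)
            else:
                report["incomplete_nights"].append(
                    (track.individual_id, night.night_date, reasons))
        per_individual_nights[track.individual_id] = kept
        complete_counts[track.individual_id] = len(kept)
        report["nights_complete"] += len(kept)

    selected = select_individuals(complete_counts, cfg.min_nights)
    report["individuals_selected"] = sorted(selected)

    dars: list[DAR] = []
    for ind in sorted(selected):
        for night in per_individual_nights[ind]:
            segments = detect_flight_segments(
                night, cfg.flight_window_s, cfg.flight_speed_threshold,
                cfg.flight_min_run_s)
            start, end, no_flight = extract_endpoints(night, segments, cfg.endpoint_n)
            points = subsample(night, cfg.subsample_s)
            dars.append(DAR(
                dar_id=f"{ind}_{night.night_date.isoformat()}",
                individual_id=ind,
                night_date=night.night_date,
                points=points,
                start_point=start,
                end_point=end,
                quality={
                    "n_raw_fixes": len(night),
                    "started_before": True,
                    "ended_after": True,
                    "no_flight": no_flight,
                    "start_missing": start is None,
                    "end_missing": end is None,
                },
            ))
    report["dars"] = len(dars)
    return dars, report


def dars_to_frames(dars: list[DAR]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular export: one row per DAR plus a long points table keyed by dar_id."""
    if not dars:
        raise DataError("no DARs to export")
    rows, pts = [], []
    for d in dars:
        rows.append({
            "dar_id": d.dar_id, "individual_id": d.individual_id,
            "night_date": d.night_date,
            "start_x": d.start_point[0] if d.start_point else np.nan,
            "start_y": d.start_point[1] if d.start_point else np.nan,
            "end_x": d.end_point[0] if d.end_point else np.nan,
            "end_y": d.end_point[1] if d.end_point else np.nan,
            **{f"q_{k}": v for k, v in d.quality.items()},
        })
        p = d.points.copy()
        p.insert(0, "dar_id", d.dar_id)
        pts.append(p)
    return pd.DataFrame(rows), pd.concat(pts, ignore_index=True)
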