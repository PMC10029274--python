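"""Reading and writing relocation tables and individual metadata.

Coordinates are consumed already projected, in meters (the barn-owl study
uses Israeli Transverse Mercator); no geographic support in core.
Timestamps are stored timezone-aware in UTC; diel logic later interprets
them in a single configured IANA zone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .config import RunConfig
from .errors import ConfigError, DataError

SEX_TOKENS = {"f": "female", "female": "female", "m": "male", "male": "male"}
AGE_TOKENS = {"young": "young", "juvenile": "young", "adult": "adult"}

FIX_COLUMNS = ["timestamp", "x", "y", "accuracy_std"]


@dataclass
class Track:
    """Time-ordered fixes of one individual.

    ``fixes`` is a DataFrame with columns timestamp (UTC tz-aware), x, y,
    accuracy_std (NaN when missing), strictly increasing in time.
    """

    individual_id: str
    fixes: pd.DataFrame

    def __post_init__(self) -> None:
        ts = self.fixes["timestamp"]
        if len(ts) > 1 and not ts.is_monotonic_increasing:
            raise DataError(f"track {self.individual_id}: timestamps not sorted")

    def __len__(self) -> int:
        return len(self.fixes)


@dataclass
class IndividualMeta:
    individual_id: str
    sex: str                      # female | male
    age_class: str                # young (<= 1 yr at assignment) | adult
    birth_or_assignment_date: date | None = None
    family_id: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise DataError(f"{self.individual_id}: unknown sex {self.sex!r}")
        if self.age_class not in ("young", "adult"):
            raise DataError(f"{self.individual_id}: unknown age class {self.age_class!r}")


def read_tracks(path: str, config: RunConfig | None = None) -> tuple[list[Track], int]:
    """Read a delimited relocation table into one :class:`Track` per individual.

    Rows are sorted by time within individual; duplicate (individual,
    timestamp) rows are collapsed to the first. Returns the tracks and the
    number of dropped duplicate rows.
    """
    config = config or RunConfig()
    df = pd.read_csv(path, delimiter=config.delimiter)
    cols = config.columns
    unknown = [v for k, v in cols.items() if k != "accuracy_std" and v not in df.columns]
    if unknown:
        raise ConfigError(f"{path}: mapped columns not in file: {unknown}")

    out = pd.DataFrame({
        "individual_id": df[cols["individual_id"]].astype(str),
    })
    ts = pd.to_datetime(df[cols["timestamp"]], errors="coerce", utc=False, format="ISO8601")
    bad = ts.isna() & df[cols["timestamp"]].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise DataError(f"{path}: unparseable timestamp at data row {row}: "
                        f"{df[cols['timestamp']].iloc[row]!r}")
    if ts.dt.tz is None:
        # naive timestamps are interpreted in the configured local zone
        ts = ts.dt.tz_localize(config.timezone, ambiguous="NaT", nonexistent="NaT")
        if ts.isna().any():
            row = int(np.flatnonzero(ts.isna().to_numpy())[0])
            raise DataError(f"{path}: ambiguous local timestamp at data row {row}")
    out["timestamp"] = ts.dt.tz_convert("UTC")

    for key in ("x", "y"):
        vals = pd.to_numeric(df[cols[key]], errors="coerce")
        bad = vals.isna() | ~np.isfinite(vals)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(f"{path}: non-numeric {key} at data row {row}: "
                            f"{df[cols[key]].iloc[row]!r}")
        out[key] = vals.astype(float)

    std_col = cols.get("accuracy_std")
    if std_col is not None and std_col in df.columns:
        std = pd.to_numeric(df[std_col], errors="coerce").astype(float)
        if (std.dropna() < 0).any():
            raise DataError(f"{path}: negative accuracy STD values present")
        out["accuracy_std"] = std
    else:
        out["accuracy_std"] = np.nan

    out = out.sort_values(["individual_id", "timestamp"], kind="mergesort")
    before = len(out)
    out = out.drop_duplicates(subset=["individual_id", "timestamp"], keep="first")
    dropped = before - len(out)

    tracks = [
        Track(ind, g[FIX_COLUMNS].reset_index(drop=True))
        for ind, g in out.groupby("individual_id", sort=True)
    ]
    return tracks, dropped


def read_metadata(path: str, config: RunConfig | None = None
                  ) -> tuple[list[IndividualMeta], list[str]]:
    """Read the individual-metadata table (ring ID, sex, age class).

    Unknown sex/age tokens reject the record with a message; duplicate ring
    IDs are a hard error. Returns (records, rejection messages).
    """
    config = config or RunConfig()
    df = pd.read_csv(path, delimiter=config.delimiter)
    cols = {c.lower(): c for c in df.columns}

    def col(*names: str) -> str | None:
        for n in names:
            if n in cols:
                return cols[n]
        return None

    id_col = col("individual_id", "ring_id", "ringid", "id")
    sex_col = col("sex")
    age_col = col("age_class", "age")
    if id_col is None or sex_col is None or age_col is None:
        raise ConfigError(f"{path}: need ring ID, sex and age columns")
    birth_col = col("birth_or_assignment_date", "birth_date", "assignment_date")
    family_col = col("family_id", "family")

    ids = df[id_col].astype(str)
    dupes = ids[ids.duplicated()].unique()
    if len(dupes):
        raise DataError(f"{path}: duplicate ring IDs: {list(dupes)}")

    records: list[IndividualMeta] = []
    rejected: list[str] = []
    for i, row in df.iterrows():
        sex = SEX_TOKENS.get(str(row[sex_col]).strip().lower())
        age = AGE_TOKENS.get(str(row[age_col]).strip().lower())
        if sex is None or age is None:
            rejected.append(
                f"row {i} ({row[id_col]}): unrecognized "
                f"{'sex ' + repr(row[sex_col]) if sex is None else ''}"
                f"{' ' if sex is None and age is None else ''}"
                f"{'age ' + repr(row[age_col]) if age is None else ''}".strip())
            continue
        birth = None
        if birth_col is not None and pd.notna(row[birth_col]):
            birth = pd.Timestamp(row[birth_col]).date()
        family = None
        if family_col is not None and pd.notna(row[family_col]):
            family = str(row[family_col])
        records.append(IndividualMeta(str(row[id_col]), sex, age, birth, family))
    return records, rejected


def write_table(records: pd.DataFrame, path: str, delimiter: str = ",") -> None:
    """Write a tabular artifact as delimited text; round-trips through pandas."""
    if records is None or len(records) == 0:
        raise DataError(f"refusing to write empty table to {path}")
    records.to_csv(path, index=False, sep=delimiter)


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Concatenate tracks back into one long relocation table."""
    frames = []
    for t in tracks:
        f = t.fixes.copy()
        f.insert(0, "individual_id", t.individual_id)
        frames.append(f)
    if not frames:
        raise DataError("no tracks to concatenate")
    return pd.concat(frames, ignore_index=True)


def metadata_to_frame(metas: list[IndividualMeta]) -> pd.DataFrame:
    return pd.DataFrame({
        "individual_id": [m.individual_id for m in metas],
        "sex": [m.sex for m in metas],
        "age_class": [m.age_class for m in metas],
        "birth_or_assignment_date": [m.birth_or_assignment_date for m in metas],
        "family_id": [m.family_id for m in metas],
    })
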