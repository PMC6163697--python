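"""Personal dosimetry recordings: parsing, cleaning, and subgroup labeling.

A recording is a uniformly sampled series of magnetic-field magnitudes (µT)
worn by one subject, accompanied by questionnaire metadata. The analysis
operates on complete calendar days (00:00-24:00): at a 30-s sample interval a
full day holds 2880 samples, at 3 s it holds 28,800. Recordings shorter than
24 h are discarded; longer ones are cut at midnight. Subjects whose alarm
clock stood within 50 cm of the bed can be excluded (a protocol rule of one of the
campaigns this methodology targets),
because the alarm clock dominates the night-time field.

Events (stationary segments) and days are labeled along four subgroup
dimensions: day/night window, age group, town-size class, and
distance-to-substation class. The vocabularies are closed; see
``subgroup_vocabulary``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

SECONDS_PER_DAY = 86_400

#: day window is [07:00, 21:00); night is the complement [21:00, 07:00).
DAY_WINDOW_START_S = 7 * 3600
DAY_WINDOW_END_S = 21 * 3600

AGE_GROUPS = ("0-4", "5-9", "10-14")
INHABITANT_CLASSES = (
    "rural (<2000 inhab.)",
    "2000-4999 inhab.",
    "5000-9999 inhab.",
    "10000-19999 inhab.",
    "20000-49999 inhab.",
    "50000-99999 inhab.",
    "100000-199999 inhab.",
    "200000-1999999 inhab.",
)
#: upper bounds (exclusive) matching INHABITANT_CLASSES
_INHABITANT_BOUNDS = (2000, 5000, 10_000, 20_000, 50_000, 100_000, 200_000, 2_000_000)
SUBSTATION_CLASSES = (">=40 m", "<40 m", "same building or adjacent")
DAYNIGHT_LEVELS = ("day", "night")

SUBGROUP_DIMENSIONS = {
    "daynight": DAYNIGHT_LEVELS,
    "age": AGE_GROUPS,
    "inhabitants": INHABITANT_CLASSES,
    "substation": SUBSTATION_CLASSES,
}


class SubgroupKey(NamedTuple):
    """One level of one subgroup dimension, e.g. ('age', '5-9')."""

    dimension: str
    level: str


def subgroup_vocabulary() -> pd.DataFrame:
    """Machine-readable table of every (dimension, level) pair."""
    with resources.files("elf_expochar.data").joinpath("subgroup_vocabulary.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class Recording:
    """A raw uniformly sampled exposure series for one subject.

    values are field magnitudes in µT, one per sample_interval_s starting at
    start_time. Metadata carries the questionnaire fields used for subgroup
    assignment.
    """

    subject_id: str
    start_time: dt.datetime
    sample_interval_s: int
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("recording needs a 1-D series with at least one sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("recording contains non-finite values")
        if np.any(self.values < 0):
            raise ValueError("field magnitudes must be non-negative")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.size

    def time_of(self, index: int) -> dt.datetime:
        return self.start_time + dt.timedelta(seconds=index * self.sample_interval_s)


@dataclass
class DayRecording:
    """Exactly one 00:00-24:00 day: 86400 / sample_interval_s samples."""

    subject_id: str
    date: dt.date
    sample_interval_s: int
    values: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        expected = SECONDS_PER_DAY // self.sample_interval_s
        if self.values.size != expected:
            raise ValueError(
                f"a full day at {self.sample_interval_s} s holds {expected} samples, "
                f"got {self.values.size}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def start_time(self) -> dt.datetime:
        return dt.datetime.combine(self.date, dt.time(0, 0))


# ---------------------------------------------------------------------------
# I/O


def read_recording(path, metadata: dict | None = None) -> Recording:
    """Parse a recording CSV (columns ``timestamp_iso,field_uT``).

    Timestamps must form a uniform grid; the first gap or irregular step is
    reported in the error message.
    """
    df = pd.read_csv(path)
    if list(df.columns) != ["timestamp_iso", "field_uT"]:
        raise ValueError(f"{path}: expected columns timestamp_iso,field_uT, got {list(df.columns)}")
    if len(df) < 1:
        raise ValueError(f"{path}: empty recording")
    try:
        times = pd.to_datetime(df["timestamp_iso"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"{path}: unparseable timestamp: {exc}") from exc
    values = pd.to_numeric(df["field_uT"], errors="raise").to_numpy(dtype=float)
    if len(df) >= 2:
        steps = times.diff().dt.total_seconds().to_numpy()[1:]
        interval = steps[0]
        bad = np.nonzero(steps != interval)[0]
        if interval <= 0:
            raise ValueError(f"{path}: non-increasing timestamps at row 1 ({times.iloc[1]})")
        if bad.size:
            i = int(bad[0]) + 1
            raise ValueError(
                f"{path}: non-uniform sampling: step before {times.iloc[i + 1]} is "
                f"{steps[bad[0]]} s, expected {interval} s"
            )
        interval = int(interval)
    else:
        interval = int((metadata or {}).get("sample_interval_s", 30))
    meta = dict(metadata or {})
    subject_id = str(meta.get("subject_id", "unknown"))
    return Recording(
        subject_id=subject_id,
        start_time=times.iloc[0].to_pydatetime(),
        sample_interval_s=interval,
        values=values,
        metadata=meta,
    )


def write_recording(rec: Recording | DayRecording, path) -> None:
    """Write the ``timestamp_iso,field_uT`` CSV for a recording or day."""
    start = rec.start_time if isinstance(rec, Recording) else dt.datetime.combine(rec.date, dt.time())
    times = pd.date_range(start=start, periods=rec.n_samples, freq=f"{rec.sample_interval_s}s")
    pd.DataFrame(
        {"timestamp_iso": times.strftime("%Y-%m-%dT%H:%M:%S"), "field_uT": rec.values}
    ).to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Cleaning rules


def extract_full_days(rec: Recording) -> list[DayRecording]:
    """Keep only complete 00:00-24:00 days; trim partial leading/trailing data.

    Recordings spanning less than 24 h produce an empty list. A day is kept
    only if midnight falls exactly on the sampling grid and the following
    86400 s are fully covered.
    """
    interval = rec.sample_interval_s
    per_day = SECONDS_PER_DAY // interval
    start = rec.start_time
    first_midnight = dt.datetime.combine(start.date(), dt.time())
    if first_midnight < start:
        first_midnight += dt.timedelta(days=1)
    offset_s = (first_midnight - start).total_seconds()
    if offset_s % interval != 0:
        return []  # midnight never aligns with the sampling grid
    days: list[DayRecording] = []
    i = int(offset_s) // interval
    while i + per_day <= rec.n_samples:
        date = (first_midnight + dt.timedelta(days=len(days))).date()
        days.append(
            DayRecording(
                subject_id=rec.subject_id,
                date=date,
                sample_interval_s=interval,
                values=rec.values[i : i + per_day],
                metadata=rec.metadata,
            )
        )
        i += per_day
    return days


@dataclass(frozen=True)
class ExclusionRules:
    """Cohort-level exclusion switches (the alarm-clock protocol rule)."""

    exclude_alarm_clock_near: bool = True


def apply_exclusions(recs: Iterable[Recording], rules: ExclusionRules | None = None) -> list[Recording]:
    """Drop recordings whose metadata flags an alarm clock within 50 cm of the bed."""
    rules = rules or ExclusionRules()
    recs = list(recs)
    if not rules.exclude_alarm_clock_near:
        return recs
    return [r for r in recs if not bool(r.metadata.get("alarm_clock_near", False))]


# ---------------------------------------------------------------------------
# Subgroup scheme


def age_group(age_years: float) -> str:
    if 0 <= age_years <= 4:
        return "0-4"
    if 5 <= age_years <= 9:
        return "5-9"
    if 10 <= age_years <= 14:
        return "10-14"
    raise ValueError(f"age {age_years} outside the 0-14 study range")


def inhabitants_group(inhabitants: float) -> str:
    if inhabitants < 0:
        raise ValueError("inhabitants must be non-negative")
    for bound, label in zip(_INHABITANT_BOUNDS, INHABITANT_CLASSES):
        if inhabitants < bound:
            return label
    raise ValueError(f"town size {inhabitants} above the largest class (<2,000,000)")


def assign_subgroups(meta: dict) -> set[SubgroupKey]:
    """Map subject metadata to one level per applicable subgroup dimension.

    Returns keys for every dimension whose metadata field is present;
    unknown levels raise rather than silently passing through.
    """
    keys: set[SubgroupKey] = set()
    if "age_years" in meta:
        keys.add(SubgroupKey("age", age_group(float(meta["age_years"]))))
    if "inhabitants" in meta:
        keys.add(SubgroupKey("inhabitants", inhabitants_group(float(meta["inhabitants"]))))
    if "substation_class" in meta:
        level = str(meta["substation_class"])
        if level not in SUBSTATION_CLASSES:
            raise ValueError(
                f"substation class {level!r} not in {SUBSTATION_CLASSES}"
            )
        keys.add(SubgroupKey("substation", level))
    return keys


def _day_overlap_s(start: dt.datetime, end: dt.datetime) -> float:
    """Seconds of [start, end) falling inside any 07:00-21:00 day window."""
    total = 0.0
    d = start.date()
    while dt.datetime.combine(d, dt.time()) < end:
        w0 = dt.datetime.combine(d, dt.time()) + dt.timedelta(seconds=DAY_WINDOW_START_S)
        w1 = dt.datetime.combine(d, dt.time()) + dt.timedelta(seconds=DAY_WINDOW_END_S)
        lo, hi = max(start, w0), min(end, w1)
        if hi > lo:
            total += (hi - lo).total_seconds()
        d += dt.timedelta(days=1)
    return total


def assign_daynight(start: dt.datetime, end: dt.datetime) -> str:
    """Label an event window 'day' or 'night' by majority overlap.

    Day is [07:00, 21:00); a window with at least half its duration in the
    day window is 'day' (ties break toward day).
    """
    dur = (end - start).total_seconds()
    if dur <= 0:
        raise ValueError("zero-length event window")
    return "day" if _day_overlap_s(start, end) >= dur / 2 else "night"
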