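"""Reading device exports and building the aligned per-minute series.

Consumer wrist devices report heart rate once per minute and step counts
as 15-minute totals.  To fuse the two streams in a single minute-level
model, the 15-minute step totals are downscaled by even division across
their bin, days on which the device was evidently not worn are dropped,
and activity level is defined as ``log(steps + 1)`` per minute.  Heart
rate gaps that survive day screening are kept and flagged; the model's
likelihood handles them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RawRecording",
    "EpochSeries",
    "NonwearReport",
    "ParticipantExcludedError",
    "read_raw_recording",
    "downscale_steps",
    "detect_nonwear_days",
    "build_epoch_series",
]

#: minutes of missing heart rate above which a day counts as nonwear
NONWEAR_MISSING_HR_MINUTES = 30
#: fraction of nonwear days above which a participant is excluded
EXCLUSION_FRACTION = 0.5

STEP_BIN_MINUTES = 15
MINUTES_PER_DAY = 1440


class ParticipantExcludedError(ValueError):
    """Raised when a recording has no usable wear days left."""


@dataclass
class RawRecording:
    """Device-format streams for one participant.

    ``hr`` is a minute-resolution series of beats per minute (missing
    minutes simply absent); ``steps15`` holds 15-minute step totals
    indexed by bin start; ``stages`` optionally carries the device's own
    minute-level sleep-stage labels for later agreement comparison.
    """

    participant_id: str
    hr: pd.Series
    steps15: pd.Series
    stages: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.hr = _clean_stream(self.hr, "hr")
        self.steps15 = _clean_stream(self.steps15, "steps15")
        if self.stages is not None:
            self.stages = _clean_stream(self.stages, "stages")
        bpm = self.hr.dropna()
        bad = bpm[(bpm <= 20) | (bpm >= 250)]
        if len(bad):
            raise ValueError(
                f"heart-rate values outside (20, 250) bpm at {bad.index[0]}"
            )

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        """Start and (exclusive) end of the recording across both streams."""
        starts = [self.hr.index[0], self.steps15.index[0]]
        ends = [
            self.hr.index[-1] + pd.Timedelta(minutes=1),
            self.steps15.index[-1] + pd.Timedelta(minutes=STEP_BIN_MINUTES),
        ]
        return min(starts), max(ends)


def _clean_stream(s: pd.Series, name: str) -> pd.Series:
    if not isinstance(s.index, pd.DatetimeIndex):
        raise TypeError(f"{name}: index must be datetime timestamps")
    s = s.sort_index()
    if s.index.has_duplicates:
        warnings.warn(f"{name}: duplicate timestamps, keeping first occurrence")
        s = s[~s.index.duplicated(keep="first")]
    return s


@dataclass
class NonwearReport:
    """Per-day wear screening for one participant.

    ``days`` has one row per complete calendar day with the minutes of
    missing heart rate, the daily step total, and the nonwear flag; a
    day is nonwear when either rule fires (excess missing heart rate or
    a zero step total).
    """

    participant_id: str
    days: pd.DataFrame  # index: date; columns missing_hr_minutes, total_steps, nonwear
    nonwear_fraction: float
    excluded: bool

    @property
    def wear_dates(self) -> list:
        return list(self.days.index[~self.days["nonwear"]])


@dataclass
class EpochSeries:
    """Aligned 1-minute bivariate observations.

    ``frame`` is indexed by minute timestamps (gaps where nonwear days
    were removed) with columns ``hr`` (bpm, NaN when missing), ``step``
    (per-minute downscaled steps, may be fractional), ``act``
    (= log(step + 1)), ``hr_missing``, ``day`` (ordinal index of the
    retained day) and ``dow`` (0=Monday .. 6=Sunday).
    """

    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def hr(self) -> np.ndarray:
        return self.frame["hr"].to_numpy(dtype=float)

    @property
    def act(self) -> np.ndarray:
        return self.frame["act"].to_numpy(dtype=float)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.frame.index

    @classmethod
    def from_arrays(
        cls,
        hr: Sequence[float],
        act: Optional[Sequence[float]] = None,
        step: Optional[Sequence[float]] = None,
        start: str | pd.Timestamp = "2018-01-01 00:00",
    ) -> "EpochSeries":
        """Build a series directly from minute-level arrays.

        Exactly one of ``act``/``step`` may be given (``act`` wins if
        both); missing values are NaN.
        """
        hr = np.asarray(hr, dtype=float)
        if act is None:
            if step is None:
                raise ValueError("need act or step")
            step = np.asarray(step, dtype=float)
            act = np.log1p(step)
        else:
            act = np.asarray(act, dtype=float)
            step = np.expm1(act) if step is None else np.asarray(step, dtype=float)
        if len(act) != len(hr):
            raise ValueError("hr and act lengths differ")
        idx = pd.date_range(start, periods=len(hr), freq="min")
        frame = pd.DataFrame(
            {
                "hr": hr,
                "step": step,
                "act": act,
                "hr_missing": ~np.isfinite(hr),
                "day": (idx.normalize() - idx[0].normalize()).days,
                "dow": idx.dayofweek.to_numpy(dtype="int64"),
            },
            index=idx,
        )
        return cls(frame)

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "timestamp"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "EpochSeries":
        frame = pd.read_csv(path, index_col="timestamp", parse_dates=["timestamp"])
        frame["hr_missing"] = frame["hr_missing"].astype(bool)
        frame.index.name = None
        return cls(frame)


def read_raw_recording(
    hr_path,
    steps_path,
    stages_path=None,
    participant_id: str = "anon",
) -> RawRecording:
    """Read the two (optionally three) per-participant CSV exports.

    ``hr.csv`` has columns (timestamp, bpm) — missing minutes are absent
    rows or empty bpm cells; ``steps.csv`` has (timestamp, steps) with
    bin-start timestamps; ``stages.csv`` has (timestamp, stage).
    """
    hr_df = pd.read_csv(hr_path, parse_dates=["timestamp"])
    hr = pd.Series(
        pd.to_numeric(hr_df["bpm"], errors="coerce").to_numpy(),
        index=pd.DatetimeIndex(hr_df["timestamp"]).floor("min"),
    ).dropna()
    st_df = pd.read_csv(steps_path, parse_dates=["timestamp"])
    steps = pd.Series(
        st_df["steps"].to_numpy(dtype=float),
        index=pd.DatetimeIndex(st_df["timestamp"]),
    )
    stages = None
    if stages_path is not None:
        sg = pd.read_csv(stages_path, parse_dates=["timestamp"])
        stages = pd.Series(
            sg["stage"].astype(str).to_numpy(),
            index=pd.DatetimeIndex(sg["timestamp"]).floor("min"),
        )
    return RawRecording(participant_id, hr, steps, stages)


def downscale_steps(steps15: pd.Series) -> pd.Series:
    """Evenly divide each 15-minute step total across its 15 minutes.

    Every minute of a bin receives count/15, so the bin total is
    preserved exactly; bins absent from the input yield 15 NaN minutes.
    Returns a minute-indexed series spanning first bin start to last bin
    end.
    """
    if len(steps15) == 0:
        raise ValueError("empty step stream")
    steps15 = _clean_stream(steps15, "steps15")
    vals = steps15.to_numpy(dtype=float)
    if np.nanmin(vals) < 0:
        t = steps15.index[np.nanargmin(vals)]
        raise ValueError(f"negative step count at {t}")
    misaligned = (steps15.index.minute % STEP_BIN_MINUTES != 0) | (
        steps15.index.second != 0
    )
    if misaligned.any():
        t = steps15.index[misaligned][0]
        raise ValueError(f"step bin start not on a 15-minute boundary: {t}")
    grid = pd.date_range(
        steps15.index[0],
        steps15.index[-1] + pd.Timedelta(minutes=STEP_BIN_MINUTES - 1),
        freq="min",
    )
    per_min = steps15.reindex(grid.floor(f"{STEP_BIN_MINUTES}min")) / STEP_BIN_MINUTES
    per_min.index = grid
    return per_min


def detect_nonwear_days(rec: RawRecording) -> NonwearReport:
    """Flag nonwear days and decide participant exclusion.

    A complete calendar day is nonwear when more than
    ``NONWEAR_MISSING_HR_MINUTES`` minutes of heart rate are missing or
    the daily step total is zero (a removed device reports no steps).
    Partial first/last days are not counted.  The participant is
    excluded when more than half of the counted days are nonwear.
    """
    if len(rec.hr) == 0 or len(rec.steps15) == 0:
        raise ValueError("empty recording")
    start, end = rec.span
    first_day = start.normalize() if start == start.normalize() else start.normalize() + pd.Timedelta(days=1)
    last_day_end = end.normalize()  # exclusive
    dates = pd.date_range(first_day, last_day_end - pd.Timedelta(days=1), freq="D")
    if len(dates) == 0:
        raise ValueError("recording does not span a full calendar day")
    hr_per_day = rec.hr.groupby(rec.hr.index.normalize()).size()
    steps_per_day = rec.steps15.groupby(rec.steps15.index.normalize()).sum()
    rows = []
    for d in dates:
        observed = int(hr_per_day.get(d, 0))
        missing = MINUTES_PER_DAY - observed
        total = float(steps_per_day.get(d, 0.0))
        nonwear = (missing > NONWEAR_MISSING_HR_MINUTES) or (total == 0)
        rows.append((d, missing, total, nonwear))
    days = pd.DataFrame(
        rows, columns=["date", "missing_hr_minutes", "total_steps", "nonwear"]
    ).set_index("date")
    frac = float(days["nonwear"].mean())
    return NonwearReport(rec.participant_id, days, frac, frac > EXCLUSION_FRACTION)


def build_epoch_series(rec: RawRecording, report: NonwearReport) -> EpochSeries:
    """Assemble the per-minute bivariate series over retained wear days.

    Nonwear days are dropped, steps are downscaled to minutes, activity
    level is log(step + 1), and residual missing heart-rate minutes are
    kept with ``hr_missing`` set — the model likelihood deals with them.
    """
    wear = report.wear_dates
    if not wear:
        raise ParticipantExcludedError(
            f"participant {rec.participant_id} excluded: all days nonwear"
        )
    per_min_steps = downscale_steps(rec.steps15)
    parts = []
    for k, d in enumerate(wear):
        idx = pd.date_range(d, periods=MINUTES_PER_DAY, freq="min")
        step = per_min_steps.reindex(idx).to_numpy(dtype=float)
        hr = rec.hr.reindex(idx).to_numpy(dtype=float)
        parts.append(
            pd.DataFrame(
                {
                    "hr": hr,
                    "step": step,
                    "act": np.log1p(step),
                    "hr_missing": ~np.isfinite(hr),
                    "day": k,
                    "dow": idx.dayofweek.to_numpy(dtype="int64"),
                },
                index=idx,
            )
        )
    return EpochSeries(pd.concat(parts))
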