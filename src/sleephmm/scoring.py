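"""From decoded states to sleep/wake scores.

Decoded hidden states are mapped to sleep/wake by their emission means
(the higher-heart-rate, higher-activity state is wake), then passed
through the Webster rescoring rules, which correct actigraphy's
systematic over-scoring of sleep by converting short sleep bouts
adjacent to long wake runs into wake.  Helpers compare scorers
minute-by-minute, reclassify a device's native sleep stages to binary
sleep/wake, and total the sleep minutes inside a habitual bedtime
window per night.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass
from itertools import product
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .model import FitResult, viterbi_decode
from .preprocess import EpochSeries

__all__ = [
    "SLEEP",
    "WAKE",
    "ScoredSeries",
    "SleepWindow",
    "Agreement",
    "label_states",
    "webster_rescore",
    "score_series",
    "compare_scorers",
    "reclassify_fitbit",
    "minute_agreement",
    "total_sleep_time",
]

SLEEP = "sleep"
WAKE = "wake"

#: device stage vocabulary -> binary label
FITBIT_STAGE_MAP = {
    "asleep": SLEEP, "deep": SLEEP, "light": SLEEP, "rem": SLEEP,
    "restless": WAKE, "awake": WAKE, "wake": WAKE,
}

#: Webster rules 1-3: after >= n_wake minutes of wake, the first
#: n_rescore sleep minutes are rescored wake
_TRAILING_RULES = ((4, 1), (10, 3), (15, 4))
#: Webster rules 4-5: sleep runs of <= max_sleep minutes flanked by
#: >= n_wake minutes of wake are rescored wake entirely
_SURROUND_RULES = ((6, 10), (10, 20))


@dataclass
class ScoredSeries:
    """Per-minute sleep/wake labels before and after rescoring.

    ``raw`` and ``rescored`` are object arrays of ``'sleep'``/``'wake'``
    (``None`` marks minutes the scorer has no record for, e.g. device
    gaps); rescoring only ever turns sleep into wake.
    """

    timestamps: Optional[pd.DatetimeIndex]
    raw: np.ndarray
    rescored: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=object)
        self.rescored = np.asarray(self.rescored, dtype=object)
        if len(self.raw) != len(self.rescored):
            raise ValueError("raw and rescored lengths differ")

    def __len__(self) -> int:
        return len(self.raw)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"raw_label": self.raw, "rescored_label": self.rescored},
            index=self.timestamps,
        )


@dataclass
class SleepWindow:
    """Habitual bedtime window; may cross midnight."""

    bedtime: dt.time
    risetime: dt.time

    @property
    def minutes(self) -> int:
        bed = self.bedtime.hour * 60 + self.bedtime.minute
        rise = self.risetime.hour * 60 + self.risetime.minute
        length = (rise - bed) % (24 * 60)
        if length == 0:
            raise ValueError("window length must be in (0, 24h)")
        return length


class Agreement(NamedTuple):
    fraction: float
    n_compared: int
    n_excluded: int


def label_states(fit: FitResult) -> dict[int, str]:
    """Map the two hidden states to sleep/wake by their emission means.

    The state with higher mean heart rate and higher mean activity is
    wake.  If the two channels rank the states oppositely, activity
    decides and a discordance warning is emitted; univariate models
    label by their single mean.
    """
    p = fit.parameters
    if fit.scheme == "HR_ONLY":
        key = p.mu_hr
    elif fit.scheme == "ACT_ONLY":
        key = p.mu_act
    else:
        hr_order = np.argsort(p.mu_hr)
        act_order = np.argsort(p.mu_act)
        if not np.array_equal(hr_order, act_order):
            warnings.warn(
                "heart-rate and activity means rank the states oppositely; "
                "labeling by activity level"
            )
        key = p.mu_act
    if key[0] == key[1]:
        raise ValueError("degenerate fit: states have equal means on the deciding channel")
    wake_state = int(np.argmax(key))
    return {wake_state: WAKE, 1 - wake_state: SLEEP}


def _validate_labels(labels: np.ndarray) -> np.ndarray:
    arr = np.asarray(labels, dtype=object)
    bad = {v for v in arr if v not in (SLEEP, WAKE)}
    if bad:
        raise ValueError(f"labels must be 'sleep'/'wake'; got {sorted(map(str, bad))}")
    return arr


def _runs(x: np.ndarray) -> list[tuple[object, int, int]]:
    """Run-length encoding: list of (value, start, length)."""
    out = []
    start = 0
    for i in range(1, len(x) + 1):
        if i == len(x) or x[i] != x[start]:
            out.append((x[start], start, i - start))
            start = i
    return out


def webster_rescore(labels: Sequence[str], surround: str = "both") -> np.ndarray:
    """Apply the five Webster rescoring rules, one pass each, in order.

    (1) after >= 4 wake minutes the next sleep minute becomes wake;
    (2) after >= 10 wake, the next 3 sleep minutes; (3) after >= 15
    wake, the next 4; (4) sleep runs of <= 6 minutes flanked by >= 10
    wake minutes are rescored wake; (5) sleep runs of <= 10 minutes
    flanked by >= 20 wake minutes likewise.  Each rule makes one
    left-to-right pass over the sequence as updated by the earlier
    rules (rescored minutes count as wake for later rules), and no rule
    ever converts wake to sleep.

    ``surround`` controls rules 4-5: ``'both'`` (default) requires the
    wake threshold on both flanks, ``'either'`` on at least one.
    """
    if surround not in ("both", "either"):
        raise ValueError("surround must be 'both' or 'either'")
    x = _validate_labels(labels)
    if len(x) == 0:
        return x
    for n_wake, n_rescore in _TRAILING_RULES:
        runs = _runs(x)
        out = x.copy()
        for k in range(1, len(runs)):
            prev_val, _, prev_len = runs[k - 1]
            val, start, length = runs[k]
            if val == SLEEP and prev_val == WAKE and prev_len >= n_wake:
                out[start : start + min(n_rescore, length)] = WAKE
        x = out
    for max_sleep, n_wake in _SURROUND_RULES:
        runs = _runs(x)
        out = x.copy()
        for k, (val, start, length) in enumerate(runs):
            if val != SLEEP or length > max_sleep:
                continue
            before = runs[k - 1][2] if k > 0 and runs[k - 1][0] == WAKE else None
            after = (
                runs[k + 1][2]
                if k + 1 < len(runs) and runs[k + 1][0] == WAKE
                else None
            )
            if surround == "both":
                fire = before is not None and after is not None \
                    and before >= n_wake and after >= n_wake
            else:
                fire = (before is not None and before >= n_wake) or (
                    after is not None and after >= n_wake)
            if fire:
                out[start : start + length] = WAKE
        x = out
    return x


def score_series(
    fit: FitResult,
    series: EpochSeries | tuple,
    rescore: bool = True,
    surround: str = "both",
    provenance: Optional[str] = None,
) -> ScoredSeries:
    """Decode, label and (optionally) rescore a series in one call."""
    path = viterbi_decode(fit.parameters, fit.scheme, series)
    mapping = label_states(fit)
    raw = np.array([mapping[s] for s in path.states], dtype=object)
    rescored = webster_rescore(raw, surround=surround) if rescore else raw.copy()
    ts = series.timestamps if isinstance(series, EpochSeries) else None
    return ScoredSeries(ts, raw, rescored, provenance or fit.scheme)


def compare_scorers(
    series: EpochSeries,
    act_scored: ScoredSeries,
    hr_scored: ScoredSeries,
    fusion_scored: ScoredSeries,
) -> pd.DataFrame:
    """Cross-tabulate three scorers minute-by-minute.

    Returns one row per (activity-only, heart-rate-only, fusion) label
    combination with the minute count, percentage of total minutes, and
    the mean (SD) heart rate and activity level in that cell; empty
    cells report count 0 and no summaries.
    """
    n = len(series)
    for s in (act_scored, hr_scored, fusion_scored):
        if len(s) != n:
            raise ValueError("scored series lengths differ from the epoch series")
    hr = series.hr
    act = series.act
    rows = []
    for combo in product((WAKE, SLEEP), repeat=3):
        mask = (
            (act_scored.rescored == combo[0])
            & (hr_scored.rescored == combo[1])
            & (fusion_scored.rescored == combo[2])
        )
        count = int(mask.sum())
        row = {
            "activity_only": combo[0],
            "hr_only": combo[1],
            "fusion": combo[2],
            "n": count,
            "pct": 100.0 * count / n,
        }
        if count:
            h = hr[mask & np.isfinite(hr)]
            a = act[mask & np.isfinite(act)]
            row.update(
                hr_mean=h.mean() if len(h) else np.nan,
                hr_sd=h.std(ddof=1) if len(h) > 1 else np.nan,
                act_mean=a.mean() if len(a) else np.nan,
                act_sd=a.std(ddof=1) if len(a) > 1 else np.nan,
            )
        else:
            row.update(hr_mean=np.nan, hr_sd=np.nan, act_mean=np.nan, act_sd=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def reclassify_fitbit(stages: Sequence[str]) -> np.ndarray:
    """Collapse the device's 7-value stage vocabulary to sleep/wake.

    asleep/deep/light/rem -> sleep; restless/awake/wake -> wake.
    """
    arr = np.asarray(list(stages), dtype=object)
    unknown = sorted({str(s) for s in arr if s not in FITBIT_STAGE_MAP})
    if unknown:
        raise ValueError(f"unknown sleep stages: {unknown}")
    return np.array([FITBIT_STAGE_MAP[s] for s in arr], dtype=object)


def minute_agreement(a: ScoredSeries, b: ScoredSeries) -> Agreement:
    """Fraction of aligned minutes on which two scorers agree.

    Minutes missing a label in either scorer are excluded and counted.
    """
    if len(a) != len(b):
        raise ValueError("scored series lengths differ")
    la = a.rescored
    lb = b.rescored
    valid = np.array(
        [(x in (SLEEP, WAKE)) and (y in (SLEEP, WAKE)) for x, y in zip(la, lb)]
    )
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no overlapping scored minutes")
    agree = int((la[valid] == lb[valid]).sum())
    return Agreement(agree / n, n, len(a) - n)


def total_sleep_time(scored: ScoredSeries, window: SleepWindow) -> pd.DataFrame:
    """Sleep minutes inside the bedtime window, per night.

    A window crossing midnight attaches to the night of the bedtime.
    Nights whose window has no scored minutes at all are omitted with a
    warning; nights only partially covered (e.g. a removed nonwear day
    overlapping the window) are flagged incomplete.
    """
    if scored.timestamps is None:
        raise ValueError("scored series carries no timestamps")
    frame = scored.to_frame()
    wlen = window.minutes
    dates = pd.date_range(
        frame.index[0].normalize() - pd.Timedelta(days=1),
        frame.index[-1].normalize(),
        freq="D",
    )
    rows = []
    for d in dates:
        start = d + pd.Timedelta(hours=window.bedtime.hour, minutes=window.bedtime.minute)
        end = start + pd.Timedelta(minutes=wlen)
        chunk = frame.loc[(frame.index >= start) & (frame.index < end)]
        covered = len(chunk)
        if covered == 0:
            if frame.index[0] <= start and end <= frame.index[-1]:
                warnings.warn(f"night of {d.date()}: window not covered by data")
            continue
        sleep_minutes = int((chunk["rescored_label"] == SLEEP).sum())
        rows.append(
            {
                "night": d.date(),
                "sleep_minutes": sleep_minutes,
                "minutes_covered": covered,
                "window_minutes": wlen,
                "complete": covered == wlen,
            }
        )
    return pd.DataFrame(rows)
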