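"""Per-day model fits, weekday/weekend comparisons, cohort summaries.

Fitting the personalized model to each anchored 24-hour day yields a
daily trajectory of parameter estimates; two-tailed independent t tests
then ask whether weekday (Mon-Fri) and weekend (Sat-Sun) days differ in
any of the twelve reported parameters (the two off-diagonal transition
probabilities and, per state, the activity mean/variance, heart-rate
mean/variance, and correlation).  Diagonal transition entries are
omitted — their tests are identical to the off-diagonals'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import FitResult, fit_hmm, state_posteriors
from .preprocess import EpochSeries, MINUTES_PER_DAY

__all__ = [
    "DailyFit",
    "DailyFitSet",
    "PARAMETER_NAMES",
    "fit_daily_models",
    "weekday_weekend_tests",
    "summarize_cohort",
]

#: the twelve parameters compared between weekday and weekend models
PARAMETER_NAMES = (
    "gamma_wake_to_sleep",
    "gamma_sleep_to_wake",
    "wake_mu_act", "wake_sigma2_act", "wake_mu_hr", "wake_sigma2_hr", "wake_rho",
    "sleep_mu_act", "sleep_sigma2_act", "sleep_mu_hr", "sleep_sigma2_hr", "sleep_rho",
)

#: minimum minutes of posterior occupancy for each state on a valid day
MIN_STATE_OCCUPANCY = 30.0


def _extract_parameters(fit: FitResult) -> dict[str, float]:
    """Named parameter values; state 0 is sleep, state 1 wake (canonical)."""
    p = fit.parameters
    return {
        "gamma_wake_to_sleep": p.transmat[1, 0],
        "gamma_sleep_to_wake": p.transmat[0, 1],
        "wake_mu_act": p.mu_act[1], "wake_sigma2_act": p.sigma2_act[1],
        "wake_mu_hr": p.mu_hr[1], "wake_sigma2_hr": p.sigma2_hr[1],
        "wake_rho": p.rho[1],
        "sleep_mu_act": p.mu_act[0], "sleep_sigma2_act": p.sigma2_act[0],
        "sleep_mu_hr": p.mu_hr[0], "sleep_sigma2_hr": p.sigma2_hr[0],
        "sleep_rho": p.rho[0],
    }


@dataclass
class DailyFit:
    date: pd.Timestamp  # anchored day start date
    weekday: bool  # Mon-Fri by the anchor date
    valid: bool
    fit: Optional[FitResult]
    note: str = ""


@dataclass
class DailyFitSet:
    fits: list[DailyFit]
    scheme: str
    anchor_hour: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for d in self.fits:
            row = {"date": d.date, "weekday": d.weekday, "valid": d.valid,
                   "note": d.note}
            if d.fit is not None:
                row.update(_extract_parameters(d.fit))
                row["log_likelihood"] = d.fit.log_likelihood
            rows.append(row)
        return pd.DataFrame(rows)

    def valid_frame(self) -> pd.DataFrame:
        frame = self.to_frame()
        return frame[frame["valid"]].reset_index(drop=True)


def fit_daily_models(
    series: EpochSeries,
    scheme: str = "M1",
    anchor_hour: int = 8,
    seed: Optional[int] = None,
    n_restarts: int = 2,
    participant_fit: Optional[FitResult] = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> DailyFitSet:
    """Fit one model per anchored 24-hour day.

    Days run from ``anchor_hour`` to the same hour next morning (default
    08:00, so a full sleep episode sits inside one day) and are classed
    weekday/weekend by their anchor date.  Days not fully covered after
    nonwear removal are invalid; so are days on which EM degenerates (a
    state occupying fewer than ``MIN_STATE_OCCUPANCY`` posterior
    minutes).  When a participant-level fit is supplied its parameters
    seed each day's EM as an extra restart.
    """
    frame = series.frame
    anchored = frame.index - pd.Timedelta(hours=anchor_hour)
    keys = anchored.normalize()
    rng = np.random.default_rng(seed)
    init = participant_fit.parameters if participant_fit is not None else None
    fits: list[DailyFit] = []
    for date, chunk in frame.groupby(keys):
        weekday = date.dayofweek < 5
        if len(chunk) < MINUTES_PER_DAY:
            fits.append(DailyFit(date, weekday, False, None, "incomplete day"))
            continue
        hr = chunk["hr"].to_numpy(dtype=float)
        act = chunk["act"].to_numpy(dtype=float)
        day_seed = int(rng.integers(0, 2**31 - 1))
        try:
            fit = fit_hmm(
                (hr, act), scheme=scheme,
                n_restarts=n_restarts + (init is not None),
                seed=day_seed, tol=tol, max_iter=max_iter, init_params=init,
            )
        except ValueError as e:
            fits.append(DailyFit(date, weekday, False, None, str(e)))
            continue
        gamma = state_posteriors(fit.parameters, scheme, (hr, act))
        occ = gamma.sum(axis=0)
        if occ.min() < MIN_STATE_OCCUPANCY:
            fits.append(DailyFit(
                date, weekday, False, fit,
                f"degenerate day: state occupancy {occ.min():.1f} min"))
            continue
        fits.append(DailyFit(date, weekday, True, fit))
    n_valid = sum(d.valid for d in fits)
    if n_valid < 7:
        warnings.warn(f"only {n_valid} valid days; daily comparisons will be weak")
    return DailyFitSet(fits, scheme, anchor_hour)


def weekday_weekend_tests(
    daily: DailyFitSet, equal_var: bool = False, fdr: bool = False
) -> pd.DataFrame:
    """Two-tailed independent t tests of weekday vs weekend estimates.

    One row per parameter with group means, the p-value (Welch by
    default; ``equal_var=True`` pools variances) and a significance flag
    at P < .05.  With fewer than two valid days in either group the
    test set is skipped: an empty frame is returned with the reason in
    ``.attrs['skipped']``.  ``fdr=True`` adds Benjamini-Hochberg
    adjusted p-values.
    """
    frame = daily.valid_frame()
    scheme = daily.scheme
    names = [n for n in PARAMETER_NAMES
             if scheme == "M1" or not n.endswith("rho")]
    if scheme in ("HR_ONLY", "ACT_ONLY"):
        drop = "_act" if scheme == "HR_ONLY" else "_hr"
        names = [n for n in names if drop not in n]
    wd = frame[frame["weekday"]]
    we = frame[~frame["weekday"]]
    if len(wd) < 2 or len(we) < 2:
        msg = (f"skipped: need >= 2 valid days per group "
               f"(weekday {len(wd)}, weekend {len(we)})")
        warnings.warn(msg)
        out = pd.DataFrame(
            columns=["parameter", "weekday_mean", "weekend_mean", "p", "significant"])
        out.attrs["skipped"] = msg
        return out
    rows = []
    for name in names:
        a = wd[name].to_numpy(dtype=float)
        b = we[name].to_numpy(dtype=float)
        note = ""
        # variances that are zero up to float rounding of identical values
        tol_a = (1e-7 * max(abs(a.mean()), 1e-9)) ** 2
        tol_b = (1e-7 * max(abs(b.mean()), 1e-9)) ** 2
        degen_a, degen_b = a.var(ddof=1) <= tol_a, b.var(ddof=1) <= tol_b
        if degen_a and degen_b:
            if np.isclose(a.mean(), b.mean()):
                p = 1.0  # identical groups: t = 0
            else:
                p = np.nan
                note = "zero variance in a group"
        elif degen_a or degen_b:
            p = np.nan
            note = "zero variance in a group"
        else:
            p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        rows.append({
            "parameter": name,
            "weekday_mean": a.mean(), "weekend_mean": b.mean(),
            "p": p, "significant": bool(p < 0.05) if np.isfinite(p) else False,
            "note": note,
        })
    out = pd.DataFrame(rows)
    if fdr:
        mask = np.isfinite(out["p"].to_numpy(dtype=float))
        adj = np.full(len(out), np.nan)
        adj[mask] = stats.false_discovery_control(out.loc[mask, "p"])
        out["p_adjusted"] = adj
    return out


def summarize_cohort(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Mean (SD) of each parameter across participants.

    Rows cover the per-state emission parameters and the transition
    probabilities, mirroring a cohort summary table; sample SD
    (ddof=1) is NaN with a single participant.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to summarize")
    values = pd.DataFrame([_extract_parameters(f) for f in fits])
    rows = []
    for name in values.columns:
        v = values[name].to_numpy(dtype=float)
        rows.append({
            "parameter": name,
            "mean": v.mean(),
            "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
        })
    return pd.DataFrame(rows)
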