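"""Device-realistic synthetic wearable streams from the generative HMM.

The generator draws a two-state Markov chain (sleep/wake) at 1-minute
resolution, emits (heart rate, log-activity) pairs from the per-state
bivariate normals, and then degrades the series the way a wrist device
would: heart rate rounded to integer bpm, activity converted back to
integer per-minute step counts and summed into 15-minute bins, heart
rate minutes deleted in short runs, and whole nonwear days blanked.

Default parameter values are centred on the cohort-level estimates from
a three-month study of community-dwelling older adults (mean wake heart
rate 87.2 bpm, sleep 66.4 bpm; wake-to-sleep transition probability
0.011 per minute, sleep-to-wake 0.017; missing heart rate around 0.6%
of minutes), so simulated participants look like the population the
method was built for.  Two named presets reproduce the two
demonstration participants: ``"high_contrast"`` (vigorous, widely
separated states) and ``"sedentary"`` (low wake activity, smaller
heart-rate separation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .model import HMMParameters
from .preprocess import MINUTES_PER_DAY, RawRecording, STEP_BIN_MINUTES

__all__ = [
    "ParticipantProfile",
    "COHORT_MEAN_PARAMETERS",
    "COHORT_SD_PARAMETERS",
    "preset_profile",
    "sample_profile",
    "simulate_states",
    "simulate_observations",
    "to_device_format",
    "inject_missingness",
    "simulate_recording",
]

# state 0 = sleep, state 1 = wake throughout.
COHORT_MEAN_PARAMETERS = HMMParameters(
    pi=np.array([0.5, 0.5]),
    transmat=np.array([[0.983, 0.017], [0.011, 0.989]]),
    mu_hr=np.array([66.37, 87.18]),
    sigma2_hr=np.array([47.18, 241.16]),
    mu_act=np.array([0.02, 2.24]),
    sigma2_act=np.array([0.01, 1.16]),
    rho=np.array([0.01, 0.54]),
)

#: between-participant SDs matching the cohort means above
COHORT_SD_PARAMETERS = {
    "mu_hr": np.array([7.82, 12.52]),
    "sigma2_hr": np.array([36.91, 110.75]),
    "mu_act": np.array([0.07, 0.29]),
    "sigma2_act": np.array([0.04, 0.19]),
    "rho": np.array([0.01, 0.07]),
    "gamma_sleep_to_wake": 0.002,
    "gamma_wake_to_sleep": 0.003,
}

_PRESETS = {
    # vigorous participant: large separation in both channels
    "high_contrast": HMMParameters(
        pi=np.array([0.5, 0.5]),
        transmat=np.array([[0.983, 0.017], [0.0097, 0.9903]]),
        mu_hr=np.array([74.39, 110.21]),
        sigma2_hr=np.array([157.37, 213.68]),
        mu_act=np.array([0.27, 2.98]),
        sigma2_act=np.array([0.15, 0.83]),
        rho=np.array([0.04, 0.41]),
    ),
    # sedentary participant: near-zero sleep activity, lower wake heart rate
    "sedentary": HMMParameters(
        pi=np.array([0.5, 0.5]),
        transmat=np.array([[0.983, 0.017], [0.0082, 0.9918]]),
        mu_hr=np.array([56.46, 80.17]),
        sigma2_hr=np.array([58.56, 276.27]),
        mu_act=np.array([0.005, 2.22]),
        sigma2_act=np.array([0.005, 1.08]),
        rho=np.array([0.01, 0.56]),
    ),
}


@dataclass
class ParticipantProfile:
    """Generating parameters and degradation rates for one simulated wearer."""

    params: HMMParameters
    missing_rate: float = 0.0064  # fraction of heart-rate minutes deleted
    missing_run_mean: float = 5.0  # geometric mean run length, minutes
    nonwear_day_prob: float = 0.0
    n_days: int = 90

    def __post_init__(self) -> None:
        for r in (self.missing_rate, self.nonwear_day_prob):
            if not 0.0 <= r < 1.0:
                raise ValueError("rates must lie in [0, 1)")


def preset_profile(name: str, **overrides) -> ParticipantProfile:
    """A named demonstration profile (``'high_contrast'`` or ``'sedentary'``)."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; have {sorted(_PRESETS)}")
    return ParticipantProfile(params=_PRESETS[name], **overrides)


def _truncated_normal(rng, mean, sd, lo, hi, max_tries=1000) -> float:
    if sd == 0:
        if not (lo <= mean <= hi):
            raise ValueError(f"degenerate draw {mean} outside [{lo}, {hi}]")
        return float(mean)
    for _ in range(max_tries):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    raise ValueError(f"truncation bounds [{lo}, {hi}] infeasible for N({mean}, {sd}^2)")


def sample_profile(
    seed: Optional[int] = None,
    means: HMMParameters = COHORT_MEAN_PARAMETERS,
    sds: Optional[dict] = None,
    **profile_kwargs,
) -> ParticipantProfile:
    """Draw a random participant around the cohort-level estimates.

    Each parameter is drawn from a normal centred at the cohort mean
    with the cohort between-participant SD, truncated to its valid
    range (positive variances, transition probabilities in (0, 1),
    wake correlation in (0, 1), sleep correlation non-negative).
    Deterministic under ``seed``; SDs of zero reproduce the means.
    """
    sds = COHORT_SD_PARAMETERS if sds is None else sds
    rng = np.random.default_rng(seed)
    mu_hr = np.array([
        _truncated_normal(rng, means.mu_hr[i], sds["mu_hr"][i], 25.0, 245.0)
        for i in range(2)])
    sigma2_hr = np.array([
        _truncated_normal(rng, means.sigma2_hr[i], sds["sigma2_hr"][i], 1.0, np.inf)
        for i in range(2)])
    mu_act = np.array([
        _truncated_normal(rng, means.mu_act[i], sds["mu_act"][i], 0.0, np.inf)
        for i in range(2)])
    sigma2_act = np.array([
        _truncated_normal(rng, means.sigma2_act[i], sds["sigma2_act"][i], 1e-4, np.inf)
        for i in range(2)])
    rho = np.array([
        _truncated_normal(rng, means.rho[0], sds["rho"][0], 0.0, 0.99),
        _truncated_normal(rng, means.rho[1], sds["rho"][1], 1e-6, 0.99),
    ])
    g_sw = _truncated_normal(
        rng, means.transmat[0, 1], sds["gamma_sleep_to_wake"], 1e-4, 0.5)
    g_ws = _truncated_normal(
        rng, means.transmat[1, 0], sds["gamma_wake_to_sleep"], 1e-4, 0.5)
    params = HMMParameters(
        pi=means.pi.copy(),
        transmat=np.array([[1 - g_sw, g_sw], [g_ws, 1 - g_ws]]),
        mu_hr=mu_hr, sigma2_hr=sigma2_hr,
        mu_act=mu_act, sigma2_act=sigma2_act, rho=rho,
    )
    params.validate("M1")
    return ParticipantProfile(params=params, **profile_kwargs)


def simulate_states(params: HMMParameters, T: int, seed=None) -> np.ndarray:
    """Sample a hidden state path: z_1 ~ pi, z_{t+1} | z_t ~ its transition row."""
    if T < 1:
        raise ValueError("T must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.random(T)
    z = np.empty(T, dtype=np.int64)
    z[0] = 0 if u[0] < params.pi[0] else 1
    p_stay = np.diag(params.transmat)
    for t in range(1, T):
        zt = z[t - 1]
        z[t] = zt if u[t] < p_stay[zt] else 1 - zt
    return z


def simulate_observations(
    params: HMMParameters,
    states: np.ndarray,
    seed=None,
    scheme: str = "M1",
    truncate_act: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Emit (heart rate, activity level) per minute given the state path.

    Scheme M1 draws from the per-state bivariate normal; M2 draws the
    two channels independently.  Activity draws below zero are truncated
    at zero by default, since log-steps cannot be negative.
    """
    rng = np.random.default_rng(seed)
    T = len(states)
    u1 = rng.standard_normal(T)
    u2 = rng.standard_normal(T)
    sh = np.sqrt(params.sigma2_hr[states])
    sa = np.sqrt(params.sigma2_act[states])
    rho = params.rho[states] if scheme == "M1" else np.zeros(T)
    hr = params.mu_hr[states] + sh * u1
    act = params.mu_act[states] + sa * (rho * u1 + np.sqrt(1.0 - rho**2) * u2)
    if truncate_act:
        act = np.maximum(act, 0.0)
    return hr, act


def to_device_format(
    hr: np.ndarray,
    act: np.ndarray,
    start="2018-01-01 00:00",
    participant_id: str = "sim",
) -> RawRecording:
    """Degrade a minute-level series into the device's export format.

    Heart rate is rounded to whole bpm (clipped to the physiological
    range the reader accepts); activity level is inverted to per-minute
    integer steps, ``max(0, round(exp(act) - 1))``, and summed into
    aligned 15-minute bins.  The series length is trimmed to whole bins.
    """
    T = (len(hr) // STEP_BIN_MINUTES) * STEP_BIN_MINUTES
    idx = pd.date_range(start, periods=T, freq="min")
    hr_round = np.clip(np.round(hr[:T]), 21, 249)
    hr_series = pd.Series(hr_round, index=idx)
    hr_series = hr_series[np.isfinite(hr[:T])]
    steps_min = np.maximum(0, np.round(np.expm1(act[:T]))).astype(int)
    bins = steps_min.reshape(-1, STEP_BIN_MINUTES).sum(axis=1)
    bin_idx = pd.date_range(start, periods=len(bins), freq=f"{STEP_BIN_MINUTES}min")
    return RawRecording(participant_id, hr_series, pd.Series(bins.astype(float), index=bin_idx))


def inject_missingness(
    rec: RawRecording,
    missing_rate: float,
    run_mean: float = 5.0,
    nonwear_day_prob: float = 0.0,
    nonwear_days=None,
    seed=None,
) -> RawRecording:
    """Delete heart-rate minutes in runs and blank whole nonwear days.

    Heart-rate minutes are removed in geometric-length runs (mean
    ``run_mean``) at random starts until the realized missing fraction
    reaches ``missing_rate`` (it lands within a tenth of a percentage
    point of the target, by construction just above it).  Nonwear days
    — either the given dates or each day independently with probability
    ``nonwear_day_prob`` — have their steps zeroed and heart rate
    deleted entirely, which is what a removed device reports.
    """
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    start, end = rec.span
    full_idx = pd.date_range(start.ceil("min"), end - pd.Timedelta(minutes=1), freq="min")
    n_total = len(full_idx)
    keep = rec.hr.reindex(full_idx)
    observed = np.isfinite(keep.to_numpy(dtype=float))
    target_missing = missing_rate * n_total
    n_missing = int((~observed).sum())
    guard = 0
    while n_missing < target_missing and guard < 10 * n_total:
        guard += 1
        s = int(rng.integers(0, n_total))
        length = int(rng.geometric(1.0 / run_mean))
        sl = slice(s, min(s + length, n_total))
        n_missing += int(observed[sl].sum())
        observed[sl] = False
    hr = keep[observed]

    steps = rec.steps15.copy()
    dates = pd.Series(full_idx.normalize().unique())
    if nonwear_days is None:
        if nonwear_day_prob > 0:
            pick = rng.random(len(dates)) < nonwear_day_prob
            nonwear_days = list(dates[pick])
        else:
            nonwear_days = []
    for d in nonwear_days:
        d = pd.Timestamp(d)
        day_mask = hr.index.normalize() == d
        hr = hr[~day_mask]
        steps[steps.index.normalize() == d] = 0.0
    if len(hr) == 0:
        raise ValueError("missingness injection removed every heart-rate minute")
    return RawRecording(rec.participant_id, hr, steps, rec.stages)


def simulate_recording(
    profile: ParticipantProfile,
    seed=None,
    start="2018-01-01 00:00",
    scheme: str = "M1",
) -> tuple[RawRecording, pd.DataFrame]:
    """End-to-end draw: states, observations, device format, missingness.

    Returns the degraded recording plus a truth frame (timestamp,
    state, hr, act) on the full minute grid for accuracy evaluation.
    """
    rng = np.random.default_rng(seed)
    T = profile.n_days * MINUTES_PER_DAY
    s1, s2, s3 = (int(x) for x in rng.integers(0, 2**31 - 1, 3))
    states = simulate_states(profile.params, T, seed=s1)
    hr, act = simulate_observations(profile.params, states, seed=s2, scheme=scheme)
    rec = to_device_format(hr, act, start=start, participant_id="sim")
    rec = inject_missingness(
        rec, profile.missing_rate, profile.missing_run_mean,
        profile.nonwear_day_prob, seed=s3,
    )
    truth = pd.DataFrame(
        {"state": states, "hr": hr, "act": act},
        index=pd.date_range(start, periods=T, freq="min"),
    )
    return rec, truth
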