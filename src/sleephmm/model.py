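"""Two-state hidden Markov models for minute-level (heart rate, activity) data.

The observed minute series ``x_t = (x_HR, x_ACT)`` is modelled by a
two-state homogeneous Markov chain with Gaussian emissions under one of
four schemes:

* ``M1``   — bivariate normal emission per state, with a per-state
  correlation ``rho`` between heart rate and activity level;
* ``M2``   — contemporaneous conditional independence: the product of
  the two univariate normal marginals (``rho`` constrained to 0);
* ``HR_ONLY`` / ``ACT_ONLY`` — univariate normal on a single channel.

Missing observations are handled inside the likelihood: a minute with
both channels missing contributes emission probability 1 in every state,
and a minute with one channel missing contributes that state's marginal
density of the observed channel.  Fitting is Baum-Welch EM with
closed-form Gaussian M-steps (missing components enter through their
state-conditional expected sufficient statistics, so each iteration is
an exact EM step and the observed-data log likelihood never decreases).
States are canonicalized after fitting so that state 0 has the lower
mean heart rate (the "sleep-like" state) — EM's label switching never
reaches downstream code.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from ._kernels import forward_backward, forward_loglik, viterbi_path
from .preprocess import EpochSeries

__all__ = [
    "SCHEMES",
    "HMMParameters",
    "FitResult",
    "StatePath",
    "PseudoResidualSeries",
    "count_free_parameters",
    "information_criteria",
    "emission_log_density",
    "forward_log_likelihood",
    "fit_hmm",
    "select_model",
    "viterbi_decode",
    "pseudo_residuals",
]

SCHEMES = ("M1", "M2", "HR_ONLY", "ACT_ONLY")

VARIANCE_FLOOR = 1e-6
RHO_MAX = 0.999
PROB_FLOOR = 1e-10
LOG_2PI = np.log(2.0 * np.pi)


def _check_scheme(scheme: str) -> str:
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    return scheme


def _uses(scheme: str) -> tuple[bool, bool]:
    """Which of (heart rate, activity) the scheme observes."""
    return scheme in ("M1", "M2", "HR_ONLY"), scheme in ("M1", "M2", "ACT_ONLY")


@dataclass
class HMMParameters:
    """Initial distribution, transition matrix and per-state emissions.

    Arrays are indexed by state; after canonicalization state 0 is the
    low-heart-rate (sleep-like) state.  ``rho`` is only meaningful under
    scheme M1 and is identically 0 under M2.
    """

    pi: np.ndarray  # (2,)
    transmat: np.ndarray  # (2, 2); [i, j] = P(z_{t+1}=j | z_t=i)
    mu_hr: np.ndarray  # (2,) bpm
    sigma2_hr: np.ndarray  # (2,) bpm^2
    mu_act: np.ndarray  # (2,) log-steps
    sigma2_act: np.ndarray  # (2,)
    rho: np.ndarray  # (2,) in (-1, 1)

    def __post_init__(self) -> None:
        for name in ("pi", "transmat", "mu_hr", "sigma2_hr", "mu_act", "sigma2_act", "rho"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def validate(self, scheme: str = "M1") -> None:
        use_hr, use_act = _uses(_check_scheme(scheme))
        if self.pi.shape != (2,) or self.transmat.shape != (2, 2):
            raise ValueError("expected 2 states")
        if not np.isclose(self.pi.sum(), 1.0) or (self.pi < 0).any():
            raise ValueError("pi must be a distribution")
        if not np.allclose(self.transmat.sum(axis=1), 1.0) or (self.transmat < 0).any():
            raise ValueError("transition matrix rows must be distributions")
        if use_hr and not (np.isfinite(self.sigma2_hr).all() and (self.sigma2_hr > 0).all()):
            raise ValueError("sigma2_hr must be positive")
        if use_act and not (np.isfinite(self.sigma2_act).all() and (self.sigma2_act > 0).all()):
            raise ValueError("sigma2_act must be positive")
        if scheme == "M1" and not (np.abs(self.rho) < 1).all():
            raise ValueError("rho must lie in (-1, 1)")

    def reordered(self, order: Sequence[int]) -> "HMMParameters":
        order = list(order)
        return HMMParameters(
            pi=self.pi[order],
            transmat=self.transmat[np.ix_(order, order)],
            mu_hr=self.mu_hr[order],
            sigma2_hr=self.sigma2_hr[order],
            mu_act=self.mu_act[order],
            sigma2_act=self.sigma2_act[order],
            rho=self.rho[order],
        )

    def to_dict(self) -> dict:
        return {k: np.asarray(v).tolist() for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParameters":
        return cls(**{k: np.asarray(d[k], dtype=float) for k in (
            "pi", "transmat", "mu_hr", "sigma2_hr", "mu_act", "sigma2_act", "rho")})


@dataclass
class FitResult:
    """A fitted model plus its likelihood bookkeeping."""

    parameters: HMMParameters
    scheme: str
    log_likelihood: float
    df: int
    aic: float
    bic: float
    t_effective: int
    iterations: int
    converged: bool
    restart_log: list = field(default_factory=list)
    loglik_history: Optional[np.ndarray] = None


@dataclass
class StatePath:
    """Decoded hidden states, defined at every minute (missing included)."""

    states: np.ndarray  # (T,) int, 0 or 1
    log_joint: float
    posterior: Optional[np.ndarray] = None  # (T, 2)


@dataclass
class PseudoResidualSeries:
    """Ordinary normal pseudo-residuals per observed channel.

    If the model generated the data, each residual series is standard
    normal; the Kolmogorov-Smirnov statistics summarize overall fit.
    """

    u_hr: Optional[np.ndarray]
    u_act: Optional[np.ndarray]
    n_clipped: int
    ks_hr: Optional[tuple[float, float]] = None  # (statistic, p-value)
    ks_act: Optional[tuple[float, float]] = None


def count_free_parameters(scheme: str) -> int:
    """Free parameters: per-state emissions + 2 transition + 1 initial.

    M1 has 5 emission parameters per state (two means, two variances,
    one correlation) giving 13; M2 drops the correlations (11); the
    univariate models keep one mean and variance per state (7).
    """
    _check_scheme(scheme)
    per_state = {"M1": 5, "M2": 4, "HR_ONLY": 2, "ACT_ONLY": 2}[scheme]
    return 2 * per_state + 2 + 1


def information_criteria(log_likelihood: float, df: int, t: int) -> tuple[float, float]:
    """AIC = -2*ll + 2*df and BIC = -2*ll + df*ln(T)."""
    if t < 1:
        raise ValueError("T must be >= 1")
    if df < 0:
        raise ValueError("df must be >= 0")
    return (-2.0 * log_likelihood + 2.0 * df,
            -2.0 * log_likelihood + df * np.log(t))


# ---------------------------------------------------------------------------
# emission densities


def _emission_log_matrix(
    params: HMMParameters, scheme: str, hr: np.ndarray, act: np.ndarray
) -> np.ndarray:
    """(T, 2) state-conditional log emission densities with missing-data rules.

    Both channels missing -> 0 (density 1 in every state); one channel
    missing -> the observed channel's marginal log density.
    """
    use_hr, use_act = _uses(scheme)
    T = hr.shape[0]
    hr_obs = np.isfinite(hr) if use_hr else np.zeros(T, dtype=bool)
    act_obs = np.isfinite(act) if use_act else np.zeros(T, dtype=bool)
    logB = np.zeros((T, 2))
    for i in range(2):
        lh = np.zeros(T)
        la = np.zeros(T)
        if use_hr:
            z = hr[hr_obs] - params.mu_hr[i]
            lh[hr_obs] = -0.5 * (LOG_2PI + np.log(params.sigma2_hr[i])
                                 + z * z / params.sigma2_hr[i])
        if use_act:
            z = act[act_obs] - params.mu_act[i]
            la[act_obs] = -0.5 * (LOG_2PI + np.log(params.sigma2_act[i])
                                  + z * z / params.sigma2_act[i])
        if scheme == "M1":
            both = hr_obs & act_obs
            r = params.rho[i]
            sh = np.sqrt(params.sigma2_hr[i])
            sa = np.sqrt(params.sigma2_act[i])
            zh = (hr[both] - params.mu_hr[i]) / sh
            za = (act[both] - params.mu_act[i]) / sa
            om = 1.0 - r * r
            biv = (-LOG_2PI - np.log(sh * sa) - 0.5 * np.log(om)
                   - 0.5 * (zh * zh - 2.0 * r * zh * za + za * za) / om)
            out = lh + la  # marginals cover the one-channel cases
            out[both] = biv
            logB[:, i] = out
        else:
            logB[:, i] = lh + la
    return logB


def emission_log_density(
    params: HMMParameters, scheme: str, x_hr: float, x_act: float, state: int
) -> float:
    """Log emission density of one minute's observation in one state.

    ``nan`` marks a missing channel; both missing returns 0 (log of
    density 1, the missing-data likelihood rule).
    """
    _check_scheme(scheme)
    params.validate(scheme)
    for v in (x_hr, x_act):
        if not np.isfinite(v) and not np.isnan(v):
            raise ValueError("observations must be finite or NaN (missing)")
    logB = _emission_log_matrix(
        params, scheme, np.array([float(x_hr)]), np.array([float(x_act)])
    )
    return float(logB[0, state])


def _series_arrays(series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, EpochSeries):
        return series.hr, series.act
    hr, act = series
    return np.asarray(hr, dtype=float), np.asarray(act, dtype=float)


def forward_log_likelihood(params: HMMParameters, scheme: str, series) -> float:
    """Log likelihood summed over all state paths (forward algorithm).

    Runs a scaled forward recursion, stable for series of 10^5+ minutes.
    ``series`` is an :class:`EpochSeries` or an ``(hr, act)`` array pair.
    """
    _check_scheme(scheme)
    params.validate(scheme)
    hr, act = _series_arrays(series)
    if hr.shape[0] == 0:
        raise ValueError("empty series")
    logB = _emission_log_matrix(params, scheme, hr, act)
    offset = logB.max(axis=1)
    b = np.exp(logB - offset[:, None])
    ll = forward_loglik(
        np.ascontiguousarray(params.pi), np.ascontiguousarray(params.transmat), b
    )
    return float(ll + offset.sum())


# ---------------------------------------------------------------------------
# fitting


def _t_effective(scheme: str, hr: np.ndarray, act: np.ndarray) -> int:
    use_hr, use_act = _uses(scheme)
    obs = np.zeros(hr.shape[0], dtype=bool)
    if use_hr:
        obs |= np.isfinite(hr)
    if use_act:
        obs |= np.isfinite(act)
    return int(obs.sum())


def _initial_parameters(
    scheme: str, hr: np.ndarray, act: np.ndarray, rng: np.random.Generator, perturb: bool
) -> HMMParameters:
    """Median split on the scheme's leading channel seeds the two states."""
    lead = act if scheme != "HR_ONLY" else hr
    lead_obs = lead[np.isfinite(lead)]
    med = np.median(lead_obs)
    low = lead <= med
    mu_hr = np.empty(2); s2_hr = np.empty(2)
    mu_act = np.empty(2); s2_act = np.empty(2)
    rho = np.zeros(2)
    for i, mask in enumerate((low, ~low)):
        h = hr[mask & np.isfinite(hr)]
        a = act[mask & np.isfinite(act)]
        mu_hr[i] = h.mean() if len(h) else np.nanmean(hr)
        s2_hr[i] = max(h.var(), VARIANCE_FLOOR) if len(h) > 1 else 1.0
        mu_act[i] = a.mean() if len(a) else np.nanmean(act)
        s2_act[i] = max(a.var(), VARIANCE_FLOOR) if len(a) > 1 else 1.0
        if scheme == "M1":
            bothm = mask & np.isfinite(hr) & np.isfinite(act)
            if bothm.sum() > 2 and hr[bothm].std() > 0 and act[bothm].std() > 0:
                rho[i] = np.clip(np.corrcoef(hr[bothm], act[bothm])[0, 1], -0.9, 0.9)
    if perturb:
        mu_hr = mu_hr + rng.uniform(-0.5, 0.5, 2) * np.sqrt(s2_hr)
        mu_act = mu_act + rng.uniform(-0.5, 0.5, 2) * np.sqrt(s2_act)
    return HMMParameters(
        pi=np.array([0.5, 0.5]),
        transmat=np.array([[0.95, 0.05], [0.05, 0.95]]),
        mu_hr=mu_hr, sigma2_hr=s2_hr,
        mu_act=mu_act, sigma2_act=s2_act, rho=rho,
    )


def _expected_moments(
    params: HMMParameters, scheme: str, i: int,
    hr: np.ndarray, act: np.ndarray,
    hr_obs: np.ndarray, act_obs: np.ndarray,
):
    """State-conditional expected sufficient statistics per minute.

    Missing components are replaced by their conditional expectations
    given the observed component (and the state), which makes the
    Gaussian M-step an exact EM update under the missing-data rule.
    """
    mh, ma = params.mu_hr[i], params.mu_act[i]
    s2h, s2a = params.sigma2_hr[i], params.sigma2_act[i]
    r = params.rho[i] if scheme == "M1" else 0.0
    sh, sa = np.sqrt(s2h), np.sqrt(s2a)

    Eh = np.where(hr_obs, hr, mh)
    Ea = np.where(act_obs, act, ma)
    Eh2 = np.where(hr_obs, hr * hr, s2h + mh * mh)
    Ea2 = np.where(act_obs, act * act, s2a + ma * ma)
    if scheme == "M1" and r != 0.0:
        only_a = act_obs & ~hr_obs
        if only_a.any():
            cm = mh + r * sh / sa * (act[only_a] - ma)
            cv = s2h * (1.0 - r * r)
            Eh[only_a] = cm
            Eh2[only_a] = cv + cm * cm
        only_h = hr_obs & ~act_obs
        if only_h.any():
            cm = ma + r * sa / sh * (hr[only_h] - mh)
            cv = s2a * (1.0 - r * r)
            Ea[only_h] = cm
            Ea2[only_h] = cv + cm * cm
    Eha = Eh * Ea
    neither = ~hr_obs & ~act_obs
    if scheme == "M1" and neither.any():
        Eha[neither] = r * sh * sa + mh * ma
    return Eh, Eh2, Ea, Ea2, Eha


def _em_run(
    scheme: str, hr: np.ndarray, act: np.ndarray,
    init: HMMParameters, tol: float, max_iter: int,
):
    use_hr, use_act = _uses(scheme)
    T = hr.shape[0]
    hr_obs = np.isfinite(hr) if use_hr else np.zeros(T, dtype=bool)
    act_obs = np.isfinite(act) if use_act else np.zeros(T, dtype=bool)
    params = init
    history = []
    converged = False
    gamma = None
    for it in range(max_iter):
        logB = _emission_log_matrix(params, scheme, hr, act)
        offset = logB.max(axis=1)
        b = np.exp(logB - offset[:, None])
        ll, gamma, xi_sum, *_ = forward_backward(
            np.ascontiguousarray(params.pi),
            np.ascontiguousarray(params.transmat), b,
        )
        ll = float(ll + offset.sum())
        history.append(ll)
        if len(history) > 1:
            prev = history[-2]
            if abs(ll - prev) < tol * (abs(prev) + 1.0):
                converged = True
                break
        # --- M-step
        pi = np.clip(gamma[0], PROB_FLOOR, None)
        pi /= pi.sum()
        A = np.clip(xi_sum, PROB_FLOOR, None)
        A /= A.sum(axis=1, keepdims=True)
        new = {"mu_hr": np.empty(2), "sigma2_hr": np.empty(2),
               "mu_act": np.empty(2), "sigma2_act": np.empty(2),
               "rho": np.zeros(2)}
        for i in range(2):
            w = gamma[:, i]
            wsum = w.sum()
            Eh, Eh2, Ea, Ea2, Eha = _expected_moments(
                params, scheme, i, hr, act, hr_obs, act_obs)
            if use_hr:
                m = (w @ Eh) / wsum
                v = max((w @ Eh2) / wsum - m * m, VARIANCE_FLOOR)
                new["mu_hr"][i], new["sigma2_hr"][i] = m, v
            else:
                new["mu_hr"][i], new["sigma2_hr"][i] = np.nan, np.nan
            if use_act:
                m = (w @ Ea) / wsum
                v = max((w @ Ea2) / wsum - m * m, VARIANCE_FLOOR)
                new["mu_act"][i], new["sigma2_act"][i] = m, v
            else:
                new["mu_act"][i], new["sigma2_act"][i] = np.nan, np.nan
            if scheme == "M1":
                cov = (w @ Eha) / wsum - new["mu_hr"][i] * new["mu_act"][i]
                new["rho"][i] = np.clip(
                    cov / np.sqrt(new["sigma2_hr"][i] * new["sigma2_act"][i]),
                    -RHO_MAX, RHO_MAX)
        params = HMMParameters(pi=pi, transmat=A, **new)
    return params, history, converged, gamma


def fit_hmm(
    series,
    scheme: str = "M1",
    n_restarts: int = 5,
    seed: Optional[int] = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    init_params: Optional[HMMParameters] = None,
) -> FitResult:
    """Fit the two-state HMM by Baum-Welch EM with random restarts.

    The first start splits minutes at the median activity level (heart
    rate for the heart-rate-only model) and estimates state moments from
    the two halves; further restarts perturb the initial means by up to
    half a standard deviation using ``seed``.  The best restart by final
    log likelihood wins.  States are then reordered so state 0 has the
    lower mean heart rate.

    Parameters
    ----------
    series : EpochSeries or (hr, act) arrays with NaN for missing.
    n_restarts : total number of EM starts (>= 1).
    seed : seeds the restart perturbations; required when n_restarts > 1.
    tol : relative log-likelihood change declaring convergence.
    max_iter : EM iteration cap per start.
    init_params : optional extra initialization tried as restart 0
        (e.g. a participant-level fit seeding per-day fits).
    """
    _check_scheme(scheme)
    hr, act = _series_arrays(series)
    t_eff = _t_effective(scheme, hr, act)
    if t_eff < 100:
        raise ValueError("need at least 100 non-missing minutes to fit")
    rng = np.random.default_rng(seed)
    best = None
    restart_log = []
    for r in range(max(1, n_restarts)):
        if init_params is not None and r == 0:
            init = init_params
        else:
            first = r == 0 or (init_params is not None and r == 1)
            init = _initial_parameters(scheme, hr, act, rng, perturb=not first)
        params, history, converged, gamma = _em_run(
            scheme, hr, act, init, tol, max_iter)
        occ = gamma.sum(axis=0) / gamma.sum()
        note = ""
        if occ.min() < 1e-3:
            note = f"degenerate state: occupancy {occ.min():.2e}"
        restart_log.append({
            "restart": r, "log_likelihood": history[-1],
            "iterations": len(history), "converged": converged, "note": note,
        })
        if best is None or history[-1] > best[1][-1]:
            best = (params, history, converged)
    params, history, converged = best
    if not converged:
        warnings.warn(f"EM did not converge within {max_iter} iterations")
    # canonical state order: ascending mean heart rate (activity if no HR)
    key = params.mu_hr if scheme != "ACT_ONLY" else params.mu_act
    order = np.argsort(key, kind="stable")
    params = params.reordered(order)
    ll = history[-1]
    df = count_free_parameters(scheme)
    aic, bic = information_criteria(ll, df, t_eff)
    return FitResult(
        parameters=params, scheme=scheme, log_likelihood=ll, df=df,
        aic=aic, bic=bic, t_effective=t_eff, iterations=len(history),
        converged=converged, restart_log=restart_log,
        loglik_history=np.asarray(history),
    )


def select_model(fits: Sequence[FitResult], prefer: str = "aic") -> FitResult:
    """Pick the best fit by information criterion.

    Default selects minimum AIC; ties go to the model with fewer free
    parameters.  When AIC and BIC disagree the disagreement is logged
    and BIC's choice is used only if ``prefer='bic'``.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("no fits to select from")
    if len({f.t_effective for f in fits}) > 1:
        raise ValueError("fits were computed on different series lengths")
    if len(fits) == 1:
        return fits[0]
    by_aic = min(fits, key=lambda f: (f.aic, f.df))
    by_bic = min(fits, key=lambda f: (f.bic, f.df))
    if by_aic is not by_bic:
        warnings.warn(
            f"AIC prefers {by_aic.scheme} but BIC prefers {by_bic.scheme}")
    return by_bic if prefer == "bic" else by_aic


def viterbi_decode(params: HMMParameters, scheme: str, series) -> StatePath:
    """Globally most probable state path given the whole observation series.

    Missing minutes use the missing-data emission rule, so the path is
    defined everywhere; exact ties (possible only in missing stretches)
    resolve to the lower state index.
    """
    _check_scheme(scheme)
    params.validate(scheme)
    hr, act = _series_arrays(series)
    logB = _emission_log_matrix(params, scheme, hr, act)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.pi)
        log_A = np.log(params.transmat)
    path, score = viterbi_path(log_pi, log_A, np.ascontiguousarray(logB))
    return StatePath(states=np.asarray(path), log_joint=float(score))


def state_posteriors(params: HMMParameters, scheme: str, series) -> np.ndarray:
    """(T, 2) smoothed posteriors P(z_t | all observations)."""
    hr, act = _series_arrays(series)
    logB = _emission_log_matrix(params, scheme, hr, act)
    offset = logB.max(axis=1)
    b = np.exp(logB - offset[:, None])
    _, gamma, *_ = forward_backward(
        np.ascontiguousarray(params.pi), np.ascontiguousarray(params.transmat), b)
    return gamma


def pseudo_residuals(
    params: HMMParameters, scheme: str, series, eps: float = 1e-12
) -> PseudoResidualSeries:
    """Ordinary normal pseudo-residuals per observed channel.

    For channel ``c`` at minute ``t`` the residual is
    ``u = Phi^{-1}( F_t(x) )`` where ``F_t`` is the two-component normal
    mixture CDF with state weights ``P(z_t = i | all other
    observations)`` — the model's conditional distribution of minute
    ``t`` given the rest of the series.  Under a correct model the
    residuals are standard normal; the result carries Kolmogorov-Smirnov
    summaries per channel.  CDF values of exactly 0 or 1 are clipped to
    ``[eps, 1 - eps]`` and counted.
    """
    _check_scheme(scheme)
    params.validate(scheme)
    use_hr, use_act = _uses(scheme)
    hr, act = _series_arrays(series)
    T = hr.shape[0]
    logB = _emission_log_matrix(params, scheme, hr, act)
    offset = logB.max(axis=1)
    b = np.exp(logB - offset[:, None])
    pi = np.ascontiguousarray(params.pi)
    A = np.ascontiguousarray(params.transmat)
    _, _, _, alpha, beta, c = forward_backward(pi, A, b)
    # weights P(z_t | x_{-t}): drop minute t's own emission term
    pred = np.empty((T, 2))
    pred[0] = pi
    pred[1:] = alpha[:-1] @ A
    succ = np.ones((T, 2))
    succ[:-1] = ((b[1:] * beta[1:]) / c[1:, None]) @ A.T
    w = pred * succ
    w /= w.sum(axis=1, keepdims=True)

    n_clipped = 0

    def channel(x, mu, s2, use):
        nonlocal n_clipped
        if not use:
            return None
        obs = np.isfinite(x)
        F = np.zeros(obs.sum())
        for i in range(2):
            F += w[obs, i] * stats.norm.cdf(x[obs], mu[i], np.sqrt(s2[i]))
        n_clipped += int(((F <= 0) | (F >= 1)).sum())
        F = np.clip(F, eps, 1 - eps)
        u = np.full(T, np.nan)
        u[obs] = stats.norm.ppf(F)
        return u

    u_hr = channel(hr, params.mu_hr, params.sigma2_hr, use_hr)
    u_act = channel(act, params.mu_act, params.sigma2_act, use_act)

    def ks(u):
        if u is None:
            return None
        v = u[np.isfinite(u)]
        if len(v) == 0:
            return None
        r = stats.kstest(v, "norm")
        return (float(r.statistic), float(r.pvalue))

    return PseudoResidualSeries(
        u_hr=u_hr, u_act=u_act, n_clipped=n_clipped, ks_hr=ks(u_hr), ks_act=ks(u_act)
    )
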