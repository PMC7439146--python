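"""Independent brute-force references for the HMM recursions.

These enumerate all 2^T hidden-state paths explicitly and evaluate
emission densities through scipy, so they share no code with the
dynamic-programming implementations they check.
"""

import itertools

import numpy as np
from scipy import stats


def oracle_emission_logpdf(params, scheme, x_hr, x_act, state):
    """State-conditional log density via scipy, with the missing-data rules."""
    i = state
    hr_obs = np.isfinite(x_hr) and scheme in ("M1", "M2", "HR_ONLY")
    act_obs = np.isfinite(x_act) and scheme in ("M1", "M2", "ACT_ONLY")
    if hr_obs and act_obs and scheme == "M1":
        sh = np.sqrt(params.sigma2_hr[i])
        sa = np.sqrt(params.sigma2_act[i])
        cov = params.rho[i] * sh * sa
        return stats.multivariate_normal.logpdf(
            [x_hr, x_act],
            mean=[params.mu_hr[i], params.mu_act[i]],
            cov=[[params.sigma2_hr[i], cov], [cov, params.sigma2_act[i]]],
        )
    out = 0.0
    if hr_obs:
        out += stats.norm.logpdf(x_hr, params.mu_hr[i], np.sqrt(params.sigma2_hr[i]))
    if act_obs:
        out += stats.norm.logpdf(x_act, params.mu_act[i], np.sqrt(params.sigma2_act[i]))
    return out


def _emission_table(params, scheme, hr, act):
    return np.array([
        [oracle_emission_logpdf(params, scheme, hr[t], act[t], i) for i in (0, 1)]
        for t in range(len(hr))
    ])


def _path_logprob(params, logb, path):
    lp = np.log(params.pi[path[0]]) + logb[0, path[0]]
    for t in range(1, len(logb)):
        lp += np.log(params.transmat[path[t - 1], path[t]]) + logb[t, path[t]]
    return lp


def brute_force_loglik(params, scheme, hr, act):
    """log sum over all 2^T paths of pi * emissions * transitions."""
    logb = _emission_table(params, scheme, hr, act)
    lps = [
        _path_logprob(params, logb, path)
        for path in itertools.product((0, 1), repeat=len(hr))
    ]
    m = max(lps)
    return m + np.log(sum(np.exp(lp - m) for lp in lps))


def brute_force_viterbi(params, scheme, hr, act):
    """Exhaustive argmax path; strictly-greater comparison keeps the first
    (lexicographically smallest) optimum, matching lower-index tie-breaks."""
    logb = _emission_table(params, scheme, hr, act)
    best_lp = -np.inf
    best_path = None
    for path in itertools.product((0, 1), repeat=len(hr)):
        lp = _path_logprob(params, logb, path)
        if lp > best_lp:
            best_lp = lp
            best_path = path
    return np.array(best_path), best_lp
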