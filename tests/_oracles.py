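"""Independent brute-force oracles used by the test suite.

Everything here is written from the defining formulas with plain loops,
deliberately sharing no code with the package, so agreement is evidence and
not tautology.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def breslow_log_partial_likelihood(beta, x, time, event):
    """Direct-sum log partial likelihood (Breslow ties) for 1-D or 2-D x."""
    x = np.atleast_2d(np.asarray(x, float).T).T  # (n, p)
    beta = np.atleast_1d(np.asarray(beta, float))
    ll = 0.0
    for i in range(len(time)):
        if event[i] != 1:
            continue
        risk = [j for j in range(len(time)) if time[j] >= time[i]]
        denom = sum(np.exp(x[j] @ beta) for j in risk)
        ll += float(x[i] @ beta) - np.log(denom)
    return ll


def efron_log_partial_likelihood(beta, x, time, event):
    """Direct Efron log partial likelihood, looping over tied event groups."""
    x = np.atleast_2d(np.asarray(x, float).T).T
    beta = np.atleast_1d(np.asarray(beta, float))
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        D = [j for j in range(len(time)) if time[j] == t and event[j] == 1]
        R = [j for j in range(len(time)) if time[j] >= t]
        d = len(D)
        s_risk = sum(np.exp(x[j] @ beta) for j in R)
        s_tied = sum(np.exp(x[j] @ beta) for j in D)
        for j in D:
            ll += float(x[j] @ beta)
        for ell in range(d):
            ll -= np.log(s_risk - ell / d * s_tied)
    return ll


def maximize_partial_likelihood(x, time, event, ties="breslow", p=1):
    """Maximise the hand-written partial likelihood numerically."""
    fn = breslow_log_partial_likelihood if ties == "breslow" else efron_log_partial_likelihood

    def nll(b):
        return -fn(b, x, time, event)

    res = optimize.minimize(nll, np.zeros(p), method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    return res.x


def logrank_chi2(time, event, group):
    """Two-group log-rank chi-square from the standard O-E / V sums."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    group = np.asarray(group)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (group == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def logrank_p(time, event, group):
    return float(stats.chi2.sf(logrank_chi2(time, event, group), 1))


def km_by_hand(time, event):
    """Product-limit survival by explicit multiplication."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    s = 1.0
    out = []
    for t in sorted(set(time)):
        n = (time >= t).sum()
        d = ((time == t) & (event == 1)).sum()
        s *= 1 - d / n
        out.append((t, s))
    return out


def auc_by_pairs(y, score):
    """Exhaustive case-control pair comparison, ties counted one half."""
    y = np.asarray(y)
    score = np.asarray(score, float)
    cases = score[y == 1]
    controls = score[y == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            total += 1.0 if c > k else (0.5 if c == k else 0.0)
    return total / (len(cases) * len(controls))
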