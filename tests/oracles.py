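"""Independent brute-force oracles used only by the test suite.

Each function re-derives a quantity by direct enumeration or naive
tabulation, sharing no code with the implementation it checks.
"""

import numpy as np


def brute_force_logrank(times, events, group1_mask):
    """O/E/V of the group-1 event sum by direct hypergeometric tabulation.

    Walks the distinct event times and accumulates, from explicit 2x2
    tables, the observed count, the conditional expectation d*n1/n and the
    conditional hypergeometric variance d*(n1/n)*(n2/n)*(n-d)/(n-1).
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    g1 = np.asarray(group1_mask, bool)
    O1 = E1 = V = 0.0
    for ti in sorted(set(times[events == 1])):
        n = int((times >= ti).sum())
        n1 = int(((times >= ti) & g1).sum())
        d = int(((times == ti) & (events == 1)).sum())
        d1 = int(((times == ti) & (events == 1) & g1).sum())
        O1 += d1
        E1 += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * ((n - n1) / n) * (n - d) / (n - 1)
    return O1, E1, V


def breslow_partial_loglik(beta, times, events, x):
    """Breslow partial log-likelihood of a single covariate, naively."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for ti in sorted(set(times[events == 1])):
        here = (times == ti) & (events == 1)
        risk = times >= ti
        ll += float(beta * x[here].sum())
        ll -= int(here.sum()) * np.log(np.exp(beta * x[risk]).sum())
    return ll


def grid_search_cox(times, events, x, lo=-5.0, hi=5.0, n_grid=200001):
    """Maximiser of the Breslow partial likelihood over a dense beta grid."""
    grid = np.linspace(lo, hi, n_grid)
    lls = [breslow_partial_loglik(b, times, events, x) for b in grid]
    return float(grid[int(np.argmax(lls))])


def exhaustive_scan(values, times, events, logrank, bounds=(0.10, 0.90)):
    """Evaluate every admissible distinct-value midpoint split directly.

    Uses the supplied two-group log-rank test on each induced split and
    returns (best cutoff, best p, number of candidates), breaking p ties
    toward the most balanced split.
    """
    v = np.asarray(values, float)
    n = v.size
    sv = np.sort(v)
    candidates = []
    for k in range(1, n):
        if sv[k - 1] == sv[k]:
            continue
        frac = k / n
        if frac < bounds[0] - 1e-12 or frac > bounds[1] + 1e-12:
            continue
        candidates.append((k, 0.5 * (sv[k - 1] + sv[k])))
    best = None
    for k, cut in candidates:
        labels = (v > cut).astype(int)
        res = logrank(times, events, labels)
        key = (res.p, abs(k / n - 0.5), k)
        if best is None or key < best[0]:
            best = (key, cut, res.p)
    if best is None:
        return None
    return best[1], best[2], len(candidates)
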