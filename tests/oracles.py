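"""Independent brute-force oracles used to cross-check the package's statistics.

These deliberately share no code with cytomet.stats: ranking + Pearson for
Spearman, the closed-form t on differences, an explicit risk-set product for
Kaplan-Meier, and an event-table accumulation for the logrank statistic.
"""

import numpy as np
from scipy import stats as sps


def spearman_bruteforce(x, y):
    """Midranks by sorting, then the Pearson formula on the ranks."""

    def midrank(v):
        v = np.asarray(v, float)
        order = np.argsort(v)
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    rho = np.sum((rx - rx.mean()) * (ry - ry.mean())) / np.sqrt(
        np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2)
    )
    n = len(rx)
    t = rho * np.sqrt((n - 2) / (1 - rho**2)) if abs(rho) < 1 else np.inf
    p = 2 * sps.t.sf(abs(t), df=n - 2)
    return float(rho), float(p)


def paired_t_bruteforce(x, y):
    d = np.asarray(x, float) - np.asarray(y, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    return float(t), float(2 * sps.t.sf(abs(t), df=n - 1))


def km_bruteforce(times, events):
    """Explicit product over risk sets at each distinct event time."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    steps = [(0.0, 1.0)]
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_at_risk = sum(ti >= t for ti in times)
        d = sum((ti == t) and (ei == 1) for ti, ei in zip(times, events))
        s = s * (1 - d / n_at_risk)
        steps.append((t, s))
    return steps


def logrank_bruteforce(times, events, groups):
    """Observed-minus-expected accumulation with hypergeometric variance."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    levels = sorted(set(groups))
    assert len(levels) == 2
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = [i for i in range(len(times)) if times[i] >= t]
        n = len(at_risk)
        n1 = sum(groups[i] == levels[0] for i in at_risk)
        deaths = [i for i in at_risk if times[i] == t and events[i] == 1]
        d = len(deaths)
        d1 = sum(groups[i] == levels[0] for i in deaths)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    p = float(sps.chi2.sf(chi2, df=1)) if var > 0 else 1.0
    return float(chi2), p
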