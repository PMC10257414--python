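"""Inferential layer: Spearman correlation, paired t-test, Kaplan–Meier
product-limit estimation, two-group logrank comparison, and high/low
stratification.

Spearman and the paired t-test delegate to scipy (midrank ties, t
approximation); the survival estimators are implemented here directly — the
test suite cross-checks them against lifelines and brute-force oracles.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


def spearman(x, y, method: Literal["t", "exact"] = "t") -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    ``method="t"`` uses midranks and the t approximation. ``method="exact"``
    enumerates all rank permutations (n ≤ 10 only) and returns the exact
    two-sided permutation p for |rho|.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    if method == "t":
        return float(rho), float(p)
    if n > 10:
        raise ValueError("exact permutation p limited to n <= 10")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)

    def _rho(r1, r2):
        return np.corrcoef(r1, r2)[0, 1]

    observed = abs(_rho(rx, ry))
    count = total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(_rho(rx, ry[list(perm)])) >= observed - 1e-12:
            count += 1
    return float(rho), count / total


def paired_t(x, y) -> tuple[float, float]:
    """Paired t-test: one-sample t on the differences, two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance differences; paired t undefined")
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


def km_estimate(times, events) -> pd.DataFrame:
    """Kaplan–Meier product-limit estimator.

    Returns a step-function table (time, at_risk, observed, survival)
    starting at (0, n, 0, 1); survival is right-continuous and non-increasing,
    censored subjects leave the risk set after their time.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    if times.shape != events.shape or times.ndim != 1:
        raise ValueError("times and events must be 1-D vectors of equal length")
    if len(times) == 0:
        raise ValueError("need at least one record")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    rows = [(0.0, len(times), 0, 1.0)]
    s = 1.0
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / at_risk
        rows.append((float(t), at_risk, d, s))
    return pd.DataFrame(rows, columns=["time", "at_risk", "observed", "survival"])


def km_survival_at(km: pd.DataFrame, t: float) -> float:
    """S(t) from a km_estimate table (right-continuous step lookup)."""
    mask = km["time"] <= t
    return float(km.loc[mask, "survival"].iloc[-1])


def logrank(times, events, groups) -> tuple[float, float]:
    """Two-group logrank test (hypergeometric variance), chi-square df=1 p."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups)
    if not (len(times) == len(events) == len(groups)):
        raise ValueError("times, events and groups must align")
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"logrank needs exactly 2 non-empty groups, got {len(levels)}")
    g1 = groups == levels[0]

    observed = expected = variance = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        observed += d1
        expected += d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0:
        return 0.0, 1.0
    chi2 = (observed - expected) ** 2 / variance
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


def stratify(
    values,
    rule: Literal["median"] | tuple[Literal["threshold"], float] = "median",
) -> np.ndarray:
    """Label each value 'high' (> cutpoint) or 'low' (<= cutpoint).

    The default cutpoint is the median; ``("threshold", t)`` uses a fixed
    cutpoint (H-score conventions). A degenerate split (all one label) warns.
    """
    values = np.asarray(values, float)
    if rule == "median":
        if len(values) < 2:
            raise ValueError("median stratification needs at least 2 values")
        cut = float(np.median(values))
    elif isinstance(rule, tuple) and rule[0] == "threshold":
        cut = float(rule[1])
    else:
        raise ValueError(f"unknown stratification rule {rule!r}")
    labels = np.where(values > cut, "high", "low").astype(object)
    if len(set(labels)) == 1:
        warnings.warn("degenerate stratification: all values on one side of the cutpoint",
                      stacklevel=2)
    return labels
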