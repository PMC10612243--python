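"""Independent brute-force reference implementations used only by tests.

Each function recomputes a statistic from first principles (explicit loops,
exhaustive enumeration) so the package's implementations can be checked
against a second route.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def km_oracle(times, events) -> list[tuple[float, int, int, float]]:
    """Hand product-limit: (time, at_risk, events, survival_after) rows
    for every distinct observed time, censorings included."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    surv = 1.0
    rows = []
    for t in sorted(set(times.tolist())):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        if d > 0:
            surv *= 1.0 - d / at_risk
        rows.append((t, at_risk, d, surv))
    return rows


def logrank_chi2_oracle(times, events, groups) -> float:
    """Two-group log-rank chi-square via explicit per-event-time
    hypergeometric expectation and (tie-corrected) variance sums."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups, dtype=object)
    labels = sorted(set(groups.tolist()))
    assert len(labels) == 2
    g1 = groups == labels[0]
    num = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1].tolist())):
        at_risk = times >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & g1).sum())
        d = int(((times == t) & (events == 1)).sum())
        d1 = int(((times == t) & (events == 1) & g1).sum())
        e1 = d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        num += d1 - e1
    return num**2 / var


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration of tables with the
    observed margins, summing hypergeometric probabilities <= observed."""
    (a, b), (c, d) = np.asarray(table, dtype=int)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(x: int) -> float:
        # P(first cell = x) under fixed margins
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


def combo_counts_oracle(bool_rows) -> Counter:
    """Direct per-cell pattern counting."""
    return Counter(tuple(bool(v) for v in row) for row in bool_rows)


def polyfunc_oracle(bool_rows, min_positive: int) -> float:
    """Per-cell popcount threshold fraction."""
    rows = list(bool_rows)
    hits = sum(1 for row in rows if sum(bool(v) for v in row) >= min_positive)
    return hits / len(rows)


def high_low_oracle(scores: dict, exclusion_fraction: float) -> dict:
    """Independent re-implementation of the rank-symmetric exclusion split."""
    order = sorted(scores, key=lambda pid: (scores[pid], str(pid)))
    n = len(order)
    m = math.floor(n * exclusion_fraction / 2)
    n_low = (n - 2 * m) // 2
    labels = {}
    for rank, pid in enumerate(order):
        if rank < n_low:
            labels[pid] = "Low"
        elif rank < n_low + 2 * m:
            labels[pid] = "Excluded"
        else:
            labels[pid] = "High"
    return labels
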