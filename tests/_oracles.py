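"""Independent brute-force reference implementations used by the tests.

These stay deliberately naive (explicit loops, no shared code with the
package) so they can serve as oracles for the vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def es_brute_force(scores: np.ndarray, hit_mask: np.ndarray, weight_p: float) -> tuple[float, list[float]]:
    """Running-sum enrichment score by explicit walk down the list."""
    n = len(scores)
    n_hit = int(np.sum(hit_mask))
    total = sum(abs(scores[i]) ** weight_p for i in range(n) if hit_mask[i])
    running = []
    acc = 0.0
    for i in range(n):
        if hit_mask[i]:
            acc += (abs(scores[i]) ** weight_p / total) if total > 0 else 1.0 / n_hit
        else:
            acc -= 1.0 / (n - n_hit)
        running.append(acc)
    mx, mn = max(running), min(running)
    es = mx if mx >= -mn - 1e-12 else mn  # near-ties resolve positive
    return es, running


def bh_brute_force(pvals: list[float]) -> list[float]:
    """Step-up BH by direct definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = []
        for later_pos, j in enumerate(order, start=1):
            if later_pos >= rank_pos:
                candidates.append(pvals[j] * m / later_pos)
        q[i] = min(1.0, min(candidates))
    return q


def hypergeom_tail(k: int, universe: int, n_a: int, n_b: int) -> float:
    """P(overlap >= k) by exact summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(n_a, n_b) + 1):
        total += (
            math.comb(n_a, x)
            * math.comb(universe - n_a, n_b - x)
            / math.comb(universe, n_b)
        )
    return total


def km_by_hand(times: list[float], events: list[int]) -> dict[float, float]:
    """Product-limit estimate at each distinct event time, by definition."""
    pairs = sorted(zip(times, events))
    event_times = sorted({t for t, e in pairs if e == 1})
    s = 1.0
    out = {}
    for et in event_times:
        at_risk = sum(1 for t, _ in pairs if t >= et)
        deaths = sum(1 for t, e in pairs if t == et and e == 1)
        s *= 1 - deaths / at_risk
        out[et] = s
    return out


def logrank_by_hand(ta, ea, tb, eb) -> float:
    """Two-group log-rank chi-square from explicit 2x2 risk tables."""
    event_times = sorted({t for t, e in list(zip(ta, ea)) + list(zip(tb, eb)) if e == 1})
    o_minus_e = 0.0
    var = 0.0
    for t in event_times:
        n_a = sum(1 for x in ta if x >= t)
        n_b = sum(1 for x in tb if x >= t)
        d_a = sum(1 for x, e in zip(ta, ea) if x == t and e == 1)
        d_b = sum(1 for x, e in zip(tb, eb) if x == t and e == 1)
        n, d = n_a + n_b, d_a + d_b
        if n < 2:
            continue
        o_minus_e += d_a - d * n_a / n
        var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var
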