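"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: exact rational
arithmetic and exhaustive enumeration at tiny n.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import comb

import numpy as np


def hypergeom_overlap_counts(N: int, L: int, M: int) -> dict[int, int]:
    """Histogram of |draw ∩ L-set| over all C(N, M) draws, by enumeration.

    The L-set is {0, .., L-1}; draws are enumerated as bitmasks.
    """
    l_mask = (1 << L) - 1
    hist: dict[int, int] = {}
    for combo in itertools.combinations(range(N), M):
        mask = 0
        for i in combo:
            mask |= 1 << i
        k = (mask & l_mask).bit_count()
        hist[k] = hist.get(k, 0) + 1
    return hist


def hypergeom_tail_exact(N: int, L: int, M: int, x: int) -> Fraction:
    """P(overlap >= x) as an exact fraction from the enumeration above."""
    hist = hypergeom_overlap_counts(N, L, M)
    total = comb(N, M)
    return Fraction(sum(c for k, c in hist.items() if k >= x), total)


def bh_stepup(pvalues) -> np.ndarray:
    """Textbook Benjamini-Hochberg step-up: min over the tail of p*m/rank."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adjusted[idx] = running
    return adjusted


def ranksum_exact_p(a, b) -> float:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments.

    Ties get midranks; two-sided p = min(1, 2*min(P(U<=u), P(U>=u))).
    """
    from scipy.stats import rankdata

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n_a = len(a)
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    u_obs = ranks[:n_a].sum() - n_a * (n_a + 1) / 2
    us = [
        sum(ranks[i] for i in comb_idx) - n_a * (n_a + 1) / 2
        for comb_idx in itertools.combinations(range(len(pooled)), n_a)
    ]
    eps = 1e-9
    p_low = sum(u <= u_obs + eps for u in us) / len(us)
    p_high = sum(u >= u_obs - eps for u in us) / len(us)
    return min(1.0, 2 * min(p_low, p_high))


def kaplan_meier_hand(times, events):
    """Product-limit estimate computed the slow way, for tiny inputs."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = []
    s = 1.0
    for t in np.unique(times[events == 1]):
        at_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1 - d / at_risk
        out.append((float(t), s))
    return out
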