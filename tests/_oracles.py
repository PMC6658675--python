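"""Independent brute-force reference implementations used only by tests.

Each oracle is written as a direct, unoptimised transcription of the
defining formula (explicit double loops, no shared code with the
package) so it can serve as an independent check.
"""

from __future__ import annotations

import math

import numpy as np


def cox_partial_nll_breslow(f, time, event) -> float:
    """Negative log-partial likelihood, Breslow ties, direct double loop."""
    total = 0.0
    n = len(time)
    for i in range(n):
        if not event[i]:
            continue
        denom = 0.0
        for j in range(n):
            if time[j] >= time[i]:
                denom += math.exp(f[j])
        total += math.log(denom) - f[i]
    return total


def cindex_pair_counts(risk, time, event):
    """Exhaustive Harrell pair enumeration.

    A pair (i, j) is comparable when sample i's event was observed and
    time_i < time_j strictly; concordant when risk_i > risk_j, tied at
    equal risk.
    """
    conc = disc = tied = 0
    n = len(time)
    for i in range(n):
        if not event[i]:
            continue
        for j in range(n):
            if time[j] <= time[i]:
                continue
            if risk[i] > risk[j]:
                conc += 1
            elif risk[i] < risk[j]:
                disc += 1
            else:
                tied += 1
    total = conc + disc + tied
    value = (conc + 0.5 * tied) / total if total else float("nan")
    return value, conc, disc, tied


def merge_points(rank_lists):
    """Gene ranking points by direct summation: Point_j = sum_k (N - R_jk)."""
    genes = sorted(rank_lists[0].keys())
    N = len(genes)
    points = {}
    for g in genes:
        points[g] = sum(N - ranks[g] for ranks in rank_lists)
    order = sorted(genes, key=lambda g: (-points[g], g))
    return order, points


def dp_direct(w_high, w_low, X_high, X_low):
    """DP_j = |w_high_j * mean(HIGH)_j - w_low_j * mean(LOW)_j| per gene."""
    d = X_high.shape[1]
    out = np.empty(d)
    for j in range(d):
        out[j] = abs(
            w_high[j] * X_high[:, j].mean() - w_low[j] * X_low[:, j].mean()
        )
    return out


def fisher_direct(X_high, X_low):
    """Two-class Fisher criterion, direct per-gene transcription."""
    d = X_high.shape[1]
    out = np.empty(d)
    for j in range(d):
        a, b = X_high[:, j], X_low[:, j]
        mu = np.concatenate([a, b]).mean()
        num = a.size * (a.mean() - mu) ** 2 + b.size * (b.mean() - mu) ** 2
        den = a.size * a.var() + b.size * b.var()
        if den == 0:
            out[j] = math.inf if num > 0 else 0.0
        else:
            out[j] = num / den
    return out
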