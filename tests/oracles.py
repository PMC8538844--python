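"""Independent brute-force oracles, deliberately written with plain Python
loops and a different numerical route than the package implementations.
They exist so that the fast vectorized code paths can be checked against
a second, slower derivation of the same definitions."""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import optimize, special


def brute_force_es(values, gene_ids, gene_set, alpha):
    """Running-sum enrichment score by direct enumeration.

    Ranks ascending by abundance with midranks for ties; walk from most to
    least abundant, ties broken by gene id.
    """
    n = len(values)
    gene_set = set(gene_set)
    sorted_vals = sorted(values)
    rank = {}
    for i in range(n):
        positions = [j + 1 for j in range(n) if sorted_vals[j] == values[i]]
        rank[i] = sum(positions) / len(positions)
    order = sorted(range(n), key=lambda i: (-values[i], str(gene_ids[i])))
    in_set = [str(gene_ids[i]) in gene_set for i in range(n)]
    denom_in = sum(rank[i] ** alpha for i in range(n) if in_set[i])
    n_out = n - sum(in_set)
    es = 0.0
    cum_in = 0.0
    cum_out = 0
    for i in order:
        if in_set[i]:
            cum_in += rank[i] ** alpha
        else:
            cum_out += 1
        es += cum_in / denom_in - cum_out / n_out
    return es


def brute_force_kcdf(x):
    """Kernel-CDF normalization by direct double loop per gene."""
    x = np.asarray(x, dtype=float)
    g, n = x.shape
    out = np.empty_like(x)
    for i in range(g):
        s = np.std(x[i], ddof=1)
        if s == 0:
            out[i] = 0.5
            continue
        h = s / 4.0
        for j in range(n):
            total = 0.0
            for k in range(n):
                total += 0.5 * (1.0 + math.erf((x[i, j] - x[i, k]) / (h * math.sqrt(2))))
            out[i, j] = total / n
    return out


def brute_force_bh(p):
    """Step-up BH q-values straight from the definition."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    for rank_pos, i in enumerate(order, start=1):
        candidates = []
        for later_pos in range(rank_pos, m + 1):
            j = order[later_pos - 1]
            candidates.append(min(1.0, m * p[j] / later_pos))
        q[i] = min(candidates)
    return q


def brute_force_moderated_t(xa, xb):
    """Empirical-Bayes moderated t by a second derivation.

    Uses brentq root-finding on trigamma (instead of Newton) and explicit
    per-gene loops.  Returns (d0, s0_sq, t, p) arrays.
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    na, nb = xa.shape[1], xb.shape[1]
    dg = na + nb - 2
    genes = xa.shape[0]
    s2 = np.empty(genes)
    fc = np.empty(genes)
    for g in range(genes):
        fc[g] = xa[g].mean() - xb[g].mean()
        ss = ((xa[g] - xa[g].mean()) ** 2).sum() + ((xb[g] - xb[g].mean()) ** 2).sum()
        s2[g] = ss / dg
    e = np.log(s2) - special.digamma(dg / 2) + np.log(dg / 2)
    target = e.var(ddof=1) - special.polygamma(1, dg / 2)
    if target <= 0:
        d0 = np.inf
        s0 = math.exp(e.mean())
    else:
        half = optimize.brentq(
            lambda x: special.polygamma(1, x) - target, 1e-6, 1e8
        )
        d0 = 2 * half
        s0 = math.exp(e.mean() + special.digamma(d0 / 2) - math.log(d0 / 2))
    t = np.empty(genes)
    p = np.empty(genes)
    from scipy import stats

    for g in range(genes):
        if np.isinf(d0):
            post = s0
        else:
            post = (d0 * s0 + dg * s2[g]) / (d0 + dg)
        t[g] = fc[g] / math.sqrt(post * (1 / na + 1 / nb))
        if np.isinf(d0):
            p[g] = 2 * stats.norm.sf(abs(t[g]))
        else:
            p[g] = 2 * stats.t.sf(abs(t[g]), d0 + dg)
    return d0, s0, t, p


def brute_force_km(times, events):
    """Product-limit curve by explicit risk-set recomputation."""
    times = list(map(float, times))
    events = list(map(int, events))
    event_times = sorted({t for t, e in zip(times, events) if e == 1})
    surv = []
    s = 1.0
    for t in event_times:
        n = sum(1 for x in times if x >= t)
        d = sum(1 for x, e in zip(times, events) if x == t and e == 1)
        s *= 1 - d / n
        surv.append(s)
    return event_times, surv


def exact_mannwhitney_p(a, b):
    """Two-sided exact rank-sum p by full label enumeration (midranks)."""
    a = list(map(float, a))
    b = list(map(float, b))
    na, nb = len(a), len(b)
    pooled = a + b
    srt = sorted(pooled)
    ranks = []
    for v in pooled:
        pos = [i + 1 for i, x in enumerate(srt) if x == v]
        ranks.append(sum(pos) / len(pos))
    center = na * nb / 2

    def u_of(idx):
        return sum(ranks[i] for i in idx) - na * (na + 1) / 2

    u_obs = u_of(range(na))
    hits = total = 0
    for idx in combinations(range(na + nb), na):
        total += 1
        if abs(u_of(idx) - center) >= abs(u_obs - center) - 1e-12:
            hits += 1
    return u_obs, hits / total
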