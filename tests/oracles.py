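"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from first principles (exact
fractions, full enumeration, per-subject loops) and shares no code with
the package implementations it checks.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from math import factorial

import numpy as np


def _binom(n: int, k: int) -> int:
    if k < 0 or k > n:
        return 0
    return factorial(n) // (factorial(k) * factorial(n - k))


def fisher_oracle(a: int, b: int, c: int, d: int, sidedness: str) -> float:
    """Exact Fisher p by exhaustive enumeration with Fraction arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = _binom(n, c1)
    probs = {}
    for x in range(0, c1 + 1):
        w = _binom(r1, x) * _binom(r2, c1 - x)
        if w > 0:
            probs[x] = Fraction(w, denom)
    p_obs = probs[a]
    if sidedness == "greater":
        total = sum(p for x, p in probs.items() if x >= a)
    elif sidedness == "less":
        total = sum(p for x, p in probs.items() if x <= a)
    else:
        total = sum(p for p in probs.values() if p <= p_obs)
    return float(total)


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Direct-formula BH: q_i = min_{j: p_j >= p_i} min(p_j * m / rank_j, 1)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = ranked * m / np.arange(1, m + 1)
    # enforce step-up monotonicity from the largest p downwards
    for i in range(m - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def anova_oracle(groups) -> tuple[float, float]:
    """F statistic and p via explicit sum-of-squares decomposition."""
    from scipy.stats import f as fdist

    allv = np.concatenate([np.asarray(g, float) for g in groups])
    k = len(groups)
    n = allv.size
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    fstat = (ssb / (k - 1)) / (ssw / (n - k))
    return fstat, float(fdist.sf(fstat, k - 1, n - k))


def wilcoxon_exact_oracle(x, y) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments."""
    x, y = list(x), list(y)
    combined = sorted(x + y)
    ranks = {}
    # midranks
    vals = np.asarray(combined, float)
    order = np.argsort(vals)
    r = np.empty(len(vals))
    i = 0
    while i < len(vals):
        j = i
        while j + 1 < len(vals) and vals[order[j + 1]] == vals[order[i]]:
            j += 1
        r[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    rank_of = {}
    used = [False] * len(combined)

    def rank_lookup(v):
        for idx, c in enumerate(combined):
            if c == v and not used[idx]:
                used[idx] = True
                return r[idx]
        raise AssertionError

    rx = sum(rank_lookup(v) for v in x)
    nx = len(x)
    all_ranks = list(r)
    stats = []
    for subset in itertools.combinations(range(len(all_ranks)), nx):
        stats.append(sum(all_ranks[i] for i in subset))
    stats = np.asarray(stats)
    mean = stats.mean()
    return float(np.mean(np.abs(stats - mean) >= abs(rx - mean) - 1e-12))


def kw_permutation_oracle(groups, n_perm=None) -> float:
    """Permutation p for the Kruskal–Wallis statistic (full enumeration)."""
    sizes = [len(g) for g in groups]
    allv = np.concatenate([np.asarray(g, float) for g in groups])

    def kw_stat(vals_by_group):
        pooled = np.concatenate(vals_by_group)
        n = pooled.size
        order = np.argsort(pooled, kind="mergesort")
        ranks = np.empty(n)
        sv = pooled[order]
        i = 0
        while i < n:
            j = i
            while j + 1 < n and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        start = 0
        h = 0.0
        for g in vals_by_group:
            rsum = ranks[start : start + len(g)].sum()
            h += rsum**2 / len(g)
            start += len(g)
        h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
        # tie correction
        _, counts = np.unique(pooled, return_counts=True)
        corr = 1 - np.sum(counts**3 - counts) / (n**3 - n)
        return h / corr if corr > 0 else 0.0

    obs = kw_stat(groups)
    count = 0
    total = 0
    for perm in itertools.permutations(range(allv.size)):
        vals = allv[list(perm)]
        parts = []
        start = 0
        for s in sizes:
            parts.append(vals[start : start + s])
            start += s
        if kw_stat(parts) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def corr_oracle(m: np.ndarray) -> np.ndarray:
    """Pearson correlation via the explicit covariance formula."""
    m = np.asarray(m, float)
    g = m.shape[0]
    out = np.empty((g, g))
    for i in range(g):
        for j in range(g):
            xi, xj = m[i] - m[i].mean(), m[j] - m[j].mean()
            denom = np.sqrt((xi**2).sum() * (xj**2).sum())
            out[i, j] = (xi * xj).sum() / denom if denom > 0 else np.nan
    return out


def km_oracle(times, events):
    """Product-limit estimate with an explicit per-subject loop.

    Returns (event_times, survival) lists.
    """
    pairs = sorted(zip(times, events))
    evt = sorted({t for t, e in pairs if e == 1})
    surv = []
    s = 1.0
    for t in evt:
        at_risk = sum(1 for tt, _ in pairs if tt >= t)
        deaths = sum(1 for tt, e in pairs if tt == t and e == 1)
        s *= 1.0 - deaths / at_risk
        surv.append(s)
    return evt, surv


def logrank_stat_oracle(times, events, labels) -> float:
    """Two-group log-rank chi-square, independent per-time loop (sum (O-E)^2/E)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    evt = sorted(set(times[events == 1]))
    O = {u: 0.0 for u in uniq}
    E = {u: 0.0 for u in uniq}
    for t in evt:
        n_t = np.sum(times >= t)
        d_t = np.sum((times == t) & (events == 1))
        for u in uniq:
            mask = labels == u
            n_u = np.sum(times[mask] >= t)
            d_u = np.sum((times[mask] == t) & (events[mask] == 1))
            O[u] += d_u
            E[u] += d_t * n_u / n_t
    return sum((O[u] - E[u]) ** 2 / E[u] for u in uniq if E[u] > 0)


def logrank_permutation_p(times, events, labels, stat_fn) -> float:
    """Permutation p-value: fraction of label reassignments with stat >= observed."""
    labels = np.asarray(labels)
    n = labels.size
    n1 = int(np.sum(labels == np.unique(labels)[0]))
    obs = stat_fn(times, events, labels)
    count = total = 0
    base = np.unique(labels)
    for subset in itertools.combinations(range(n), n1):
        perm = np.full(n, base[1], dtype=labels.dtype)
        perm[list(subset)] = base[0]
        if stat_fn(times, events, perm) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total
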