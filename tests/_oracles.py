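"""Independent reference implementations used as test oracles.

These deliberately recompute results by direct definition (per-threshold
simulation, exact combinatorics, exhaustive enumeration) rather than through
the package's algorithms.
"""

from __future__ import annotations

import math
from math import comb, inf


def sweep_clusters(pos, cnt, min_tags, min_fold, max_length):
    """Threshold-sweep clustering oracle.

    For every achievable density d (the density of some site run), the site
    run is recursively split at its minimum-density proper prefix or suffix
    while that minimum is below d (prefix boundary wins ties); the surviving
    runs are the clusters at threshold d. A cluster's d_break is the largest
    d at which it appears (+inf for single sites) and its d_form the largest
    achievable density strictly below the smallest d at which it appears.
    The three reporting filters and the containment simplification are then
    applied by brute force.
    """
    n = len(pos)
    dens = {}
    for a in range(n):
        t = 0
        for b in range(a, n):
            t += cnt[b]
            dens[(a, b)] = t / (pos[b] - pos[a] + 1)
    thresholds = sorted(set(dens.values()))
    appear: dict = {}
    for d in thresholds:
        stack = [(0, n - 1)]
        while stack:
            a, b = stack.pop()
            if a < b:
                pref = min((dens[(a, m)], m) for m in range(a, b))
                suf = min((dens[(m, b)], m) for m in range(a + 1, b + 1))
                if min(pref[0], suf[0]) < d:
                    split = pref[1] if pref[0] <= suf[0] else suf[1] - 1
                    stack += [(a, split), (split + 1, b)]
                    continue
            appear.setdefault((a, b), set()).add(d)
    ext = [0.0] + thresholds
    reported = []
    for (a, b), seen in appear.items():
        d_break = inf if a == b else max(seen)
        lo = min(seen)
        d_form = max(x for x in ext if x < lo)
        total = sum(cnt[a:b + 1])
        span = pos[b] - pos[a] + 1
        if total < min_tags or span > max_length:
            continue
        if d_form > 0 and not (d_break / d_form >= min_fold):
            continue
        reported.append((pos[a], pos[b], total, d_form, d_break))
    kept = []
    for c in reported:
        contained = any(o is not c and o[0] <= c[0] and o[1] >= c[1]
                        and (o[0], o[1]) != (c[0], c[1]) for o in reported)
        if not contained:
            kept.append(c)
    return sorted(kept)


def hypergeom_pmf(k, a_total, b_total, n_draw):
    """P[K = k] drawing n_draw from a_total successes + b_total failures."""
    return (comb(a_total, k) * comb(b_total, n_draw - k)
            / comb(a_total + b_total, n_draw))


def fisher_exact_oracle(a, b, c, d, alternative="two-sided"):
    """Fisher exact p by exhaustive enumeration over the table family."""
    row1, col1 = a + b, a + c
    total = a + b + c + d
    kmin = max(0, row1 + col1 - total)
    kmax = min(row1, col1)
    pmf = {k: hypergeom_pmf(k, col1, total - col1, row1)
           for k in range(kmin, kmax + 1)}
    p_obs = pmf[a]
    if alternative == "greater":
        return sum(p for k, p in pmf.items() if k >= a)
    if alternative == "less":
        return sum(p for k, p in pmf.items() if k <= a)
    return min(1.0, sum(p for p in pmf.values() if p <= p_obs * (1 + 1e-12)))


def binomial_two_sided(y_a, n, p_success):
    """Two-sided exact binomial test, sum-of-smaller-likelihoods convention."""
    pmf = [comb(n, k) * p_success ** k * (1 - p_success) ** (n - k)
           for k in range(n + 1)]
    p_obs = pmf[y_a]
    return min(1.0, sum(p for p in pmf if p <= p_obs * (1 + 1e-12)))


def maximal_cliques_bruteforce(nodes, edges):
    """All maximal cliques by plain recursive extension (no pivoting)."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    out = []

    def extend(clique, candidates, banned):
        if not candidates and not banned:
            out.append(frozenset(clique))
            return
        for v in sorted(candidates):
            extend(clique | {v}, candidates & adj[v], banned & adj[v])
            candidates = candidates - {v}
            banned = banned | {v}

    extend(set(), set(nodes), set())
    return {tuple(sorted(c)) for c in out}
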