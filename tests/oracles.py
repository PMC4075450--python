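"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths (and, where possible, the
libraries) they are checking: pure-Python enumeration and all-pairs
loops only.
"""
from __future__ import annotations

import itertools
import math


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration.

    Sums the probabilities of every table with the observed margins
    whose probability is <= that of the observed table.
    """
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2

    def prob(x: int) -> float:
        if x < 0 or x > n1 or k - x < 0 or k - x > n2:
            return 0.0
        return math.comb(n1, x) * math.comb(n2, k - x) / math.comb(n, k)

    p_obs = prob(a)
    tol = 1e-12
    return min(
        1.0, sum(prob(x) for x in range(0, k + 1) if prob(x) <= p_obs * (1 + tol))
    )


def mannwhitney_two_sided(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all group assignments.

    Requires tie-free data.  p = 2 * min(P(U <= u), P(U >= u)), capped at 1.
    """
    n, m = len(x), len(y)
    pooled = list(x) + list(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    count_le = count_ge = total = 0
    for comb in itertools.combinations(range(n + m), n):
        chosen = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in range(n + m) if i not in chosen]
        u = sum(1 for xi in xs for yj in ys if xi > yj)
        total += 1
        if u <= u_obs:
            count_le += 1
        if u >= u_obs:
            count_ge += 1
    return min(1.0, 2 * min(count_le, count_ge) / total)


def mannwhitney_u(x, y) -> float:
    """U statistic for the first group (0.5 per tie)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def hypergeom_upper_tail(k: int, universe: int, size_a: int, size_b: int) -> float:
    """P(overlap >= k) for random subsets of given sizes, by direct summation."""
    total = 0.0
    hi = min(size_a, size_b)
    denom = math.comb(universe, size_b)
    for i in range(k, hi + 1):
        total += (
            math.comb(size_a, i) * math.comb(universe - size_a, size_b - i) / denom
        )
    return min(1.0, total)


def link_oracle(peaks, genes, promoter_bp=3000, downstream_bp=1000):
    """All-pairs summit-membership links as a set of (peak_id, gene_id)."""
    out = set()
    for p in peaks:
        for g in genes:
            if p.contig != g.contig:
                continue
            s = p.summit
            if g.start <= s < g.end:
                out.add((p.peak_id, g.gene_id))
                continue
            if g.strand == "+":
                d = s - g.tss
                e = s - g.three_prime_end
            else:
                d = g.tss - s
                e = g.three_prime_end - s
            if -promoter_bp <= d < 0 or 0 < e <= downstream_bp:
                out.add((p.peak_id, g.gene_id))
    return out


def min_pair_distance(summits_a, summits_b) -> int:
    """Brute-force minimum |a - b| over all pairs."""
    return min(abs(a - b) for a in summits_a for b in summits_b)
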