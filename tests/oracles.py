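"""Independent reference implementations used only to check the package.

Each oracle is written from first principles (brute force, exact rational
arithmetic, textbook formulas) and deliberately shares no code with the
implementation under test.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations


def expand_and_touch(a, b, tol_bp: int, tol_mode: str = "both") -> bool:
    """Tolerance match by explicit expansion: slacken each interval and test
    for overlap-or-touch of the expanded spans."""
    if a.chrom != b.chrom:
        return False
    ta = tol_bp if tol_mode == "both" else 0
    tb = tol_bp
    a_lo, a_hi = a.start - ta, a.end + ta
    b_lo, b_hi = b.start - tb, b.end + tb
    return a_lo <= b_hi and b_lo <= a_hi


def union_find_consensus(peaks, tol_bp: int, tol_mode: str = "both"):
    """All-pairs single-linkage clustering of peaks via union-find.

    Returns a list of clusters, each a frozenset of indices into *peaks*,
    in no particular order.  O(n^2); test-scale only.
    """
    n = len(peaks)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            if expand_and_touch(
                peaks[i].interval, peaks[j].interval, tol_bp, tol_mode
            ):
                union(i, j)

    clusters: dict[int, set[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), set()).add(i)
    return [frozenset(c) for c in clusters.values()]


def exact_hypergeom_pmf(q: int, m: int, n: int, k: int) -> Fraction:
    """P(X = q) as an exact rational: C(m,q) C(n,k-q) / C(m+n,k)."""
    if q < 0 or q > m or k - q < 0 or k - q > n:
        return Fraction(0)
    return Fraction(math.comb(m, q) * math.comb(n, k - q), math.comb(m + n, k))


def exact_hypergeom_upper(q: int, m: int, n: int, k: int) -> Fraction:
    """P(X >= q) by exact summation over the support."""
    return sum(
        (exact_hypergeom_pmf(i, m, n, k) for i in range(q, min(m, k) + 1)),
        Fraction(0),
    )


def enumerate_hypergeom_pmf(q: int, m: int, n: int, k: int) -> Fraction:
    """P(X = q) by literally enumerating every k-subset of an (m+n)-universe
    and counting how many contain exactly q of the m marked elements.
    Exponential; only for m + n <= ~14."""
    marked = set(range(m))
    hits = 0
    total = 0
    for draw in combinations(range(m + n), k):
        total += 1
        if len(marked.intersection(draw)) == q:
            hits += 1
    return Fraction(hits, total)


def welch_t_df_p(xa, xb):
    """Welch two-sample t, Welch-Satterthwaite df and two-sided p for
    mean(xb) - mean(xa), transcribed directly from the textbook formulas.
    The p-value uses scipy's t survival function (distribution evaluation
    only; the statistic and df are computed here)."""
    from scipy.stats import t as tdist

    na, nb = len(xa), len(xb)
    ma = sum(xa) / na
    mb = sum(xb) / nb
    va = sum((x - ma) ** 2 for x in xa) / (na - 1)
    vb = sum((x - mb) ** 2 for x in xb) / (nb - 1)
    se2 = va / na + vb / nb
    t = (mb - ma) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * tdist.sf(abs(t), df)
    return t, df, p
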