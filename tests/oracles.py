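"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations (O(n^2) all-pairs overlap + union-find,
exhaustive enumeration, textbook definitions) kept free of any code path
from the package itself.
"""

from itertools import combinations
from math import comb

import numpy as np


# ---------------------------------------------------------------------------
# interval oracles


def brute_resize(intervals, window):
    out = []
    for chrom, start, end in intervals:
        mid = (start + end) // 2
        out.append((chrom, max(0, mid - window // 2), mid + window // 2))
    return out


def _overlaps(u, v):
    return u[0] == v[0] and u[1] < v[2] and v[1] < u[2]


def _union_find_components(items):
    """items: list of (chrom, start, end, side). Returns list of component index sets."""
    parent = list(range(len(items)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i, j in combinations(range(len(items)), 2):
        if _overlaps(items[i][:3], items[j][:3]):
            union(i, j)
    groups = {}
    for i in range(len(items)):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())


def brute_cobind_counts(a_intervals, b_intervals, window):
    """(n_cobound, n_a_only, n_b_only) by all-pairs overlap + union-find."""
    items = [(c, s, e, "a") for c, s, e in brute_resize(a_intervals, window)] + [
        (c, s, e, "b") for c, s, e in brute_resize(b_intervals, window)
    ]
    n_co = n_a = n_b = 0
    for grp in _union_find_components(items):
        sides = {items[i][3] for i in grp}
        if sides == {"a", "b"}:
            n_co += 1
        elif sides == {"a"}:
            n_a += 1
        else:
            n_b += 1
    return n_co, n_a, n_b


def brute_shared_loci(loci1, loci2):
    """(n_shared_components, n_side1_shared, n_side2_shared) at >=1 bp overlap."""
    items = [(c, s, e, "a") for c, s, e in loci1] + [(c, s, e, "b") for c, s, e in loci2]
    n_shared = s1 = s2 = 0
    for grp in _union_find_components(items):
        sides = [items[i][3] for i in grp]
        if "a" in sides and "b" in sides:
            n_shared += 1
            s1 += sides.count("a")
            s2 += sides.count("b")
    return n_shared, s1, s2


# ---------------------------------------------------------------------------
# statistics oracles


def brute_trimmed_sd(values, trim_mass):
    """Percentile-filter then n-1 SD, written independently of the package."""
    values = np.sort(np.asarray(values, dtype=float))
    lo_q = (1.0 - trim_mass) / 2.0 * 100.0
    lo = np.percentile(values, lo_q)
    hi = np.percentile(values, 100.0 - lo_q)
    kept = values[(values >= lo) & (values <= hi)]
    return float(np.std(kept, ddof=1)) if kept.size > 1 else 0.0


def brute_bh(pvalues):
    """q_i = min_{j >= i} (m * p_(j) / j), mapped back to input order."""
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def brute_hypergeom_upper(k, N, n, K):
    """P[X >= k] for X ~ Hypergeom(N, n, K), by explicit enumeration."""
    total = comb(N, K)
    acc = 0
    for j in range(k, min(n, K) + 1):
        if K - j <= N - n:
            acc += comb(n, j) * comb(N - n, K - j)
    return acc / total


def brute_pairwise_pearson(data):
    """Pairwise-complete Pearson matrix; pairs with <3 complete cells -> NaN."""
    cols = list(data.columns)
    out = np.full((len(cols), len(cols)), np.nan)
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            x, y = data[ci].to_numpy(float), data[cj].to_numpy(float)
            mask = ~np.isnan(x) & ~np.isnan(y)
            if i == j:
                out[i, j] = 1.0
            elif mask.sum() >= 3:
                xm, ym = x[mask] - x[mask].mean(), y[mask] - y[mask].mean()
                denom = np.sqrt((xm**2).sum() * (ym**2).sum())
                if denom > 0:
                    out[i, j] = (xm * ym).sum() / denom
    return out


def brute_venn(sets):
    """Exhaustive membership enumeration: element -> exact tissue combination."""
    combos = {}
    universe = set().union(*sets.values())
    for el in universe:
        key = frozenset(t for t, s in sets.items() if el in s)
        combos.setdefault(key, set()).add(el)
    return combos
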