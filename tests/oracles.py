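"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own code paths: enumeration and
direct formula evaluation only.
"""

from fractions import Fraction
from itertools import product
from math import comb, factorial

import numpy as np


def enumerate_fixed_margin_tables(row, col):
    """All nonnegative integer tables with the given margins, with their
    exact probabilities under the uniform-multivariate-hypergeometric null
    P(T) = prod(r_i!) prod(c_j!) / (N! prod(t_ij!))."""
    row, col = list(row), list(col)
    n_rows, n_cols = len(row), len(col)
    N = sum(row)
    assert N == sum(col)
    base = Fraction(1)
    for r in row:
        base *= factorial(r)
    for c in col:
        base *= factorial(c)
    base /= factorial(N)

    tables = []

    def rec(i, remaining_cols, current):
        if i == n_rows - 1:
            last = tuple(remaining_cols)
            if all(v >= 0 for v in last):
                tables.append(current + [list(last)])
            return
        r = row[i]

        def fill(j, left, rowvals):
            if j == n_cols - 1:
                if 0 <= left <= remaining_cols[j]:
                    rec(
                        i + 1,
                        [rc - rv for rc, rv in zip(remaining_cols, rowvals + [left])],
                        current + [rowvals + [left]],
                    )
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                fill(j + 1, left - v, rowvals + [v])

        fill(0, r, [])

    rec(0, col, [])
    out = []
    for t in tables:
        p = base
        for rowvals in t:
            for v in rowvals:
                p /= factorial(v)
        out.append((np.array(t), p))
    assert abs(sum(p for _, p in out) - 1) == 0
    return out


def chi2_of(table):
    t = np.asarray(table, dtype=float)
    e = np.outer(t.sum(1), t.sum(0)) / t.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(e > 0, (t - e) ** 2 / e, 0.0)
    return float(terms.sum())


def exact_chi2_pvalue(table):
    """P(X2 >= X2_obs) under the fixed-margins null, by full enumeration."""
    t = np.asarray(table, dtype=int)
    obs = chi2_of(t)
    total = Fraction(0)
    for tab, p in enumerate_fixed_margin_tables(t.sum(1), t.sum(0)):
        if chi2_of(tab) >= obs - 1e-9:
            total += p
    return float(total)


def fisher_two_sided_oracle(table):
    """Two-sided Fisher p for a 2x2 table: sum of fixed-margin table
    probabilities not exceeding the observed table's probability."""
    t = np.asarray(table, dtype=int)
    tables = enumerate_fixed_margin_tables(t.sum(1), t.sum(0))
    p_obs = next(p for tab, p in tables if (tab == t).all())
    return float(sum(p for _, p in tables if p <= p_obs))


def linkage_clusters_oracle(positions, window):
    """All-pairs single-linkage on integer positions: connected components
    of the graph joining every pair within ``window``... chained through
    intermediate members (transitive closure)."""
    positions = list(positions)
    n = len(positions)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= window:
                parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(g) for g in groups.values())


def merge_components_oracle(items, mergeable):
    """Connected components of the pairwise mergeable relation."""
    n = len(items)
    adj = {i: set() for i in range(n)}
    for i in range(n):
        for j in range(i + 1, n):
            if mergeable(items[i], items[j]):
                adj[i].add(j)
                adj[j].add(i)
    seen, comps = set(), []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], []
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.append(k)
            stack.extend(adj[k] - seen)
        comps.append(sorted(comp))
    return sorted(comps)


def mi_bits_oracle(col_a, col_b):
    """MI in bits by direct summation over the empirical joint distribution
    of two symbol sequences (pairwise-complete: '-' rows dropped)."""
    pairs = [(a, b) for a, b in zip(col_a, col_b) if a != "-" and b != "-"]
    n = len(pairs)
    if n == 0:
        return 0.0
    joint = {}
    for ab in pairs:
        joint[ab] = joint.get(ab, 0) + 1
    pa, pb = {}, {}
    for (a, b), c in joint.items():
        pa[a] = pa.get(a, 0) + c
        pb[b] = pb.get(b, 0) + c
    mi = 0.0
    for (a, b), c in joint.items():
        mi += (c / n) * np.log2(c * n / (pa[a] * pb[b]))
    return mi


def peaks_oracle(profile, min_height=0.2, min_distance=2, min_width=2):
    """Direct local-maximum scan with the stated constraints."""
    x = list(profile)
    n = len(x)
    cands = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if (i == 0 or x[i - 1] < x[i]) and (j == n - 1 or x[j + 1] < x[i]):
            if x[i] >= min_height:
                lb = i - 1 if i > 0 else i
                rb = j + 1 if j < n - 1 else j
                if rb - lb + 1 >= min_width:
                    cands.append(((i + j) // 2, x[i]))
        i = j + 1
    cands.sort(key=lambda t: (-t[1], t[0]))
    kept = []
    for pos, h in cands:
        if all(abs(pos - q) >= min_distance for q, _ in kept):
            kept.append((pos, h))
    return sorted(kept)
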