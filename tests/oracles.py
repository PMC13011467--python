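"""Independent brute-force oracles used by the unit and acceptance tests.

Every function here recomputes a quantity by direct enumeration or naive
summation, deliberately sharing no code with the package implementations
they check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


def brute_single_linkage(positions, counts, window):
    """O(n^2) single-linkage clustering of 1-D positions.

    Builds the graph with an edge wherever |pi - pj| <= window and takes
    connected components. Returns a sorted list of
    (representative, total_count, sorted member tuple) with the
    representative = member with greatest count, ties to the smallest
    coordinate.
    """
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= window:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    out = []
    for idx in comps.values():
        members = sorted(positions[i] for i in idx)
        rep = min(idx, key=lambda i: (-counts[i], positions[i]))
        out.append((positions[rep], sum(counts[i] for i in idx), tuple(members)))
    return sorted(out)


def oneway_f(values, groups):
    """One-way ANOVA F by explicit sum-of-squares accumulation."""
    labels = sorted(set(groups))
    grand = sum(values) / len(values)
    ssb = ssw = 0.0
    for g in labels:
        xs = [v for v, lab in zip(values, groups) if lab == g]
        m = sum(xs) / len(xs)
        ssb += len(xs) * (m - grand) ** 2
        ssw += sum((x - m) ** 2 for x in xs)
    df1 = len(labels) - 1
    df2 = len(values) - len(labels)
    return (ssb / df1) / (ssw / df2)


def twoway_f(values, fa, fb):
    """Balanced two-way ANOVA term F statistics by explicit summation.

    Returns (F_a, F_b, F_ab) for the complete balanced design.
    """
    la, lb = sorted(set(fa)), sorted(set(fb))
    a, b = len(la), len(lb)
    n = len(values)
    r = n // (a * b)
    grand = sum(values) / n

    def cell(i, j):
        return [v for v, x, y in zip(values, fa, fb) if x == la[i] and y == lb[j]]

    cm = [[sum(cell(i, j)) / r for j in range(b)] for i in range(a)]
    ma = [sum(cm[i]) / b for i in range(a)]
    mb = [sum(cm[i][j] for i in range(a)) / a for j in range(b)]
    ss_a = b * r * sum((m - grand) ** 2 for m in ma)
    ss_b = a * r * sum((m - grand) ** 2 for m in mb)
    ss_ab = r * sum(
        (cm[i][j] - ma[i] - mb[j] + grand) ** 2 for i in range(a) for j in range(b)
    )
    ss_err = sum(
        (x - cm[i][j]) ** 2 for i in range(a) for j in range(b) for x in cell(i, j)
    )
    df_err = a * b * (r - 1)
    return (
        (ss_a / (a - 1)) / (ss_err / df_err),
        (ss_b / (b - 1)) / (ss_err / df_err),
        (ss_ab / ((a - 1) * (b - 1))) / (ss_err / df_err),
    )


def bh_naive(pvals):
    """Benjamini-Hochberg q-values by the O(n^2) min-over-tail definition."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    q = [0.0] * n
    for rank_pos, i in enumerate(order, start=1):
        tail = [
            pvals[j] * n / (r + 1)
            for r, j in enumerate(order)
            if r + 1 >= rank_pos
        ]
        q[i] = min(1.0, min(tail))
    return q


def fisher_two_sided(k, n, K, N):
    """Two-sided Fisher exact p by exact hypergeometric enumeration.

    The 2x2 table is (k, n-k; K-k, N-n-K+k) with margins n (DE set), K
    (category) and total N. Sums, in exact rational arithmetic, the
    probabilities of all tables with the same margins whose probability
    does not exceed that of the observed table.
    """
    def pmf(a):
        return Fraction(math.comb(K, a) * math.comb(N - K, n - a), math.comb(N, n))

    lo = max(0, n + K - N)
    hi = min(n, K)
    p_obs = pmf(k)
    total = sum(pmf(a) for a in range(lo, hi + 1) if pmf(a) <= p_obs)
    return float(total)


def de_rules(lfcs, fold=5.0):
    """The DE and salt-responsiveness rules evaluated literally.

    ``lfcs`` is the 6-vector (salt t1-t3, then no-salt t1-t3) of zeroed
    log2 fold changes. Returns (is_de, salt_class or None); the salt
    class is evaluated only when the gene is DE.
    """
    log_fold = math.log2(fold)
    seven = list(lfcs) + [0.0]
    is_de = (max(seven) - min(seven)) >= log_fold
    if not is_de:
        return False, None
    m_plus = max(lfcs[:3])
    m_minus = max(lfcs[3:])
    if m_plus - m_minus >= log_fold:
        return True, "salt_up"
    if m_minus - m_plus >= log_fold:
        return True, "salt_down"
    return True, "neither"


def grid_vectors(grid, length=6):
    """All lfc vectors over the grid (cartesian power)."""
    return itertools.product(grid, repeat=length)
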