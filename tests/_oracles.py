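"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as literal, naive transcriptions of the
definitions (plain Python loops, no vectorization, no reuse of package
internals) so the tests compare two independent routes.
"""

from __future__ import annotations

import math
from itertools import combinations

M_H = 1.007825


# ---------------------------------------------------------------- features

def _d1(a, b):
    return a - b


def _d2(a, b):
    return a - b + M_H / 2


def _d3(a, b):
    return a - b + 2 * M_H / 3


def _d4(a, b):
    return a - 2 * b + M_H / 3


def _s1(a, b):
    return a + b


def _s2(a, b):
    return a + b + M_H / 2


def _s3(a, b):
    return a + b + 2 * M_H / 3


def _s4(a, b):
    return a + 2 * b + M_H / 3


def _within(value, target, theta):
    return abs(value - target) <= theta


def oracle_diff_feature(x, ys, targets, theta):
    """Literal nine-clause difference feature (F1/F3/F4 structure)."""
    count = 0
    for y in ys:
        hit = False
        for t in targets:
            if (_within(abs(_d1(x, y)), t, theta)
                    or _within(abs(_d1(x, y)), t / 2, theta)
                    or _within(abs(_d1(x, y)), t / 3, theta)
                    or _within(abs(_d2(x, y)), t / 2, theta)
                    or _within(abs(_d2(y, x)), t / 2, theta)
                    or _within(abs(_d3(x, y)), t / 3, theta)
                    or _within(abs(_d3(y, x)), t / 3, theta)
                    or _within(abs(_d4(x, y)), t / 3, theta)
                    or _within(abs(_d4(y, x)), t / 3, theta)):
                hit = True
                break
        if hit:
            count += 1
    return count


def oracle_F1(x, ys, residue_masses, theta=0.3):
    return oracle_diff_feature(x, ys, sorted(set(residue_masses)), theta)


def oracle_F2(x, i, ys, M, theta=0.3, offset_per_position=2.0):
    t1 = M + offset_per_position * i + 2 * M_H
    t2 = (M + offset_per_position * i) / 2 + 2 * M_H
    t3 = (M + offset_per_position * i) / 3 + 2 * M_H
    count = 0
    for y in ys:
        if (_within(_s1(x, y), t1, theta)
                or _within(_s1(x, y), t2, theta)
                or _within(_s1(x, y), t3, theta)
                or _within(_s2(x, y), t2, theta)
                or _within(_s2(y, x), t2, theta)
                or _within(_s3(x, y), t3, theta)
                or _within(_s3(y, x), t3, theta)
                or _within(_s4(x, y), t3, theta)
                or _within(_s4(y, x), t3, theta)):
            count += 1
    return count


def oracle_F3(x, ys, theta=0.3, m_h2o=18.010565, m_nh3=17.026549):
    return oracle_diff_feature(x, ys, [m_h2o, m_nh3], theta)


def oracle_F4(x, ys, theta=0.3, m_co=27.994915, m_nh=15.010899):
    return oracle_diff_feature(x, ys, [m_co, m_nh], theta)


def oracle_F5(intensities, t_min, t_mean, t_max, threshold=0.3,
              partner_mean=None, shared_positions=None):
    """Literal envelope-agreement criterion over the non-anchor members.

    ``shared_positions`` maps positions in this cluster to positions in
    the overlapping partner whose mean envelope is subtracted first.
    """
    total = sum(intensities)
    e = [v / total for v in intensities]
    if shared_positions:
        for i, j in shared_positions.items():
            e[i] = e[i] - partner_mean[j]
    count = 0
    for i in range(1, len(e)):
        residual = min(abs(e[i] - t_min[i]), abs(e[i] - t_max[i]))
        if residual / t_mean[i] <= threshold:
            count += 1
    return count


# ------------------------------------------------------- isotope patterns

def oracle_isotope_distribution(formula, abundances, n_isotopes=3):
    """Isotope distribution by explicit enumeration of heavy placements.

    Enumerates every way of distributing +1 and +2 nominal-mass shifts
    over the atoms (shifts above n_isotopes-1 are dropped before
    renormalization, mirroring truncation).
    """
    elements = [(el, n) for el, n in formula.items() if n > 0]
    dist = [0.0] * n_isotopes

    def expand(idx, shift, prob):
        if shift >= n_isotopes:
            return
        if idx == len(elements):
            dist[shift] += prob
            return
        el, n = elements[idx]
        ab = list(abundances[el]) + [0.0, 0.0]
        p0, p1, p2 = ab[0], ab[1], ab[2]
        # k1 atoms at +1, k2 atoms at +2, the rest at +0
        budget = n_isotopes - 1 - shift
        for k1 in range(0, min(n, budget) + 1):
            for k2 in range(0, min(n - k1, (budget - k1) // 2) + 1):
                add = k1 + 2 * k2
                ways = math.comb(n, k1) * math.comb(n - k1, k2)
                p = ways * (p1 ** k1) * (p2 ** k2) * (p0 ** (n - k1 - k2))
                if p:
                    expand(idx + 1, shift + add, prob * p)

    expand(0, 0, 1.0)
    total = sum(dist)
    return [v / total for v in dist]


# ------------------------------------------------------------- path search

def oracle_max_path(graph, source="source", sink="sink"):
    """Maximum-score source->sink path by exhaustive DFS enumeration."""
    best = [None]

    def dfs(node, score, path):
        if node == sink:
            if best[0] is None or score > best[0]:
                best[0] = score
            return
        for _, v, data in graph.out_edges(node, data=True):
            if v in path:
                continue
            dfs(v, score + data.get("weight", 0.0), path | {v})

    dfs(source, 0.0, {source})
    if best[0] is None:
        raise ValueError("no source-sink path")
    return best[0]


def oracle_all_subset_clusters(mzs, iso_gap=1.003, tol=0.01, charges=(1, 2, 3),
                               max_len=3):
    """All 2..max_len subsets passing the common-charge gap predicate."""
    out = set()
    indices = range(len(mzs))
    for size in range(2, max_len + 1):
        for combo in combinations(indices, size):
            gaps = [mzs[b] - mzs[a] for a, b in zip(combo, combo[1:])]
            for z in charges:
                if all(abs(g - iso_gap / z) <= tol for g in gaps):
                    out.add((combo, z))
    return out


# --------------------------------------------------------------- matching

def oracle_match(exp, theo, tolerance):
    """Greedy one-to-one matching by ascending difference, quadratic form."""
    pairs = []
    for ei, e in enumerate(exp):
        for ti, t in enumerate(theo):
            if abs(e - t) <= tolerance:
                pairs.append((abs(e - t), ei, ti))
    pairs.sort()
    used_e, used_t = set(), set()
    tp = 0
    for _, ei, ti in pairs:
        if ei in used_e or ti in used_t:
            continue
        used_e.add(ei)
        used_t.add(ti)
        tp += 1
    return tp, len(exp) - tp, len(theo) - tp
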