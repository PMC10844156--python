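"""Independent reference implementations used only to cross-check the package.

Everything here works on plain coordinate tuples (x1, y1, x2, y2) and is
written as a literal, unoptimised transcription of the documented
procedures, deliberately sharing no code with the package under test.
"""

from __future__ import annotations

from itertools import product


def _area(b):
    return (b[2] - b[0]) * (b[3] - b[1])


def _centroid(b):
    return ((b[0] + b[2]) / 2.0, (b[1] + b[3]) / 2.0)


def _inside(pt, b):
    return b[0] <= pt[0] <= b[2] and b[1] <= pt[1] <= b[3]


def _correspond(b, b2):
    return _inside(_centroid(b), b2) or _inside(_centroid(b2), b)


def _inter(b, b2):
    w = min(b[2], b2[2]) - max(b[0], b2[0])
    h = min(b[3], b2[3]) - max(b[1], b2[1])
    return w * h if (w > 0 and h > 0) else 0.0


def literal_greedy_match(boxes_a, boxes_b):
    """Literal enumeration of the greedy steps.

    Repeatedly: take the largest box not yet matched and not yet set aside
    (ties: lexicographically smallest coordinates, side a first); scan the
    other side's unmatched boxes for correspondents; pick the one with the
    largest intersection, then the largest, then the lexicographically
    smallest; a seed without a correspondent is set aside but stays
    available as a candidate.  Returns the matched index-pair set
    {((side, i), (side, j)), ...} oriented a-then-b.
    """
    sides = {0: [tuple(b) for b in boxes_a], 1: [tuple(b) for b in boxes_b]}
    matched = {0: set(), 1: set()}
    set_aside = {0: set(), 1: set()}
    pairs = set()
    while True:
        seeds = [
            (s, i)
            for s in (0, 1)
            for i in range(len(sides[s]))
            if i not in matched[s] and i not in set_aside[s]
        ]
        if not seeds:
            break
        s, i = sorted(
            seeds, key=lambda t: (-_area(sides[t[0]][t[1]]), sides[t[0]][t[1]], t[0])
        )[0]
        b = sides[s][i]
        o = 1 - s
        cands = [
            j
            for j in range(len(sides[o]))
            if j not in matched[o] and _correspond(b, sides[o][j])
        ]
        if cands:
            j = sorted(
                cands,
                key=lambda j: (-_inter(b, sides[o][j]), -_area(sides[o][j]), sides[o][j]),
            )[0]
            matched[s].add(i)
            matched[o].add(j)
            pairs.add(((0, i), (1, j)) if s == 0 else ((0, j), (1, i)))
        else:
            set_aside[s].add(i)
    return pairs


def max_cardinality_matching(boxes_a, boxes_b):
    """Size of the largest correspondence-respecting matching, by recursion."""
    a = [tuple(b) for b in boxes_a]
    b = [tuple(b) for b in boxes_b]
    adj = [[j for j in range(len(b)) if _correspond(a[i], b[j])] for i in range(len(a))]

    def rec(i, used):
        if i == len(a):
            return 0
        best = rec(i + 1, used)
        for j in adj[i]:
            if j not in used:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    return rec(0, frozenset())


def exact_wilcoxon_two_sided_p(values):
    """Two-sided signed-rank p by enumerating every sign assignment.

    Zeros are discarded; ties get average ranks.  Only feasible for small
    series (2^n assignments).
    """
    d = [v for v in values if v != 0]
    n = len(d)
    if n == 0:
        return 1.0
    absd = sorted((abs(v), k) for k, v in enumerate(d))
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j < n and absd[j][0] == absd[i][0]:
            j += 1
        avg = (i + 1 + j) / 2.0
        for k in range(i, j):
            ranks[absd[k][1]] = avg
        i = j
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    dist = []
    for signs in product((0, 1), repeat=n):
        dist.append(sum(r for r, s in zip(ranks, signs) if s))
    m = len(dist)
    eps = 1e-9
    p_le = sum(1 for w in dist if w <= w_obs + eps) / m
    p_ge = sum(1 for w in dist if w >= w_obs - eps) / m
    return min(1.0, 2.0 * min(p_le, p_ge))
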