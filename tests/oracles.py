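"""Independent brute-force oracles used only by the test suite."""

from __future__ import annotations

import itertools

import numpy as np

# The sixteen triad classes written out as explicit edge sets on {0,1,2},
# in the standard census order.  Deliberately independent of the package's
# decision-table construction: classification below proceeds by raw
# isomorphism search against these exemplars.
TRIAD_EXEMPLARS = [
    ("003", set()),
    ("012", {(0, 1)}),
    ("102", {(0, 1), (1, 0)}),
    ("021D", {(1, 0), (1, 2)}),
    ("021U", {(0, 1), (2, 1)}),
    ("021C", {(0, 1), (1, 2)}),
    ("111D", {(0, 1), (1, 0), (2, 1)}),
    ("111U", {(0, 1), (1, 0), (1, 2)}),
    ("030T", {(0, 1), (2, 1), (0, 2)}),
    ("030C", {(0, 1), (1, 2), (2, 0)}),
    ("201", {(0, 1), (1, 0), (1, 2), (2, 1)}),
    ("120D", {(1, 0), (1, 2), (0, 2), (2, 0)}),
    ("120U", {(0, 1), (2, 1), (0, 2), (2, 0)}),
    ("120C", {(0, 1), (1, 2), (0, 2), (2, 0)}),
    ("210", {(0, 1), (1, 2), (2, 1), (0, 2), (2, 0)}),
    ("300", {(0, 1), (1, 0), (1, 2), (2, 1), (0, 2), (2, 0)}),
]


def classify_triad_bruteforce(edges: set[tuple[int, int]]) -> int:
    """1-based triad class of an edge set on {0,1,2} by isomorphism search."""
    for idx, (_, exemplar) in enumerate(TRIAD_EXEMPLARS, start=1):
        for perm in itertools.permutations(range(3)):
            if {(perm[u], perm[v]) for u, v in edges} == exemplar:
                return idx
    raise AssertionError("unclassifiable triad (impossible)")


def triad_census_bruteforce(network) -> np.ndarray:
    """Triple-by-triple census of a directed network, via the brute classifier."""
    nodes = sorted(network.nodes, key=str)
    counts = np.zeros(16, dtype=int)
    for triple in itertools.combinations(nodes, 3):
        pos = {v: i for i, v in enumerate(triple)}
        edges = {
            (pos[u], pos[v])
            for u, v in network.edges()
            if u in pos and v in pos
        }
        counts[classify_triad_bruteforce(edges) - 1] += 1
    return counts


def welch_f_direct(groups) -> tuple[float, float, float]:
    """Welch's F by direct high-precision evaluation of the textbook formula."""
    from fractions import Fraction

    k = len(groups)
    n = [len(g) for g in groups]
    mean = [sum(map(Fraction, map(str, g))) / len(g) for g in groups]
    var = [
        sum((Fraction(str(x)) - m) ** 2 for x in g) / (len(g) - 1)
        for g, m in zip(groups, mean)
    ]
    w = [Fraction(ni) / vi for ni, vi in zip(n, var)]
    sw = sum(w)
    mw = sum(wi * mi for wi, mi in zip(w, mean)) / sw
    a = sum(wi * (mi - mw) ** 2 for wi, mi in zip(w, mean)) / (k - 1)
    lam = sum((1 - wi / sw) ** 2 / (ni - 1) for wi, ni in zip(w, n))
    b = 1 + Fraction(2 * (k - 2), k**2 - 1) * lam
    f = a / b
    df2 = Fraction(k**2 - 1) / (3 * lam)
    return float(f), float(k - 1), float(df2)
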