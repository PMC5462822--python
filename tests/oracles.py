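"""Independent brute-force oracles used to freeze expected values in tests.

These deliberately avoid the package's own code paths: set arithmetic for the
pairwise beta-diversity formulas and exhaustive topology enumeration for
parsimony scores.
"""

from __future__ import annotations

import math


def beta_pair(set1: set, set2: set):
    """(total Sorensen, turnover, nestedness) for two presence sets."""
    a = len(set1 & set2)
    b = len(set1 - set2)
    c = len(set2 - set1)
    total = (b + c) / (2 * a + b + c)
    turn = min(b, c) / (a + min(b, c)) if (a + min(b, c)) else 0.0
    return total, turn, total - turn


def all_rooted_topologies(leaves: list[int]):
    """Every rooted binary topology (nested tuples) with the first leaf as the
    root's outgroup partner: equivalent to enumerating unrooted topologies."""

    def insert_all(t, leaf):
        yield (t, leaf)
        if not isinstance(t, int):
            l, r = t
            for nl in insert_all(l, leaf):
                yield (nl, r)
            for nr in insert_all(r, leaf):
                yield (l, nr)

    if len(leaves) < 3:
        raise ValueError("need >= 3 leaves")
    cur = [(leaves[1], leaves[2])]
    for lf in leaves[3:]:
        cur = [t2 for t in cur for t2 in insert_all(t, lf)]
    return [(leaves[0], t) for t in cur]


def fitch_steps_naive(topo, char_states: dict[int, int]) -> int:
    """Textbook Fitch first pass on a single binary character."""

    def rec(node):
        if isinstance(node, int):
            return {char_states[node]}, 0
        (s1, c1), (s2, c2) = rec(node[0]), rec(node[1])
        inter = s1 & s2
        if inter:
            return inter, c1 + c2
        return s1 | s2, c1 + c2 + 1

    return rec(topo)[1]


def exhaustive_min_length(matrix_rows, outgroup_last: bool = True) -> int:
    """Minimum Fitch length over every topology (rows = taxa incl. outgroup)."""
    n = len(matrix_rows)
    n_chars = len(matrix_rows[0])
    topos = all_rooted_topologies(list(range(n)))
    best = math.inf
    for t in topos:
        total = 0
        for j in range(n_chars):
            states = {i: int(matrix_rows[i][j]) for i in range(n)}
            total += fitch_steps_naive(t, states)
            if total >= best:
                break
        best = min(best, total)
    return int(best)
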