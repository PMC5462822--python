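"""Parsimony Analysis of Endemicity (PAE) at desk scale.

Grid cells are treated as terminals, species presences as binary characters,
and the matrix (rooted on an all-absent hypothetical outgroup) is analysed by
Fitch parsimony: random-addition-sequence starts followed by subtree
pruning-regrafting (which subsumes nearest-neighbour interchange) to a local
optimum, retaining all distinct topologies at the best length. Areas of
endemism are read from clades of the strict consensus supported by at least
one non-homoplastic species occurrence (a species found in exactly the cells
of the clade and requiring a single origin on every shortest tree).

Character state sets are bit-packed two planes per node (one per state), so a
Fitch pass costs a handful of big-integer operations per internal node.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core_data import PresenceAbsenceMatrix

logger = logging.getLogger(__name__)

# A topology is a nested tuple over leaf indices: a leaf is an int, an internal
# node a 2-tuple. The full rooted tree is (outgroup_leaf, ingroup_subtree).


@dataclass
class CharacterMatrix:
    cell_labels: list[str]
    char_names: list[str]
    data: np.ndarray  # (n_cells + 1, n_chars) uint8; last row = all-absent outgroup
    uninformative: np.ndarray  # bool per character (singleton presences)
    pruned_chars: list[str] = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.cell_labels)

    @property
    def n_chars(self) -> int:
        return len(self.char_names)

    @property
    def n_leaves(self) -> int:
        return self.n_cells + 1

    @property
    def outgroup_index(self) -> int:
        return self.n_cells

    def leaf_planes(self):
        """Bit planes (absent_bits, present_bits) per leaf, chars packed LSB-first."""
        planes = []
        for row in self.data:
            a = b = 0
            for j, v in enumerate(row):
                if v:
                    b |= 1 << j
                else:
                    a |= 1 << j
            planes.append((a, b))
        return planes


@dataclass
class PaeTree:
    topology: tuple  # (outgroup, ingroup_subtree)
    length: int


@dataclass
class PaeResult:
    shortest_trees: list[PaeTree]
    best_length: int
    consensus_clades: set[frozenset]
    matrix: CharacterMatrix

    def consensus_newick(self) -> str:
        return consensus_to_newick(self.consensus_clades, self.matrix)


@dataclass
class ConstrainedSearchResult:
    constrained_length: int
    best_length: int
    constrained_trees: list[PaeTree]

    @property
    def extra_steps(self) -> int:
        return self.constrained_length - self.best_length


def build_character_matrix(pam: PresenceAbsenceMatrix) -> CharacterMatrix:
    """Cells-as-taxa binary matrix with an all-absent outgroup appended.

    Invariant characters (species in no retained cell or in every retained
    cell) carry no grouping signal relative to cells and are pruned with a log
    message; single-cell characters are kept but flagged uninformative.
    """
    if pam.n_cells < 3:
        raise ValueError("too few taxa: need at least 3 cells")
    m = pam.matrix.astype(np.uint8)
    colsum = m.sum(axis=0)
    keep = (colsum > 0) & (colsum < pam.n_cells)
    pruned = [t for t, k in zip(pam.taxa, keep) if not k]
    if pruned:
        logger.info("pruned %d invariant characters: %s", len(pruned), pruned[:10])
    m = m[:, keep]
    names = [t for t, k in zip(pam.taxa, keep) if k]
    data = np.vstack([m, np.zeros((1, m.shape[1]), dtype=np.uint8)])
    uninf = m.sum(axis=0) <= 1
    labels = [f"cell_{c}" for c in np.asarray(pam.cells).tolist()]
    return CharacterMatrix(labels, names, data, uninf, pruned)


# ---------------------------------------------------------------------------
# Fitch scoring on bit planes

def _fitch(node, planes, full):
    """Return (absent_bits, present_bits, steps) for a subtree."""
    if isinstance(node, int):
        a, b = planes[node]
        return a, b, 0
    l, r = node
    la, lb, ls = _fitch(l, planes, full)
    ra, rb, rs = _fitch(r, planes, full)
    ia = la & ra
    ib = lb & rb
    empty = full & ~(ia | ib)
    steps = ls + rs + empty.bit_count()
    a = ia | (empty & (la | ra))
    b = ib | (empty & (lb | rb))
    return a, b, steps


def fitch_length(tree: PaeTree | tuple, matrix: CharacterMatrix) -> int:
    """Total Fitch parsimony steps of a (rooted) topology on the matrix."""
    topo = tree.topology if isinstance(tree, PaeTree) else tree
    leaves = _leaf_set(topo)
    if leaves != set(range(matrix.n_leaves)):
        raise ValueError("tree leaf set does not match matrix taxa")
    planes = matrix.leaf_planes()
    full = (1 << matrix.n_chars) - 1
    return _fitch(topo, planes, full)[2]


def character_steps(topo: tuple, matrix: CharacterMatrix, char_j: int) -> int:
    """Fitch steps of a single character on a topology."""
    full = 1 << char_j
    planes = [(a & full, b & full) for a, b in matrix.leaf_planes()]
    return _fitch(topo, planes, full)[2]


def _leaf_set(node) -> set[int]:
    if isinstance(node, int):
        return {node}
    return _leaf_set(node[0]) | _leaf_set(node[1])


def _clades(node, out=None):
    """Leaf-index frozensets of every internal node of a (sub)tree."""
    if out is None:
        out = []
    if isinstance(node, int):
        return frozenset((node,)), out
    l, _ = _clades(node[0], out)
    r, _ = _clades(node[1], out)
    s = l | r
    out.append(s)
    return s, out


def topology_signature(topo: tuple) -> frozenset:
    return frozenset(_clades(topo)[1])


# ---------------------------------------------------------------------------
# tree rearrangement

def _insert_everywhere(rest, sub):
    yield (rest, sub)
    if not isinstance(rest, int):
        l, r = rest
        for nl in _insert_everywhere(l, sub):
            yield (nl, r)
        for nr in _insert_everywhere(r, sub):
            yield (l, nr)


def _prune_options(tree):
    """All (pruned_subtree, remaining_tree) pairs for an ingroup topology."""
    if isinstance(tree, int):
        return []
    l, r = tree
    opts = [(l, r), (r, l)]
    for sub, rest in _prune_options(l):
        opts.append((sub, (rest, r)))
    for sub, rest in _prune_options(r):
        opts.append((sub, (l, rest)))
    return opts


def spr_neighbors(ingroup):
    """All subtree-prune-regraft neighbours of an ingroup topology (incl. NNI)."""
    seen = set()
    for sub, rest in _prune_options(ingroup):
        for cand in _insert_everywhere(rest, sub):
            if cand not in seen:
                seen.add(cand)
                yield cand


def _random_addition(matrix: CharacterMatrix, rng) -> tuple:
    """Greedy stepwise addition of ingroup taxa in random order."""
    order = list(rng.permutation(matrix.n_cells))
    planes = matrix.leaf_planes()
    full = (1 << matrix.n_chars) - 1
    og = matrix.outgroup_index
    ingroup = (int(order[0]), int(order[1])) if matrix.n_cells >= 2 else int(order[0])
    for t in order[2:]:
        best = None
        for cand in _insert_everywhere(ingroup, int(t)):
            s = _fitch((og, cand), planes, full)[2]
            if best is None or s < best[0]:
                best = (s, cand)
        ingroup = best[1]
    return ingroup


def _swap_to_optimum(ingroup, matrix: CharacterMatrix, plateau_cap: int = 100):
    """SPR hill-climb; returns (best_length, set of optimal ingroup topologies).

    After reaching a local optimum, a bounded breadth-first walk over
    equal-length neighbours collects the plateau of equally parsimonious
    topologies (cap *plateau_cap*).
    """
    planes = matrix.leaf_planes()
    full = (1 << matrix.n_chars) - 1
    og = matrix.outgroup_index

    def score(t):
        return _fitch((og, t), planes, full)[2]

    cur = ingroup
    cur_len = score(cur)
    improved = True
    while improved:
        improved = False
        for cand in spr_neighbors(cur):
            s = score(cand)
            if s < cur_len:
                cur, cur_len = cand, s
                improved = True
                break
    # plateau exploration at the local optimum
    best = {cur}
    frontier = [cur]
    while frontier and len(best) < plateau_cap:
        nxt = []
        for t in frontier:
            for cand in spr_neighbors(t):
                if cand in best:
                    continue
                if score(cand) == cur_len:
                    best.add(cand)
                    nxt.append(cand)
                    if len(best) >= plateau_cap:
                        break
            if len(best) >= plateau_cap:
                break
        frontier = nxt
    return cur_len, best


def strict_consensus(topologies, n_leaves: int) -> set[frozenset]:
    """Clades present in every rooted topology (including trivial ones)."""
    sets = None
    for topo in topologies:
        cl = set(_clades(topo)[1])
        cl |= {frozenset((i,)) for i in range(n_leaves)}
        sets = cl if sets is None else (sets & cl)
    return sets or set()


def heuristic_search(
    matrix: CharacterMatrix, n_ras: int = 100, seed: int = 0,
    plateau_cap: int = 100, keep_max: int = 10000,
) -> PaeResult:
    """Random-addition starts + SPR swapping, retaining all best topologies."""
    if matrix.n_cells < 3:
        raise ValueError("too few taxa")
    rng = np.random.default_rng(seed)
    best_len = None
    best_topos: set = set()
    for _ in range(n_ras):
        start = _random_addition(matrix, rng)
        length, topos = _swap_to_optimum(start, matrix, plateau_cap)
        if best_len is None or length < best_len:
            best_len = length
            best_topos = set(topos)
        elif length == best_len:
            best_topos |= topos
        if len(best_topos) > keep_max:
            best_topos = set(list(best_topos)[:keep_max])
    og = matrix.outgroup_index
    # deduplicate by unordered clade signature
    by_sig = {}
    for t in best_topos:
        by_sig.setdefault(topology_signature((og, t)), t)
    trees = [PaeTree((og, t), best_len) for t in by_sig.values()]
    clades = strict_consensus([t.topology for t in trees], matrix.n_leaves)
    return PaeResult(trees, int(best_len), clades, matrix)


@dataclass
class SupportedClade:
    cells: frozenset  # leaf indices
    cell_labels: list[str]
    characters: list[str]


def supported_clades(result: PaeResult, matrix: CharacterMatrix | None = None) -> list[SupportedClade]:
    """Strict-consensus clades backed by >= 1 non-homoplastic presence.

    A supporting character has its presences in exactly the clade's cells and
    needs exactly one step on every shortest tree (a unique, unreversed
    occurrence pattern).
    """
    matrix = matrix or result.matrix
    presence_sets = {
        j: frozenset(int(i) for i in np.nonzero(matrix.data[:, j])[0])
        for j in range(matrix.n_chars)
    }
    out = []
    ingroup_all = frozenset(range(matrix.n_cells))
    for clade in result.consensus_clades:
        if len(clade) < 2 or clade == ingroup_all or matrix.outgroup_index in clade:
            continue
        chars = []
        for j, pres in presence_sets.items():
            if pres != clade:
                continue
            if all(
                character_steps(t.topology, matrix, j) == 1
                for t in result.shortest_trees
            ):
                chars.append(matrix.char_names[j])
        if chars:
            out.append(
                SupportedClade(
                    cells=clade,
                    cell_labels=[matrix.cell_labels[i] for i in sorted(clade)],
                    characters=chars,
                )
            )
    out.sort(key=lambda c: sorted(c.cells))
    return out


# ---------------------------------------------------------------------------
# constrained search

def _groups_monophyletic(ingroup, groups: list[frozenset]) -> bool:
    clades = set(_clades(ingroup)[1])
    all_leaves = _leaf_set(ingroup)
    for g in groups:
        if len(g) <= 1 or g == all_leaves or not (g <= all_leaves):
            continue
        if g not in clades:
            return False
    return True


def _random_join(members: list[int], rng) -> tuple:
    nodes = [int(m) for m in members]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append((a, b))
    return nodes[0]


def constrained_search(
    matrix: CharacterMatrix, groups: dict, seed: int = 0, n_ras: int = 20,
    best_length: int | None = None, plateau_cap: int = 20,
) -> ConstrainedSearchResult:
    """Search restricted to trees where each cell group is monophyletic.

    *groups* maps a name to a list of cell row indices; groups must not
    overlap. Starts are built with each group as an unbreakable unit, then SPR
    moves that break a group's monophyly are rejected. ``extra_steps`` is the
    cost of the constraints relative to the unconstrained best length (found
    here if not supplied).
    """
    glists = {k: [int(i) for i in v] for k, v in groups.items()}
    seen: set[int] = set()
    for k, v in glists.items():
        if not v:
            raise ValueError(f"group {k!r} is empty")
        if seen & set(v):
            raise ValueError("contradictory constraints: overlapping groups")
        seen |= set(v)
    gsets = [frozenset(v) for v in glists.values()]

    rng = np.random.default_rng(seed)
    planes = matrix.leaf_planes()
    full = (1 << matrix.n_chars) - 1
    og = matrix.outgroup_index

    def score(t):
        return _fitch((og, t), planes, full)[2]

    free = [i for i in range(matrix.n_cells) if i not in seen]
    best_ct = None
    best_clen = None
    for _ in range(n_ras):
        units = [_random_join(v, rng) for v in glists.values()] + free
        order = rng.permutation(len(units))
        tree = units[order[0]] if len(units) == 1 else (units[order[0]], units[order[1]])
        for u in order[2:]:
            cands = [
                c for c in _insert_everywhere(tree, units[u])
                if _groups_monophyletic(c, gsets)
            ]
            tree = min(cands, key=score)
        cur, cur_len = tree, score(tree)
        improved = True
        while improved:
            improved = False
            for cand in spr_neighbors(cur):
                if not _groups_monophyletic(cand, gsets):
                    continue
                s = score(cand)
                if s < cur_len:
                    cur, cur_len = cand, s
                    improved = True
                    break
        if best_clen is None or cur_len < best_clen:
            best_clen, best_ct = cur_len, cur

    if best_length is None:
        best_length = heuristic_search(matrix, n_ras=n_ras, seed=seed,
                                       plateau_cap=plateau_cap).best_length
    # a constrained tree is also a valid unconstrained tree
    best_length = min(best_length, best_clen)
    return ConstrainedSearchResult(
        constrained_length=int(best_clen),
        best_length=int(best_length),
        constrained_trees=[PaeTree((og, best_ct), int(best_clen))],
    )


# ---------------------------------------------------------------------------
# export

def to_newick(topo: tuple, matrix: CharacterMatrix) -> str:
    labels = matrix.cell_labels + ["OUTGROUP"]

    def rec(node):
        if isinstance(node, int):
            return labels[node]
        return f"({rec(node[0])},{rec(node[1])})"

    return rec(topo) + ";"


def consensus_to_newick(clades: set[frozenset], matrix: CharacterMatrix) -> str:
    """Build a (possibly polytomous) newick tree from compatible clades."""
    labels = matrix.cell_labels + ["OUTGROUP"]
    ingroup = frozenset(range(matrix.n_cells))
    inner = sorted(
        (c for c in clades if 1 < len(c) <= len(ingroup) and matrix.outgroup_index not in c),
        key=len,
    )

    def expand(members: frozenset, available: list[frozenset]) -> str:
        chosen = []
        covered: set[int] = set()
        for c in sorted(available, key=len, reverse=True):
            if c < members and not (covered & set(c)):
                chosen.append(c)
                covered |= set(c)
        parts = [
            expand(c, [x for x in available if x < c]) for c in chosen
        ] + [labels[i] for i in sorted(members - covered)]
        return "(" + ",".join(parts) + ")"

    return f"({labels[matrix.outgroup_index]},{expand(ingroup, inner)});"
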