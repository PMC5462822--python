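import numpy as np
import pytest

from endemap.core_data import GridSpec, PresenceAbsenceMatrix
from endemap.pae import (
    CharacterMatrix,
    PaeTree,
    build_character_matrix,
    character_steps,
    constrained_search,
    fitch_length,
    heuristic_search,
    supported_clades,
    to_newick,
)

from oracles import all_rooted_topologies, exhaustive_min_length, fitch_steps_naive


def matrix_from(rows):
    """CharacterMatrix from ingroup rows (outgroup row appended here)."""
    rows = np.asarray(rows, dtype=np.uint8)
    data = np.vstack([rows, np.zeros((1, rows.shape[1]), np.uint8)])
    return CharacterMatrix(
        [f"c{i}" for i in range(rows.shape[0])],
        [f"ch{j}" for j in range(rows.shape[1])],
        data,
        rows.sum(axis=0) <= 1,
    )


def pam_from_rows(rows, counts=20):
    rows = np.asarray(rows, dtype=np.uint8)
    g = GridSpec(0, 0, float(rows.shape[0]), 1.0, 1.0)
    return PresenceAbsenceMatrix(
        g, [f"s{j}" for j in range(rows.shape[1])], np.arange(rows.shape[0]),
        rows, np.full(rows.shape[0], counts),
    )


class TestCharacterMatrix:
    def test_outgroup_all_absent_and_pruning(self):
        rows = [[1, 0, 1], [0, 1, 1], [1, 1, 1]]
        cm = build_character_matrix(pam_from_rows(rows))
        assert cm.pruned_chars == ["s2"]  # present in every cell
        assert (cm.data[-1] == 0).all()
        assert cm.uninformative.tolist() == [False, False]

    def test_singletons_flagged(self):
        rows = [[1, 1], [0, 1], [1, 0]]
        cm = build_character_matrix(pam_from_rows(rows))
        assert cm.uninformative.tolist() == [False, False]
        rows = [[1, 0, 1], [0, 1, 1], [0, 0, 1]]
        cm = build_character_matrix(pam_from_rows(rows))
        assert cm.pruned_chars == ["s2"]  # all-present column dropped
        assert cm.uninformative.tolist() == [True, True]

    def test_too_few_cells(self):
        with pytest.raises(ValueError, match="too few taxa"):
            build_character_matrix(pam_from_rows([[1], [1]]))


class TestFitch:
    def test_single_clade_character_one_step(self):
        m = matrix_from([[1], [1], [0], [0]])
        topo = (4, ((0, 1), (2, 3)))
        assert fitch_length(topo, m) == 1

    def test_split_character_two_steps_hand_checked(self):
        # presences on opposite sides of a balanced 4-leaf tree
        m = matrix_from([[1], [0], [1], [0]])
        topo = (4, ((0, 1), (2, 3)))
        states = {0: 1, 1: 0, 2: 1, 3: 0, 4: 0}
        assert fitch_steps_naive(topo, states) == 2  # oracle
        assert fitch_length(topo, m) == 2

    def test_all_zero_character_zero_steps(self):
        m = matrix_from([[0], [0], [0]])
        assert fitch_length((3, ((0, 1), 2)), m) == 0

    def test_invariance_to_character_order(self):
        rng = np.random.default_rng(0)
        rows = (rng.random((5, 12)) < 0.5).astype(np.uint8)
        m1 = matrix_from(rows)
        m2 = matrix_from(rows[:, ::-1])
        topo = (5, (((0, 1), 2), (3, 4)))
        assert fitch_length(topo, m1) == fitch_length(topo, m2)

    def test_matches_naive_oracle_on_random_trees(self):
        rng = np.random.default_rng(1)
        rows = (rng.random((6, 10)) < 0.4).astype(np.uint8)
        m = matrix_from(rows)
        data = np.vstack([rows, np.zeros((1, 10), np.uint8)])
        for topo in all_rooted_topologies(list(range(7)))[::97]:
            expect = sum(
                fitch_steps_naive(topo, {i: int(data[i, j]) for i in range(7)})
                for j in range(10)
            )
            assert fitch_length(topo, m) == expect

    def test_leaf_mismatch_rejected(self):
        m = matrix_from([[1], [0], [1]])
        with pytest.raises(ValueError, match="leaf set"):
            fitch_length((3, (0, 1)), m)


class TestHeuristicSearch:
    def test_perfect_hierarchy_single_tree(self):
        rows = np.array(
            [[1, 1, 0], [1, 1, 0], [0, 1, 0], [0, 0, 1], [0, 0, 1]], np.uint8
        )
        m = matrix_from(rows)
        res = heuristic_search(m, n_ras=10, seed=0)
        assert res.best_length == m.n_chars
        assert len(res.shortest_trees) == 1
        clades = {frozenset(c) for c in res.consensus_clades}
        assert frozenset({0, 1}) in clades and frozenset({3, 4}) in clades

    def test_determinism(self):
        rng = np.random.default_rng(2)
        rows = (rng.random((7, 15)) < 0.4).astype(np.uint8)
        m = matrix_from(rows)
        r1 = heuristic_search(m, n_ras=5, seed=9)
        r2 = heuristic_search(m, n_ras=5, seed=9)
        assert r1.best_length == r2.best_length
        assert {to_newick(t.topology, m) for t in r1.shortest_trees} == {
            to_newick(t.topology, m) for t in r2.shortest_trees
        }

    def test_matches_exhaustive_on_small_instances(self):
        rng = np.random.default_rng(5)
        hits = 0
        for rep in range(20):
            rows = (rng.random((6, 20)) < 0.4).astype(np.uint8)
            m = matrix_from(rows)
            data = np.vstack([rows, np.zeros((1, 20), np.uint8)])
            exact = exhaustive_min_length(data)
            res = heuristic_search(m, n_ras=5, seed=rep, plateau_cap=10)
            hits += res.best_length == exact
        assert hits >= 19


class TestSupportedClades:
    def test_coincident_character_supports_clade(self):
        rows = np.array([[1, 1], [1, 1], [0, 1], [0, 0]], np.uint8)
        # char0 = {c0,c1}; char1 = {c0,c1,c2}
        m = matrix_from(rows)
        res = heuristic_search(m, n_ras=10, seed=0)
        sup = supported_clades(res)
        by_cells = {tuple(sorted(c.cells)): c.characters for c in sup}
        assert by_cells.get((0, 1)) == ["ch0"]
        assert by_cells.get((0, 1, 2)) == ["ch1"]

    def test_homoplastic_character_not_support(self):
        # char with presences {c0, c2} that no shortest tree groups cleanly
        rows = np.array(
            [[1, 1, 0], [1, 0, 0], [0, 1, 1], [0, 0, 1]], np.uint8
        )
        m = matrix_from(rows)
        res = heuristic_search(m, n_ras=10, seed=0)
        for clade in supported_clades(res):
            for ch in clade.characters:
                j = m.char_names.index(ch)
                for t in res.shortest_trees:
                    assert character_steps(t.topology, m, j) == 1


class TestPlantedAreaRecovery:
    def test_supported_clades_sit_inside_planted_polygons(self):
        """Gridding the planted-areas preset at two degrees, the clades backed
        by non-homoplastic species occurrences fall inside the planted
        polygons (>= 2 of the 3 polygons recovered)."""
        from shapely.geometry import box as sbox

        from endemap.core_data import build_presence_matrix, records_from_dataframe
        from endemap.synthetic import generate_preset, scenario_presets

        df, _ = generate_preset("three_aoes")
        grid = GridSpec(-70, -15, -50, 5, 2.0)
        pam = build_presence_matrix(records_from_dataframe(df), grid)
        cm = build_character_matrix(pam)
        res = heuristic_search(cm, n_ras=1, seed=0, plateau_cap=5)
        clades = supported_clades(res)
        assert clades, "no supported clades found"

        lon, lat = grid.cell_centroid(np.asarray(pam.cells))
        half = grid.cell_size / 2
        poly_cells = []
        for p in scenario_presets()["three_aoes"].planted_aoes:
            poly_cells.append(frozenset(
                k for k, (lo, la) in enumerate(zip(lon, lat))
                if sbox(lo - half, la - half, lo + half, la + half)
                .intersection(p.polygon).area > 1e-9
            ))
        recovered = {
            i
            for c in clades
            for i, pc in enumerate(poly_cells)
            if frozenset(c.cells) <= pc
        }
        assert len(recovered) >= 2


class TestConstrainedSearch:
    def _matrix(self, seed=1):
        rng = np.random.default_rng(seed)
        rows = (rng.random((6, 20)) < 0.4).astype(np.uint8)
        return matrix_from(rows)

    def test_own_clades_cost_nothing(self):
        m = self._matrix()
        res = heuristic_search(m, n_ras=10, seed=0)
        topo = res.shortest_trees[0].topology[1]
        # take one nontrivial clade of the best tree as the constraint
        from endemap.pae import _clades

        clade = next(
            c for c in _clades(topo)[1] if 1 < len(c) < 6
        )
        cs = constrained_search(
            m, {"g": sorted(clade)}, seed=0, n_ras=10, best_length=res.best_length
        )
        assert cs.extra_steps == 0

    def test_vacuous_constraint(self):
        m = self._matrix()
        cs = constrained_search(m, {"all": list(range(6))}, seed=0, n_ras=5)
        assert cs.extra_steps == 0

    def test_forced_grouping_costs_steps(self):
        # two blocks of perfectly coherent cells; forcing one cell from each
        # block together must lengthen the tree
        rows = np.zeros((6, 12), np.uint8)
        rows[:3, :6] = 1
        rows[3:, 6:] = 1
        rows[0, 11] = 1  # mild noise
        m = matrix_from(rows)
        base = heuristic_search(m, n_ras=10, seed=0)
        data = m.data
        exact = exhaustive_min_length(data)
        assert base.best_length == exact
        cs = constrained_search(
            m, {"bad": [0, 3]}, seed=0, n_ras=10, best_length=base.best_length
        )
        assert cs.extra_steps > 0

    def test_overlapping_groups_rejected(self):
        m = self._matrix()
        with pytest.raises(ValueError, match="overlapping"):
            constrained_search(m, {"a": [0, 1], "b": [1, 2]}, seed=0)

    def test_constrained_trees_satisfy_constraint(self):
        m = self._matrix(seed=3)
        cs = constrained_search(m, {"g": [1, 2, 4]}, seed=0, n_ras=5)
        from endemap.pae import _clades

        topo = cs.constrained_trees[0].topology[1]
        assert frozenset({1, 2, 4}) in set(_clades(topo)[1])
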