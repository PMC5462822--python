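import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from endemap.composition import (
    DissimilarityMatrix,
    OrdinaryKriging,
    bray_curtis_matrix,
    cell_adjacency_weights,
    krige_axis,
    morans_i,
    nmds,
    partition_beta,
    rgb_composite,
)
from endemap.core_data import GridSpec, PresenceAbsenceMatrix
from endemap.raster import KernelSurface, RasterGeometry

from conftest import random_pam
from oracles import beta_pair


def pam_from_sets(cell_sets, n_taxa):
    g = GridSpec(0, 0, float(len(cell_sets)), 1.0, 1.0)
    m = np.zeros((len(cell_sets), n_taxa), dtype=np.uint8)
    for i, s in enumerate(cell_sets):
        m[i, list(s)] = 1
    return PresenceAbsenceMatrix(
        g, [f"t{j}" for j in range(n_taxa)], np.arange(len(cell_sets)), m,
        np.full(len(cell_sets), 20),
    )


class TestBrayCurtis:
    @pytest.mark.parametrize(
        "s1,s2,expect",
        [
            ({0, 1}, {0, 1}, 0.0),  # identical
            ({0, 1}, {2, 3}, 1.0),  # disjoint
            ({0, 1}, {1, 2}, 0.5),  # {A,B} vs {B,C}
        ],
    )
    def test_known_pairs(self, s1, s2, expect):
        d = bray_curtis_matrix(pam_from_sets([s1, s2], 4)).d
        assert d[0, 1] == pytest.approx(expect)

    def test_matches_scipy_on_binary(self):
        rng = np.random.default_rng(0)
        pam = random_pam(rng)
        ours = bray_curtis_matrix(pam).d
        ref = squareform(pdist(pam.matrix.astype(float), "braycurtis"))
        assert np.allclose(ours, ref)


class TestBetaPartition:
    def test_nested_pair_pure_nestedness(self):
        pam = pam_from_sets([{0, 1, 2, 3}, {1, 2}], 4)
        turn, nest = partition_beta(pam)
        total = bray_curtis_matrix(pam).d
        assert turn.d[0, 1] == 0.0
        assert nest.d[0, 1] == pytest.approx(total[0, 1])

    def test_hand_evaluated_case(self):
        # a=2 shared, b=1 unique to cell1, c=3 unique to cell2
        s1 = {0, 1, 2}
        s2 = {0, 1, 3, 4, 5}
        expect = beta_pair(s1, s2)
        assert expect == (pytest.approx(0.5), pytest.approx(1 / 3), pytest.approx(1 / 6))
        pam = pam_from_sets([s1, s2], 6)
        turn, nest = partition_beta(pam)
        total = bray_curtis_matrix(pam).d
        assert (total[0, 1], turn.d[0, 1], nest.d[0, 1]) == (
            pytest.approx(expect[0]), pytest.approx(expect[1]), pytest.approx(expect[2]),
        )

    def test_additive_identity_random(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            pam = random_pam(rng, n_cells=10, n_taxa=15)
            total = bray_curtis_matrix(pam).d
            turn, nest = partition_beta(pam)
            assert np.abs(total - (turn.d + nest.d)).max() < 1e-12


class TestNmds:
    def test_exact_embeddable_configuration(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 1, (15, 2))
        d = squareform(pdist(pts))
        res = nmds(DissimilarityMatrix(np.arange(15), d, "total"), k=2, n_starts=10, seed=0)
        assert res.stress <= 1e-3
        assert res.nonmetric_R2 == 1.0 - res.stress**2
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-8)

    def test_stress_monotone_in_k(self):
        rng = np.random.default_rng(3)
        d = squareform(pdist(rng.uniform(0, 1, (15, 4))))
        dm = DissimilarityMatrix(np.arange(15), d, "total")
        s2 = nmds(dm, k=2, n_starts=10, seed=0).stress
        s3 = nmds(dm, k=3, n_starts=10, seed=0).stress
        assert s3 <= s2 + 1e-9

    def test_too_few_cells(self):
        d = np.zeros((3, 3))
        with pytest.raises(ValueError, match="at least"):
            nmds(DissimilarityMatrix(np.arange(3), d, "total"), k=3)


class TestMoransI:
    def test_checkerboard_rook_is_minus_one(self):
        g = GridSpec(0, 0, 6, 6, 1.0)
        pam = PresenceAbsenceMatrix(
            g, ["a"], np.arange(36), np.ones((36, 1), np.uint8), np.ones(36)
        )
        w = cell_adjacency_weights(pam, "rook")
        vals = (np.indices((6, 6)).sum(axis=0) % 2).ravel().astype(float)
        res = morans_i(vals, w, n_perm=99, seed=0)
        assert res.I == pytest.approx(-1.0, abs=1e-12)
        assert res.expected_I == pytest.approx(-1.0 / 35)

    def test_smooth_gradient_positive_and_significant(self):
        g = GridSpec(0, 0, 8, 8, 1.0)
        pam = PresenceAbsenceMatrix(
            g, ["a"], np.arange(64), np.ones((64, 1), np.uint8), np.ones(64)
        )
        w = cell_adjacency_weights(pam, "queen")
        vals = np.repeat(np.arange(8.0), 8) + 0.01 * np.random.default_rng(0).standard_normal(64)
        res = morans_i(vals, w, n_perm=999, seed=0)
        assert res.I > 0.5
        assert res.p_value <= 0.001 + 1e-9

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            morans_i(np.ones(9), np.eye(9), n_perm=9)


class TestKriging:
    def _data(self, n=25, seed=0):
        rng = np.random.default_rng(seed)
        coords = np.column_stack([rng.uniform(-5, 5, n), rng.uniform(-5, 5, n)])
        z = np.sin(coords[:, 0]) + np.cos(coords[:, 1]) + 0.05 * rng.standard_normal(n)
        return coords, z

    def test_exact_at_data_points(self):
        coords, z = self._data()
        ok = OrdinaryKriging(coords, z)
        pred, var = ok.predict(coords[:, 0], coords[:, 1])
        assert np.abs(pred - z).max() < 1e-6
        assert np.abs(var[np.arange(len(z))]).max() < 1e-6

    def test_constant_field(self):
        coords, _ = self._data()
        kr = krige_axis(coords, np.full(len(coords), 3.25), RasterGeometry(-5, -5, 5, 5, 0.5))
        assert np.allclose(kr.prediction.values, 3.25, atol=1e-8)

    def test_far_prediction_tends_to_mean(self):
        """Beyond the variogram range the predictor settles at a single value
        (the kriging mean), close to the sample mean for unstructured data."""
        rng = np.random.default_rng(5)
        coords = np.column_stack([rng.uniform(-1, 1, 40), rng.uniform(-1, 1, 40)])
        z = rng.standard_normal(40)  # spatially unstructured
        ok = OrdinaryKriging(coords, z)
        pred, _ = ok.predict([120.0, -150.0], [60.0, -70.0])
        assert pred[0] == pytest.approx(pred[1], abs=1e-6)
        assert pred[0] == pytest.approx(z.mean(), abs=0.05 * z.std())

    def test_variance_surface_nonnegative(self):
        coords, z = self._data()
        kr = krige_axis(coords, z, RasterGeometry(-5, -5, 5, 5, 0.5))
        assert (kr.variance.values >= 0).all()

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 10"):
            OrdinaryKriging(np.zeros((5, 2)), np.zeros(5))


class TestRgbComposite:
    def _surfaces(self):
        g = RasterGeometry(0, 0, 1, 1, 0.25)
        rng = np.random.default_rng(0)
        return [KernelSurface(g, rng.random((4, 4))) for _ in range(3)]

    def test_permuting_axes_permutes_bands(self):
        s1, s2, s3 = self._surfaces()
        a = rgb_composite(s1, s2, s3)
        b = rgb_composite(s3, s1, s2)
        assert (a[..., 0] == b[..., 1]).all()
        assert (a[..., 1] == b[..., 2]).all()

    def test_constant_band_maps_to_midgray(self):
        s1, s2, s3 = self._surfaces()
        const = s3.copy_with(np.full_like(s3.values, 5.0))
        with pytest.warns(UserWarning, match="constant axis"):
            img = rgb_composite(s1, s2, const)
        assert (img[..., 2] == 128).all()

    def test_range_is_0_255(self):
        img = rgb_composite(*self._surfaces())
        assert img.dtype == np.uint8
        assert img.max() == 255 and img.min() == 0


class TestPipelineRecovery:
    def test_turnover_tracks_total_more_than_nestedness_on_river(self, one_river_pam):
        """A hard compositional break is replacement, not richness difference."""
        total = bray_curtis_matrix(one_river_pam).d
        turn, nest = partition_beta(one_river_pam)
        iu = np.triu_indices(total.shape[0], 1)
        r_turn = np.corrcoef(total[iu], turn.d[iu])[0, 1]
        r_nest = np.corrcoef(total[iu], nest.d[iu])[0, 1]
        assert r_turn > r_nest

    def test_kriged_axis1_break_sits_on_the_river(self):
        """On river-structured data the largest adjacent-cell difference in
        kriged axis-1 scores straddles the planted river (10 seeds, >= 8).

        Run at a two-degree grid to keep the repeated ordinations fast; the
        kriging predictor is exact at the cell centroids.
        """
        from endemap.core_data import build_presence_matrix, filter_cells_by_records, records_from_dataframe
        from endemap.synthetic import generate_preset

        grid = GridSpec(-70, -15, -50, 5, 2.0)
        successes = 0
        for seed in range(11, 21):
            df, _ = generate_preset("one_river", seed=seed)
            pam = filter_cells_by_records(
                build_presence_matrix(records_from_dataframe(df), grid), 10
            )
            d = bray_curtis_matrix(pam)
            scores = nmds(d, k=3, n_starts=2, seed=seed).scores
            cents = pam.cell_centroids()
            s1, _ = OrdinaryKriging(cents, scores[:, 0]).predict(cents[:, 0], cents[:, 1])
            rows, cols = np.divmod(np.asarray(pam.cells), grid.n_cols)
            adj = [
                (i, j)
                for i in range(pam.n_cells)
                for j in range(i + 1, pam.n_cells)
                if abs(rows[i] - rows[j]) + abs(cols[i] - cols[j]) == 1
            ]
            diffs = np.array([abs(s1[i] - s1[j]) for i, j in adj])
            i, j = adj[int(np.argmax(diffs))]
            successes += (cents[i, 0] < -60.0) != (cents[j, 0] < -60.0)
        assert successes >= 8

    def test_pipeline_determinism(self, one_river_pam):
        full = bray_curtis_matrix(one_river_pam)
        d = DissimilarityMatrix(full.cell_ids[:60], full.d[:60, :60], "total")
        r1 = nmds(d, k=2, n_starts=2, seed=5)
        r2 = nmds(d, k=2, n_starts=2, seed=5)
        assert np.array_equal(r1.scores, r2.scores)
        assert r1.stress == r2.stress
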