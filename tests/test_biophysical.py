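"""Biophysical network construction: SC, DC, GC pipeline pieces, RC, GCd/RCd."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr, spearmanr

from remnantnet.biophysical import (
    ExpressionBundle,
    ReceptorMaps,
    StreamlineCounts,
    assign_samples_to_regions,
    build_gc,
    dc_from_centroids,
    differential_stability,
    distance_correct,
    filter_probes_by_intensity,
    normalize_expression,
    region_gene_matrix,
    robust_sigmoid_rescale,
    sc_from_streamlines,
    select_probes,
    similarity_network,
    zscore_receptors,
)
from remnantnet.parcellation import Parcellation


def line_parcels(xs, volumes=None, hemi=None):
    n = len(xs)
    return Parcellation(
        region_id=tuple(range(n)),
        hemisphere=tuple(hemi) if hemi else ("L",) * n,
        centroid=np.column_stack([xs, np.zeros(n), np.zeros(n)]),
        volume=np.asarray(volumes if volumes is not None else [1.0] * n, float),
    )


class TestStructural:
    def test_direct_formula(self):
        T = np.array([[0.0, 10.0], [10.0, 0.0]])
        parcels = line_parcels([0.0, 1.0], volumes=[2.0, 3.0])
        sc = sc_from_streamlines(StreamlineCounts(T), parcels)
        assert sc.weights[0, 1] == pytest.approx(2.0)

    def test_zero_streamlines_zero_weight(self):
        T = np.zeros((3, 3))
        sc = sc_from_streamlines(
            StreamlineCounts(T), line_parcels([0.0, 1.0, 2.0])
        )
        assert not sc.weights.any()

    def test_matches_elementwise_oracle(self, rng):
        n = 6
        T = rng.integers(0, 30, (n, n)).astype(float)
        T = np.triu(T, 1)
        T = T + T.T
        v = rng.uniform(0.5, 3.0, n)
        parcels = line_parcels(np.arange(n, dtype=float), volumes=v)
        sc = sc_from_streamlines(StreamlineCounts(T), parcels)
        oracle = np.array(
            [[T[i, j] / (v[i] + v[j]) if i != j else 0.0 for j in range(n)]
             for i in range(n)]
        )
        np.testing.assert_allclose(sc.weights, oracle, atol=1e-14)


class TestProximity:
    def test_farthest_pair_gets_zero_nearest_gets_most(self):
        dc = dc_from_centroids(line_parcels([0.0, 3.0, 4.0]))
        assert dc.weights[0, 2] == pytest.approx(0.0)  # D = Dmax = 4
        assert dc.weights[1, 2] == pytest.approx(3.0)  # 4 - 1

    def test_proximity_plus_distance_is_dmax(self, rng):
        cent = rng.uniform(-50, 50, (7, 3))
        parcels = Parcellation(
            region_id=tuple(range(7)),
            hemisphere=("L",) * 7,
            centroid=cent,
            volume=np.ones(7),
        )
        dc = dc_from_centroids(parcels)
        D = parcels.distance_matrix()
        iu = np.triu_indices(7, 1)
        np.testing.assert_allclose(
            dc.weights[iu] + D[iu], D[iu].max(), atol=1e-10
        )

    def test_diagonal_forced_zero(self):
        dc = dc_from_centroids(line_parcels([0.0, 1.0, 5.0]))
        assert not np.diag(dc.weights).any()


class TestSimilarity:
    def test_identical_and_negated_rows(self):
        base = np.array([1.0, 2.0, 4.0, 3.0])
        X = np.vstack([base, base, -base])
        net = similarity_network(X, kind="RC")
        assert net.weights[0, 1] == pytest.approx(1.0)
        assert net.weights[0, 2] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self, rng):
        X = rng.standard_normal((5, 10))
        net = similarity_network(X, kind="GC")
        for i in range(5):
            for j in range(i + 1, 5):
                xc = X[i] - X[i].mean()
                yc = X[j] - X[j].mean()
                r = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
                assert net.weights[i, j] == pytest.approx(r, abs=1e-12)

    def test_constant_row_names_region(self):
        X = np.vstack([np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="'regA'"):
            similarity_network(X, kind="RC", region_id=["regA", "regB"])


class TestReceptors:
    def test_zscore_column(self):
        maps = ReceptorMaps(pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 0.0, 1.0]}))
        z = zscore_receptors(maps).densities
        np.testing.assert_allclose(z["a"], [-np.sqrt(1.5), 0, np.sqrt(1.5)])
        np.testing.assert_allclose(z.mean(), 0, atol=1e-12)
        np.testing.assert_allclose(z.std(ddof=0), 1, atol=1e-12)

    def test_zscore_idempotent_and_zero_variance_error(self, rng):
        maps = ReceptorMaps(pd.DataFrame(rng.standard_normal((8, 3))))
        once = zscore_receptors(maps)
        twice = zscore_receptors(once)
        np.testing.assert_allclose(
            once.densities.to_numpy(), twice.densities.to_numpy(), atol=1e-12
        )
        flat = ReceptorMaps(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]}))
        with pytest.raises(ValueError, match="zero variance"):
            zscore_receptors(flat)


def toy_bundle(above, intensities=None, donors=("d1",), sample_donor=None, xyz=None):
    above = np.asarray(above, bool)
    p, m = above.shape
    return ExpressionBundle(
        donors=tuple(donors),
        sample_donor=np.asarray(
            sample_donor if sample_donor is not None else [donors[0]] * m
        ),
        sample_xyz=np.asarray(xyz if xyz is not None else np.zeros((m, 3)), float),
        intensities=np.asarray(
            intensities if intensities is not None else np.ones((p, m)), float
        ),
        probe_gene=tuple(f"g{i}" for i in range(p)),
        above_background=above,
    )


class TestProbeFiltering:
    def test_boundary_cases(self):
        # probe 0: below background 6/10 -> discarded; probe 1: 4/10 -> kept
        above = np.vstack([
            np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], bool),
            np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0], bool),
        ])
        out = filter_probes_by_intensity(toy_bundle(above), frac=0.5)
        assert out.probe_gene == ("g1",)

    def test_hand_enumerated_survivors(self):
        rates_below = [0.0, 0.2, 0.5, 0.8, 0.4]  # frac >= 0.5 discarded
        above = np.array([
            [False] * int(r * 10) + [True] * (10 - int(r * 10))
            for r in rates_below
        ])
        out = filter_probes_by_intensity(toy_bundle(above), frac=0.5)
        assert out.probe_gene == ("g0", "g1", "g4")

    def test_all_discarded_errors(self):
        with pytest.raises(ValueError, match="every probe"):
            filter_probes_by_intensity(toy_bundle(np.zeros((2, 4), bool)))


class TestDifferentialStability:
    def _bundle_two_donors(self, profile_a, profile_b):
        k = len(profile_a)
        inten = np.concatenate([profile_a, profile_b])[None, :]
        return toy_bundle(
            np.ones((1, 2 * k), bool),
            intensities=inten,
            donors=("d1", "d2"),
            sample_donor=["d1"] * k + ["d2"] * k,
        ), np.array(list(range(k)) * 2)

    def test_rank_identical_profiles(self):
        b, regions = self._bundle_two_donors([1, 2, 3, 4], [10, 20, 30, 40])
        assert differential_stability(b, regions).iloc[0] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        b, regions = self._bundle_two_donors([1, 2, 3, 4], [40, 30, 20, 10])
        assert differential_stability(b, regions).iloc[0] == pytest.approx(-1.0)

    def test_three_donor_pairwise_oracle(self, rng):
        k, donors = 6, ("a", "b", "c")
        profiles = rng.standard_normal((3, k))
        inten = profiles.reshape(1, -1)
        b = toy_bundle(
            np.ones((1, 3 * k), bool),
            intensities=inten,
            donors=donors,
            sample_donor=[d for d in donors for _ in range(k)],
        )
        regions = np.array(list(range(k)) * 3)
        got = differential_stability(b, regions).iloc[0]
        rhos = [
            spearmanr(profiles[i], profiles[j]).statistic
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        assert got == pytest.approx(np.mean(rhos), abs=1e-12)

    def test_select_probes_keeps_max_delta_sp(self):
        # two probes for the same gene: one rank-stable, one anti-stable
        inten = np.array([
            [1, 2, 3, 4, 10, 20, 30, 40],
            [1, 2, 3, 4, 40, 30, 20, 10],
        ], float)
        b = toy_bundle(
            np.ones((2, 8), bool),
            intensities=inten,
            donors=("d1", "d2"),
            sample_donor=["d1"] * 4 + ["d2"] * 4,
        )
        b = ExpressionBundle(
            donors=b.donors, sample_donor=b.sample_donor, sample_xyz=b.sample_xyz,
            intensities=b.intensities, probe_gene=("gene", "gene"),
            above_background=b.above_background,
        )
        regions = np.array(list(range(4)) * 2)
        ds = differential_stability(b, regions)
        kept = select_probes(b, ds)
        assert kept.n_probes == 1
        np.testing.assert_array_equal(kept.intensities[0], inten[0])


class TestRobustSigmoid:
    def test_bounds_and_order(self, rng):
        x = rng.standard_normal(50)
        y = robust_sigmoid_rescale(x)
        assert y.min() == 0.0 and y.max() == 1.0
        assert spearmanr(x, y).statistic == pytest.approx(1.0)

    def test_median_maps_to_sigmoid_midpoint(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = robust_sigmoid_rescale(x)
        # the median's pre-rescale value is exactly 0.5, so after min-max
        # rescaling it sits at (0.5 - min) / (max - min) of the sigmoid values
        med_idx = 2
        assert y[med_idx] == pytest.approx(0.5, abs=0.05)
        assert y[0] == 0.0 and y[-1] == 1.0

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="distinct"):
            robust_sigmoid_rescale(np.ones(5))

    def test_normalize_expression_shape_and_bounds(self, rng):
        X = rng.lognormal(size=(6, 9))
        Y = normalize_expression(X)
        assert Y.shape == X.shape
        assert Y.min() >= 0 and Y.max() <= 1


class TestSampleAssignment:
    def test_within_and_outside_radius(self):
        parcels = line_parcels([0.0, 20.0, 40.0, 60.0])
        xyz = np.array([[1.0, 0, 0], [100.0, 0, 0]])
        b = toy_bundle(np.ones((1, 2), bool), xyz=xyz)
        region, src = assign_samples_to_regions(b, parcels, radius_mm=2, mirror=False)
        assert region.tolist() == [0, -1]

    def test_exhaustive_distance_oracle(self, rng):
        parcels = line_parcels([0.0, 10.0, 20.0, 30.0])
        xyz = rng.uniform(-5, 35, (6, 1))
        xyz = np.column_stack([xyz, np.zeros((6, 2))])
        b = toy_bundle(np.ones((2, 6), bool), xyz=xyz)
        region, _ = assign_samples_to_regions(b, parcels, radius_mm=3, mirror=False)
        for s in range(6):
            dists = [abs(xyz[s, 0] - c) for c in [0, 10, 20, 30]]
            want = int(np.argmin(dists)) if min(dists) <= 3 else -1
            assert region[s] == want

    def test_mirroring_duplicates_reflected(self):
        parcels = line_parcels([-10.0, 10.0], hemi=["L", "R"])
        xyz = np.array([[9.5, 0, 0]])
        b = toy_bundle(np.ones((1, 1), bool), xyz=xyz)
        region, src = assign_samples_to_regions(b, parcels, radius_mm=2, mirror=True)
        # original lands on the right region, the mirror on the left
        assert sorted(region.tolist()) == [0, 1]
        assert src.tolist() == [0, 0]

    def test_region_gene_matrix_donor_then_cross_donor_mean(self):
        # two donors, one region: within-donor means first, then their mean
        inten = np.array([[1.0, 3.0, 10.0]])
        b = toy_bundle(
            np.ones((1, 3), bool), intensities=inten,
            donors=("d1", "d2"), sample_donor=["d1", "d1", "d2"],
        )
        expr = region_gene_matrix(b, np.zeros(3, int), np.arange(3), 1)
        assert expr[0, 0] == pytest.approx((2.0 + 10.0) / 2)


class TestDistanceCorrection:
    def _net(self, parcels, weights):
        from remnantnet.network import WeightedNetwork

        return WeightedNetwork(weights, kind="GC", signed=True)

    def test_linear_in_distance_vanishes(self, rng):
        parcels = line_parcels(sorted(rng.uniform(0, 50, 6)))
        D = parcels.distance_matrix()
        w = 0.5 - 0.01 * D
        np.fill_diagonal(w, 0.0)
        resid = distance_correct(self._net(parcels, w), parcels)
        assert np.abs(resid.weights[np.triu_indices(6, 1)]).max() < 1e-10

    def test_residuals_orthogonal_to_distance(self, rng):
        parcels = line_parcels(sorted(rng.uniform(0, 50, 8)))
        w = np.triu(rng.standard_normal((8, 8)), 1)
        w = w + w.T
        resid = distance_correct(self._net(parcels, w), parcels)
        iu = np.triu_indices(8, 1)
        r = pearsonr(resid.weights[iu], parcels.distance_matrix()[iu]).statistic
        assert abs(r) < 1e-10

    def test_uncorrelated_weights_mean_centered(self, rng):
        # slope ~ 0 when weights ignore distance: residual = w - mean(w)
        parcels = line_parcels([0.0, 1.0, 2.0, 3.0])
        D = parcels.distance_matrix()
        iu = np.triu_indices(4, 1)
        # craft weights with exactly zero sample covariance with distance
        d = D[iu]
        w_vals = np.array([1.0, -1.0, 0.5, -0.5, 0.3, -0.3])
        w_vals = w_vals - np.polyfit(d, w_vals, 1)[0] * d  # kill the slope
        w = np.zeros((4, 4))
        w[iu] = w_vals
        w = w + w.T
        resid = distance_correct(self._net(parcels, w), parcels)
        np.testing.assert_allclose(
            resid.weights[iu], w_vals - w_vals.mean(), atol=1e-12
        )


def test_build_gc_end_to_end():
    rng = np.random.default_rng(5)
    centers = np.array([[-15.0, 0, 0], [-5.0, 0, 0], [5.0, 0, 0], [15.0, 0, 0]])
    parcels = Parcellation(
        region_id=("L1", "L0", "R0", "R1"),
        hemisphere=("L", "L", "R", "R"),
        centroid=centers,
        volume=np.ones(4) * 100,
    )
    n_probes, n_samp = 6, 16
    xyz = centers[rng.integers(0, 4, n_samp)] + rng.normal(0, 0.5, (n_samp, 3))
    donors = ("d1", "d2")
    bundle = ExpressionBundle(
        donors=donors,
        sample_donor=np.array([donors[i % 2] for i in range(n_samp)]),
        sample_xyz=xyz,
        intensities=rng.lognormal(size=(n_probes, n_samp)),
        probe_gene=("gA", "gA", "gB", "gC", "gD", "gE"),
        above_background=np.ones((n_probes, n_samp), bool),
    )
    gc = build_gc(bundle, parcels, radius_mm=3.0)
    assert gc.kind == "GC"
    assert gc.n == 4
    iu = np.triu_indices(4, 1)
    assert np.all(np.abs(gc.weights[iu]) <= 1 + 1e-12)
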