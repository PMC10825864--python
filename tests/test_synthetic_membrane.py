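"""Receptor-field generators: geometry, point-process statistics, disruption."""

import numpy as np
import pytest
from scipy.stats import binomtest, ks_2samp

from aieclust import (
    CellFootprint,
    ClusterParams,
    DisruptionParams,
    ReceptorField,
    apply_disruption,
    disruption_probability,
    nearest_neighbor_distances,
    sample_cell_footprint,
    sample_receptors_clustered,
    sample_receptors_csr,
)
from aieclust.synthetic_membrane import _uniform_in_footprint

from conftest import brute_force_nn, ray_cast_inside, segments_intersect


class TestFootprint:
    def test_zero_irregularity_is_a_circle(self):
        fp = sample_cell_footprint(0, mean_radius=5000.0, irregularity=0.0)
        assert fp.area == pytest.approx(np.pi * 5000.0**2, rel=0.01)
        w, h = fp.bounding_box
        assert w == pytest.approx(10000.0, rel=0.01)
        assert h == pytest.approx(10000.0, rel=0.01)

    def test_same_seed_gives_identical_polygon(self):
        a = sample_cell_footprint(42, irregularity=0.3)
        b = sample_cell_footprint(42, irregularity=0.3)
        np.testing.assert_array_equal(a.boundary, b.boundary)

    def test_polygons_are_simple_for_many_seeds(self):
        # brute-force segment-intersection oracle over 100 seeds
        for seed in range(100):
            ring = sample_cell_footprint(seed, irregularity=0.3).boundary
            n = len(ring)
            edges = [(ring[i], ring[(i + 1) % n]) for i in range(n)]
            for i in range(n):
                for j in range(i + 2, n):
                    if i == 0 and j == n - 1:
                        continue  # adjacent via wrap-around
                    assert not segments_intersect(*edges[i], *edges[j]), (
                        f"seed {seed}: edges {i} and {j} cross"
                    )

    def test_irregularity_one_rejected(self):
        with pytest.raises(ValueError):
            sample_cell_footprint(0, irregularity=1.0)
        with pytest.raises(ValueError):
            sample_cell_footprint(0, mean_radius=-1.0)


class TestCSR:
    def test_zero_intensity_gives_empty_field(self, circle_footprint):
        f = sample_receptors_csr(circle_footprint, 0.0, 5)
        assert len(f) == 0

    def test_mean_count_matches_poisson_expectation(self, circle_footprint):
        # lambda = 50 / um^2 on ~78.5 um^2; 200 replicates; hard-core losses
        # at h = 2 nm remove ~1 point per field, far below the 3 SE band
        lam = 50.0
        area_um2 = circle_footprint.area / 1e6
        counts = [len(sample_receptors_csr(circle_footprint, lam, s)) for s in range(200)]
        expected = lam * area_um2
        se = np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < 3 * se + 2.0

    def test_all_points_inside_polygon(self, bumpy_footprint):
        f = sample_receptors_csr(bumpy_footprint, 20.0, 11)
        assert ray_cast_inside(bumpy_footprint.boundary, f.positions).all()
        assert (f.cluster_id == -1).all()

    def test_negative_intensity_rejected(self, circle_footprint):
        with pytest.raises(ValueError):
            sample_receptors_csr(circle_footprint, -1.0, 0)


class TestClustered:
    def test_zero_parent_intensity_gives_empty_field(self, circle_footprint):
        p = ClusterParams(parent_intensity=0.0)
        assert len(sample_receptors_clustered(circle_footprint, p, 3)) == 0

    def test_mean_count_matches_thomas_expectation(self, circle_footprint):
        # kappa*mu*area, 3 SE band widened by 3% for edge-discard (~0.5%)
        # and in-cluster hard-core losses (~1%)
        p = ClusterParams(parent_intensity=0.5, mean_offspring=20.0, cluster_sd=30.0)
        area_um2 = circle_footprint.area / 1e6
        counts = [
            len(sample_receptors_clustered(circle_footprint, p, s)) for s in range(200)
        ]
        expected = p.parent_intensity * p.mean_offspring * area_um2
        var = p.parent_intensity * area_um2 * (p.mean_offspring + p.mean_offspring**2)
        se = np.sqrt(var / 200)
        assert expected - 3 * se - 0.03 * expected < np.mean(counts) < expected + 3 * se

    def test_points_inside_and_hardcore_respected(self, bumpy_footprint):
        p = ClusterParams()
        f = sample_receptors_clustered(bumpy_footprint, p, 8)
        assert ray_cast_inside(bumpy_footprint.boundary, f.positions).all()
        if len(f) >= 2:
            assert nearest_neighbor_distances(f).min() >= p.hardcore

    def test_clustered_nn_distances_smaller_than_csr(self, circle_footprint):
        # paired seeds, sign test at alpha = 0.01
        p = ClusterParams()
        lam = p.parent_intensity * p.mean_offspring
        wins = 0
        for s in range(20):
            fc = sample_receptors_clustered(circle_footprint, p, 100 + s)
            fr = sample_receptors_csr(circle_footprint, lam, 200 + s)
            wins += np.median(nearest_neighbor_distances(fc)) < np.median(
                nearest_neighbor_distances(fr)
            )
        assert binomtest(wins, 20, alternative="greater").pvalue < 0.01

    def test_same_seed_gives_identical_field(self, circle_footprint):
        p = ClusterParams()
        a = sample_receptors_clustered(circle_footprint, p, 77)
        b = sample_receptors_clustered(circle_footprint, p, 77)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.cluster_id, b.cluster_id)


class TestDisruption:
    def test_zero_dose_returns_field_unchanged(self, circle_footprint):
        f = sample_receptors_clustered(circle_footprint, ClusterParams(), 1)
        g = apply_disruption(f, 0.0, 24.0, DisruptionParams(), 2)
        np.testing.assert_array_equal(f.positions, g.positions)
        h = apply_disruption(f, 10.0, 0.0, DisruptionParams(), 2)
        np.testing.assert_array_equal(f.positions, h.positions)

    def test_count_conserved_for_any_dose_time(self, circle_footprint):
        f = sample_receptors_clustered(circle_footprint, ClusterParams(), 3)
        for dose, time in [(0.01, 2.0), (1.0, 8.0), (100.0, 24.0), (1e6, 1e6)]:
            g = apply_disruption(f, dose, time, DisruptionParams(), 4)
            assert len(g) == len(f)

    def test_negative_dose_or_time_rejected(self, circle_footprint):
        f = sample_receptors_clustered(circle_footprint, ClusterParams(), 5)
        with pytest.raises(ValueError):
            apply_disruption(f, -1.0, 2.0, DisruptionParams(), 0)
        with pytest.raises(ValueError):
            apply_disruption(f, 1.0, -2.0, DisruptionParams(), 0)

    def test_full_disruption_indistinguishable_from_csr(self):
        # p -> 1: NN-distance distribution vs fresh uniform placement of the
        # same count; KS at alpha = 0.01 over 20 fixed seeds. NN distances
        # within one field are weakly dependent, which inflates the KS
        # rejection rate slightly above alpha, hence the >= 18/20 bound.
        params = DisruptionParams(p_max=1.0)
        npass = 0
        for s in range(20):
            fp = sample_cell_footprint(s)
            f = sample_receptors_clustered(fp, ClusterParams(), 1000 + s)
            d = apply_disruption(f, 1e6, 1e6, params, 2000 + s)
            assert (d.cluster_id == -1).all()
            fresh = _uniform_in_footprint(fp, len(d), np.random.default_rng(3000 + s))
            p = ks_2samp(
                nearest_neighbor_distances(d.positions),
                nearest_neighbor_distances(fresh),
            ).pvalue
            npass += p > 0.01
        assert npass >= 18

    def test_disrupted_fraction_monotone_in_dose_and_time(self):
        # expected clustered fraction non-increasing in dose and time
        params = DisruptionParams(p_max=0.8, ec50=1.0, time_scale=8.0)
        doses = [0.0, 1.0, 10.0, 100.0]
        times = [2.0, 8.0, 24.0]
        frac = np.zeros((len(doses), len(times)))
        for i, dose in enumerate(doses):
            for j, time in enumerate(times):
                vals = []
                for r in range(50):
                    fp = sample_cell_footprint(r, mean_radius=3000.0)
                    f = sample_receptors_clustered(fp, ClusterParams(), 10_000 + r)
                    g = apply_disruption(f, dose, time, params, 20_000 + 100 * i + 10 * j + r)
                    vals.append(np.mean(g.cluster_id != -1))
                frac[i, j] = np.mean(vals)
        assert (np.diff(frac, axis=0) <= 0).all()  # dose direction
        assert (np.diff(frac, axis=1) <= 0).all()  # time direction

    def test_probability_formula_endpoints(self):
        params = DisruptionParams(p_max=0.8, ec50=1.0, hill=1.0, time_scale=8.0)
        assert disruption_probability(0.0, 24.0, params) == 0.0
        assert disruption_probability(1.0, 1e9, params) == pytest.approx(0.4)
        assert disruption_probability(1e12, 1e9, params) == pytest.approx(0.8, rel=1e-6)


class TestNearestNeighbor:
    def test_two_points(self, circle_footprint):
        f = ReceptorField(
            positions=[[100.0, 100.0], [150.0, 100.0]],
            cluster_id=[-1, -1],
            footprint=circle_footprint,
        )
        np.testing.assert_allclose(nearest_neighbor_distances(f), [50.0, 50.0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        pos = rng.uniform(0, 5000, size=(300, 2))
        np.testing.assert_allclose(nearest_neighbor_distances(pos), brute_force_nn(pos))

    def test_duplicate_point_has_zero_distance(self):
        pos = np.array([[0.0, 0.0], [100.0, 0.0], [100.0, 0.0]])
        d = nearest_neighbor_distances(pos)
        assert d[1] == 0.0 and d[2] == 0.0

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            nearest_neighbor_distances(np.array([[0.0, 0.0]]))


class TestSerialization:
    def test_csv_round_trip_lossless(self, tmp_path, bumpy_footprint):
        f = sample_receptors_clustered(bumpy_footprint, ClusterParams(), 55)
        path = tmp_path / "field.csv"
        f.to_csv(path)
        g = ReceptorField.from_csv(path, bumpy_footprint)
        np.testing.assert_array_equal(f.positions, g.positions)
        np.testing.assert_array_equal(f.cluster_id, g.cluster_id)
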