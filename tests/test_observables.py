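"""Shape and distribution observables: profiles, enrichment, uniformity."""

import numpy as np
import pytest

from memtube.mesh import build_cylinder
from memtube.observables import (
    ENRICHMENT_MAX,
    circular_ks_statistic,
    enrichment,
    largest_cluster_fraction,
    min_radius,
    protein_axial_density,
    radius_profile,
    uniformity_test,
)


@pytest.fixture(scope="module")
def cylinder():
    return build_cylinder(10.0, 100.0, seed=3)


class TestRadiusProfile:
    def test_uniform_cylinder_flat_profile(self, cylinder):
        prof = radius_profile(cylinder, n_bins=25)
        assert prof.counts.sum() == cylinder.n_vertices
        assert np.all(np.abs(prof.mean_radius - 10.0) < 0.2)

    def test_constructed_waist_shows_up(self, cylinder):
        m = cylinder.copy()
        z = m.positions[:, 2] % m.box_length
        band = np.abs(z - 50.0) < 5.0
        r = np.linalg.norm(m.positions[band, :2], axis=1)
        m.positions[band, :2] *= (3.0 / r)[:, None]
        prof = radius_profile(m, n_bins=25)
        val, where = min_radius(prof)
        assert val == pytest.approx(3.0, abs=0.1)
        assert abs(where - 50.0) < 4.0

    def test_translation_shifts_bins_correspondingly(self, cylinder):
        m = cylinder.copy()
        n_bins = 20
        before = radius_profile(m, n_bins).mean_radius
        m.positions[:, 2] = (m.positions[:, 2] + 50.0) % m.box_length
        after = radius_profile(m, n_bins).mean_radius
        assert np.allclose(np.roll(before, n_bins // 2), after, atol=1e-9)

    def test_min_radius_monotone_in_waist_depth(self, cylinder):
        vals = []
        for target in (8.0, 6.0, 4.0):
            m = cylinder.copy()
            z = m.positions[:, 2] % m.box_length
            band = np.abs(z - 50.0) < 5.0
            r = np.linalg.norm(m.positions[band, :2], axis=1)
            m.positions[band, :2] *= (target / r)[:, None]
            vals.append(min_radius(radius_profile(m, 25))[0])
        assert vals[0] > vals[1] > vals[2]

    def test_needs_two_bins(self, cylinder):
        with pytest.raises(ValueError):
            radius_profile(cylinder, n_bins=1)


class TestAxialDensity:
    def test_counts_conserved_and_normalised(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(0, 40.0, 57)
        dens = protein_axial_density(z, 40.0, n_bins=8)
        assert dens.counts.sum() == 57
        width = 40.0 / 8
        assert np.sum(dens.density * width) == pytest.approx(1.0)

    def test_point_mass_occupies_one_bin(self):
        dens = protein_axial_density(np.full(9, 13.3), 40.0, n_bins=10)
        assert (dens.counts > 0).sum() == 1

    def test_exact_grid_is_flat(self):
        z = (np.arange(40) + 0.5) * 1.0
        dens = protein_axial_density(z, 40.0, n_bins=8)
        assert np.all(dens.counts == 5)


class TestEnrichment:
    def test_uniform_is_unity(self):
        z = (np.arange(100) + 0.5) * 0.4
        dens = protein_axial_density(z, 40.0, n_bins=10)
        assert enrichment(dens, (16.0, 24.0)) == pytest.approx(1.0)

    def test_everything_in_band_returns_sentinel(self):
        dens = protein_axial_density(np.full(20, 20.0), 40.0, n_bins=10)
        assert enrichment(dens, (16.0, 24.0)) == ENRICHMENT_MAX

    def test_whole_box_band_rejected(self):
        dens = protein_axial_density(np.arange(10.0), 40.0, n_bins=10)
        with pytest.raises(ValueError):
            enrichment(dens, (0.0, 40.0))

    def test_recovers_generating_intensity(self):
        # 3x intensity inside the central fifth of the box, N = 600
        rng = np.random.default_rng(5)
        L, band = 100.0, (40.0, 60.0)
        n_in = rng.binomial(600, 3.0 / 7.0)  # 3*w / (3*w + rest)
        z = np.concatenate([
            rng.uniform(*band, n_in),
            (rng.uniform(0, 80.0, 600 - n_in) + 60.0) % L,
        ])
        dens = protein_axial_density(z, L, n_bins=10)
        est = enrichment(dens, band)
        assert abs(est - 3.0) < 0.45  # ~3 binomial standard errors

    def test_converges_to_unity_for_large_uniform_samples(self):
        rng = np.random.default_rng(6)
        z = rng.uniform(0, 40.0, 1000)
        dens = protein_axial_density(z, 40.0, n_bins=10)
        assert abs(enrichment(dens, (16.0, 24.0)) - 1.0) < 0.25


def _protein_cloud(centres):
    """(N,5,3) sphere stacks: five coincident spheres per protein."""
    c = np.asarray(centres, dtype=float)
    return np.repeat(c[:, None, :], 5, axis=1)


class TestClusterFraction:
    def test_isolated_proteins(self):
        sph = _protein_cloud([[0, 0, 0], [50, 0, 0], [0, 50, 0], [50, 50, 0]])
        assert largest_cluster_fraction(sph, 4.8) == pytest.approx(0.25)

    def test_touching_chain_is_one_cluster(self):
        sph = _protein_cloud([[4.0 * i, 0, 0] for i in range(6)])
        assert largest_cluster_fraction(sph, 4.8) == 1.0

    def test_three_and_seven_gives_point_seven(self):
        a = [[4.0 * i, 0, 0] for i in range(7)]
        b = [[4.0 * i, 500, 0] for i in range(3)]
        assert largest_cluster_fraction(_protein_cloud(a + b), 4.8) == 0.7

    def test_periodic_wrap_joins_clusters(self):
        sph = _protein_cloud([[0, 0, 1.0], [0, 0, 39.0]])
        assert largest_cluster_fraction(sph, 4.8, box_length=40.0) == 1.0
        assert largest_cluster_fraction(sph, 4.8) == 0.5

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            largest_cluster_fraction(np.zeros((0, 5, 3)), 4.8)


class TestUniformity:
    def test_perfect_grid_statistic_is_one_over_n(self):
        n = 20
        z = (np.arange(n) + 0.3) / n * 40.0
        stat = circular_ks_statistic(z, 40.0)
        assert stat == pytest.approx(1.0 / n, abs=1e-12)

    def test_grid_not_rejected_point_mass_rejected(self):
        n = 20
        grid = (np.arange(n) + 0.3) / n * 40.0
        _, p_grid = uniformity_test(grid, 40.0)
        _, p_point = uniformity_test(np.full(n, 7.0) + 1e-9 * np.arange(n),
                                     40.0)
        assert p_grid > 0.5
        assert p_point < 1e-3

    def test_rotation_invariance(self):
        rng = np.random.default_rng(7)
        z = rng.uniform(0, 40.0, 24)
        s0 = circular_ks_statistic(z, 40.0)
        s1 = circular_ks_statistic((z + 17.3) % 40.0, 40.0)
        assert s0 == pytest.approx(s1, abs=1e-12)

    def test_type_one_error_calibrated(self):
        # simulated uniform samples of n = 20: rejection rate at alpha = 0.05
        # within 3 binomial standard errors of nominal
        rng = np.random.default_rng(8)
        n_rep = 10_000
        rejections = 0
        ps = np.empty(n_rep)
        for i in range(n_rep):
            _, p = uniformity_test(rng.uniform(0, 1.0, 20), 1.0)
            ps[i] = p
        alpha = 0.05
        rate = np.mean(ps < alpha)
        se = np.sqrt(alpha * (1 - alpha) / n_rep)
        assert abs(rate - alpha) < 3 * se + 1e-3
        assert abs(ps.mean() - 0.5) < 0.02

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            uniformity_test(np.arange(3.0), 10.0)
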