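"""Hamiltonian terms against independent oracles and printed parameters."""

import numpy as np
import pytest

from memtube.energy import (
    EnergyParams,
    adhesion_energy,
    area_energy,
    bending_energy,
    constriction_energy,
    flex_energy,
    total_energy,
)
from memtube.mesh import TriMesh, build_cylinder, surface_area
from memtube.proteins import Protein, ProteinParams, sphere_centres


def brute_force_dihedral_sum(mesh):
    """Slow, from-scratch dihedral summation (the bending-energy oracle)."""
    total = 0.0
    for e in range(mesh.n_edges):
        t1, t2 = mesh.edge_tri[e]
        ns = []
        for t in (t1, t2):
            a, b, c = mesh.triangles[t]
            d1 = mesh.minimum_image(mesh.positions[b] - mesh.positions[a])
            d2 = mesh.minimum_image(mesh.positions[c] - mesh.positions[a])
            n = np.cross(d1, d2)
            ns.append(n / np.linalg.norm(n))
        total += 1.0 - float(np.dot(ns[0], ns[1]))
    return total


class TestBending:
    def test_planar_patch_has_zero_energy(self):
        # open 2-triangle strip in the plane
        m = TriMesh(
            positions=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 0]]),
            triangles=np.array([[0, 1, 2], [2, 1, 3]]),
            box_length=100.0,
            nominal_radius=1.0,
        )
        assert bending_energy(m, 20.0) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_fold_costs_kappa(self):
        # fold the second triangle up by 90 degrees: 1 - n1.n2 = 1
        m = TriMesh(
            positions=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [1, 1, 1]]),
            triangles=np.array([[0, 1, 2], [2, 1, 3]]),
            box_length=100.0,
            nominal_radius=1.0,
        )
        # place vertex 3 so the fold is exactly orthogonal
        m.positions[3] = [1.0, 0.0, 1.0]
        assert bending_energy(m, 20.0) == pytest.approx(20.0, abs=1e-9)

    def test_matches_brute_force_on_tube(self, small_tube):
        kappa = 20.0
        expected = kappa * brute_force_dihedral_sum(small_tube)
        assert bending_energy(small_tube, kappa) == pytest.approx(
            expected, abs=1e-9)

    def test_study_tube_within_factor_two_of_continuum(self, paper_tube):
        continuum = np.pi * 20.0 * 100.0 / 10.0  # pi kappa L / R = 200 pi
        u = bending_energy(paper_tube, 20.0)
        assert 0.5 * continuum < u < 2.0 * continuum

    def test_nonnegative_and_zero_only_when_flat(self, small_tube):
        assert bending_energy(small_tube, 20.0) > 0.0


class TestAreaTerm:
    def test_reference_area_gives_zero(self, small_tube):
        A = surface_area(small_tube)
        assert area_energy(small_tube, 1.0, A) == pytest.approx(0.0)

    def test_unit_excess_area_costs_gamma(self, small_tube):
        A = surface_area(small_tube)
        assert area_energy(small_tube, 1.0, A - 1.0) == pytest.approx(1.0)

    def test_linear_in_excess(self, small_tube):
        A = surface_area(small_tube)
        u1 = area_energy(small_tube, 1.0, A - 2.0)
        u2 = area_energy(small_tube, 1.0, A - 4.0)
        assert u2 == pytest.approx(2.0 * u1)


def _one_bead_mesh(bead, box=1000.0):
    return TriMesh(
        positions=np.array([bead, bead + [500.0, 0, 0], bead + [500.0, 1, 0]]),
        triangles=np.array([[0, 1, 2]]),
        box_length=box,
        nominal_radius=1.0,
    )


class TestAdhesion:
    def test_contact_pair_costs_minus_epsilon(self):
        # a tight cone isolates the middle sphere's contribution
        pp = ProteinParams(theta_pr=0.1)
        ep = EnergyParams()
        p = Protein(centre=np.zeros(3))
        c = sphere_centres(p, pp)[2]
        d_min = ep.d_min(pp)
        mesh = _one_bead_mesh(c + np.array([d_min, 0.0, 0.0]))
        u = adhesion_energy([p], mesh, 3.8, pp, ep.r_cut(pp))
        assert u == pytest.approx(-3.8, abs=1e-9)

    def test_double_distance_costs_epsilon_over_64(self):
        pp = ProteinParams(theta_pr=0.1)
        ep = EnergyParams()
        p = Protein(centre=np.zeros(3))
        c = sphere_centres(p, pp)[2]
        mesh = _one_bead_mesh(c + np.array([2.0 * ep.d_min(pp), 0.0, 0.0]))
        u = adhesion_energy([p], mesh, 3.8, pp, ep.r_cut(pp))
        assert u == pytest.approx(-3.8 / 64.0, abs=1e-9)

    def test_beyond_cutoff_or_convex_side_contributes_zero(self):
        pp = ProteinParams(theta_pr=0.1)
        ep = EnergyParams()
        p = Protein(centre=np.zeros(3))
        c = sphere_centres(p, pp)[2]
        far = _one_bead_mesh(c + np.array([ep.r_cut(pp) + 0.5, 0.0, 0.0]))
        assert adhesion_energy([p], far, 3.8, pp, ep.r_cut(pp)) == 0.0
        convex = _one_bead_mesh(c - np.array([ep.d_min(pp), 0.0, 0.0]))
        assert adhesion_energy([p], convex, 3.8, pp, ep.r_cut(pp)) == 0.0

    def test_hard_core_configuration_raises(self):
        pp = ProteinParams()
        ep = EnergyParams()
        p = Protein(centre=np.zeros(3))
        c = sphere_centres(p, pp)[2]
        mesh = _one_bead_mesh(c + np.array([0.5 * ep.d_min(pp), 0.0, 0.0]))
        with pytest.raises(ValueError):
            adhesion_energy([p], mesh, 3.8, pp, ep.r_cut(pp))

    def test_always_attractive(self, thermalised_state):
        st = thermalised_state
        u = adhesion_energy(st.proteins, st.mesh, st.eparams.eps, st.pparams,
                            st.eparams.r_cut(st.pparams))
        assert u <= 0.0


class TestFlexAndConstriction:
    def test_equilibrium_angle_costs_nothing(self):
        p = Protein(centre=np.zeros(3), wing_angle=2 * np.pi / 3)
        assert flex_energy(p, 20.0, 2 * np.pi / 3) == 0.0

    def test_tenth_radian_costs_tenth_kt(self):
        p = Protein(centre=np.zeros(3), wing_angle=2 * np.pi / 3 + 0.1)
        assert flex_energy(p, 20.0, 2 * np.pi / 3) == pytest.approx(0.1)

    def test_symmetric_about_equilibrium(self):
        for d in (0.05, 0.2, 0.5):
            up = Protein(centre=np.zeros(3), wing_angle=2 * np.pi / 3 + d)
            dn = Protein(centre=np.zeros(3), wing_angle=2 * np.pi / 3 - d)
            assert flex_energy(up, 20.0, 2 * np.pi / 3) == pytest.approx(
                flex_energy(dn, 20.0, 2 * np.pi / 3))

    def test_band_at_target_radius_costs_nothing(self):
        m = build_cylinder(3.0, 30.0, seed=1, jitter=0.0)
        assert constriction_energy(m, 0.01, 3.0) == pytest.approx(0.0, abs=1e-6)

    def test_single_displaced_vertex(self):
        m = build_cylinder(3.0, 30.0, seed=1, jitter=0.0)
        v = int(np.argmin(np.abs(m.positions[:, 2] % 30.0 - 15.0)))
        r = np.linalg.norm(m.positions[v, :2])
        m.positions[v, :2] *= 10.0 / r
        expected = 0.5 * 0.01 * (10.0 - 3.0) ** 2
        assert constriction_energy(m, 0.01, 3.0) == pytest.approx(
            expected, abs=1e-9)

    def test_disabled_potential_is_zero(self, paper_tube):
        assert constriction_energy(paper_tube, 0.0, 3.0) == 0.0


class TestTotalEnergy:
    def test_bare_cylinder_is_bending_only(self, small_tube):
        ep = EnergyParams(A_ref=surface_area(small_tube))
        terms = total_energy(small_tube, [], ep, ProteinParams())
        assert terms["U_tot"] == pytest.approx(terms["U_bend"])
        assert terms["U_adh"] == 0.0 and terms["U_flex"] == 0.0

    def test_far_away_relaxed_protein_changes_nothing(self, small_tube):
        ep = EnergyParams(A_ref=surface_area(small_tube))
        pp = ProteinParams()
        base = total_energy(small_tube, [], ep, pp)
        far = Protein(centre=np.array([500.0, 0.0, 0.0]))
        with_p = total_energy(small_tube, [far], ep, pp)
        assert with_p["U_tot"] == pytest.approx(base["U_tot"], abs=1e-12)

    def test_total_is_sum_of_terms(self, thermalised_state):
        st = thermalised_state
        band = (st.band_frac[0] * st.box[0], st.band_frac[1] * st.box[0])
        ep = EnergyParams(A_ref=st.A_ref, k_cp=st.eparams.k_cp)
        terms = total_energy(st.mesh, st.proteins, ep, st.pparams, band)
        parts = sum(v for k, v in terms.items() if k != "U_tot")
        assert terms["U_tot"] == pytest.approx(parts, abs=1e-12)

    def test_invariant_under_rotation_about_axis(self, thermalised_state):
        st = thermalised_state
        ep = EnergyParams(A_ref=st.A_ref)
        before = total_energy(st.mesh, st.proteins, ep, st.pparams)
        c, s = np.cos(1.1), np.sin(1.1)
        R = np.array([[c, -s, 0], [s, c, 0], [0, 0, 1.0]])
        mesh = st.mesh.copy()
        mesh.positions[:] = mesh.positions @ R.T
        prots = [Protein(centre=R @ p.centre, orientation=R @ p.orientation,
                         wing_angle=p.wing_angle) for p in st.proteins]
        after = total_energy(mesh, prots, ep, st.pparams)
        for key in before:
            assert after[key] == pytest.approx(before[key], abs=1e-8), key


class TestUnits:
    def test_surface_tension_maps_to_printed_value(self):
        ep = EnergyParams()  # gamma = 1 kT/sigma^2, sigma = 20 nm
        assert ep.surface_tension_pN_per_nm() == pytest.approx(0.01, rel=0.05)

    def test_printed_defaults(self):
        ep = EnergyParams()
        assert (ep.kappa, ep.gamma, ep.eps) == (20.0, 1.0, 3.8)
        assert ep.k_flex == 20.0
        assert ep.theta_eq == pytest.approx(2 * np.pi / 3)
        assert ep.R_eq == 3.0
        assert ProteinParams().D_col == 4.0


class TestIncrementalConsistency:
    def test_cached_energy_tracks_full_recompute(self, small_state):
        # every move kind runs; the incremental deltas must track a full
        # recompute to float precision over many sweeps
        st = small_state
        for _ in range(5):
            st.sweep(10)
            assert st.energy_drift() < 1e-9

    def test_null_state_deltas(self, small_state):
        st = small_state
        before = st.energy_breakdown()
        st.sweep(0)
        assert st.energy_breakdown() == before
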