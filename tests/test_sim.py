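"""Bead-filament discretization and passive relaxation."""

import numpy as np
import pytest

from dynhelix.elastic import global_minimum
from dynhelix.helix import HelixShape, shape_to_curvature
from dynhelix.membrane import MembraneTube, equilibrium_radius
from dynhelix.sim import (
    BeadFilament,
    SimSystem,
    build_bead_helix,
    discrete_curvature,
    discrete_curvature_twist,
    discrete_twist,
    measure_shape,
    relax,
    system_energy,
)


class TestBuildBeadHelix:
    def test_two_start_phase_offset(self):
        strands = build_bead_helix(HelixShape(20.0, 20.0), n_start=2, n_beads=8)
        assert len(strands) == 2
        a0 = strands[0].positions_nm[0]
        b0 = strands[1].positions_nm[0]
        assert b0[2] == pytest.approx(a0[2])
        assert np.allclose(b0[:2], -a0[:2], atol=1e-12)  # 180 deg apart

    def test_planar_ring(self):
        (ring,) = build_bead_helix(HelixShape(15.0, 0.0), n_beads=6)
        assert np.allclose(ring.positions_nm[:, 2], 0.0)

    def test_bond_lengths_equal_spacing(self):
        (f,) = build_bead_helix(HelixShape(13.5, 20.0), n_beads=12, spacing_nm=5.6)
        np.testing.assert_allclose(f.bond_lengths(), 5.6, atol=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            build_bead_helix(HelixShape(13.5, 20.0), n_beads=3)
        with pytest.raises(ValueError):
            build_bead_helix(HelixShape(13.5, 20.0), spacing_nm=0.0)
        with pytest.raises(ValueError):
            BeadFilament(positions_nm=np.zeros((3, 3)))


class TestDiscreteGeometry:
    def test_circle_curvature(self):
        radius = 25.0
        (ring,) = build_bead_helix(HelixShape(radius, 0.0), n_beads=10, spacing_nm=radius / 5)
        kappa = discrete_curvature(ring)
        np.testing.assert_allclose(kappa, 1.0 / radius, rtol=1e-2)

    def test_straight_line(self):
        line = BeadFilament(
            positions_nm=np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)]),
            spacing_nm=1.0,
        )
        assert np.all(discrete_curvature(line) == 0.0)
        assert np.all(np.isnan(discrete_twist(line)))  # dihedral undefined

    def test_helix_matches_continuous_formulas(self):
        """Discrete (κ, τ) within 5% of r/(h²+r²), h/(h²+r²) at dimer spacing."""
        shape = HelixShape(13.5, 20.0)
        (f,) = build_bead_helix(shape, n_beads=30, spacing_nm=5.6)
        ct_c = shape_to_curvature(shape)
        assert np.allclose(discrete_curvature(f), ct_c.kappa, rtol=0.05)
        assert np.allclose(discrete_twist(f), ct_c.tau, rtol=0.05)

    def test_measure_shape_rigid_motion_invariant(self, rng):
        from scipy.spatial.transform import Rotation

        (f,) = build_bead_helix(HelixShape(13.5, 20.0), n_beads=16)
        s0 = measure_shape(f)
        rot = Rotation.random(random_state=7).as_matrix()
        moved = BeadFilament(
            positions_nm=f.positions_nm @ rot.T + np.array([5.0, -3.0, 11.0]),
            spacing_nm=f.spacing_nm,
        )
        s1 = measure_shape(moved)
        assert s1.radius_nm == pytest.approx(s0.radius_nm, rel=1e-9)
        assert s1.pitch_nm == pytest.approx(s0.pitch_nm, rel=1e-9)


class TestSystemEnergy:
    def test_spontaneous_free_filament_near_zero(self):
        r_star, p_star, _ = global_minimum()
        strands = build_bead_helix(HelixShape(r_star, p_star), n_beads=16)
        e = system_energy(SimSystem(filaments=strands))
        # discrete estimators at finite spacing leave a small residual
        assert e.filament_kjmol < 0.5
        assert e.bond_kjmol == pytest.approx(0.0, abs=1e-12)

    def test_breakdown_sums_to_total(self):
        strands = build_bead_helix(HelixShape(20.0, 20.0), n_start=2, n_beads=8)
        tube = MembraneTube.cylinder(20.0, 20.0, dz_nm=1.0)
        e = system_energy(SimSystem(filaments=strands, tube=tube))
        total = e.filament_kjmol + e.bond_kjmol + e.membrane_kjmol + e.coupling_kjmol
        assert e.total_kjmol == pytest.approx(total, rel=1e-12)

    def test_two_start_lower_than_one_start(self):
        """Same bead count: two strands at pitch 20 beat one strand at pitch 10."""
        two = build_bead_helix(HelixShape(20.0, 20.0), n_start=2, n_beads=10)
        one = build_bead_helix(HelixShape(20.0, 10.0), n_start=1, n_beads=20)
        e_two = system_energy(SimSystem(filaments=two)).filament_kjmol
        e_one = system_energy(SimSystem(filaments=one)).filament_kjmol
        assert e_two < e_one

    def test_empty_system_rejected(self):
        with pytest.raises(ValueError):
            SimSystem(filaments=[], tube=None)


class TestRelax:
    def test_free_filament_reaches_spontaneous_shape(self):
        strands = build_bead_helix(HelixShape(20.0, 20.0), n_beads=16)
        traj = relax(SimSystem(filaments=strands), max_steps=12000)
        shape = measure_shape(traj.final_system.filaments[0])
        r_star, p_star, _ = global_minimum()
        assert shape.radius_nm == pytest.approx(r_star, rel=0.02)
        assert shape.pitch_nm == pytest.approx(p_star, rel=0.02)

    def test_membrane_only_reaches_equilibrium(self):
        tube = MembraneTube.cylinder(24.0, 40.0, dz_nm=1.0)
        traj = relax(SimSystem(filaments=[], tube=tube), max_steps=30000)
        r_eq = equilibrium_radius()
        assert traj.final_system.tube.radius_nm.mean() == pytest.approx(r_eq, rel=0.01)

    def test_energies_non_increasing_and_steps_increase(self):
        strands = build_bead_helix(HelixShape(16.0, 25.0), n_beads=10)
        traj = relax(SimSystem(filaments=strands), max_steps=500)
        assert np.all(np.diff(traj.energy_array) <= 1e-12)
        assert np.all(np.diff(traj.steps) > 0)
        assert np.all(np.isfinite(traj.energy_array))

    def test_endpoint_near_stationary(self):
        strands = build_bead_helix(HelixShape(14.0, 40.0), n_beads=10)
        traj = relax(SimSystem(filaments=strands), max_steps=12000, grad_tol=1e-3)
        assert traj.final_grad_inf_norm < 1e-2

    def test_deterministic(self):
        def run():
            strands = build_bead_helix(HelixShape(16.0, 25.0), n_beads=8)
            return relax(SimSystem(filaments=strands, seed=3), max_steps=300)

        t1, t2 = run(), run()
        assert t1.energies_kjmol == t2.energies_kjmol
        np.testing.assert_array_equal(
            t1.final_system.filaments[0].positions_nm,
            t2.final_system.filaments[0].positions_nm,
        )

    def test_zero_coupling_decouples_filament_and_tube(self):
        strands = build_bead_helix(HelixShape(14.0, 30.0), n_beads=10)
        tube = MembraneTube.cylinder(22.0, 30.0, dz_nm=1.5)
        traj = relax(
            SimSystem(filaments=strands, tube=tube, k_coupling=0.0),
            max_steps=30000,
        )
        final = traj.final_system
        r_star, p_star, _ = global_minimum()
        shape = measure_shape(final.filaments[0])
        assert shape.radius_nm == pytest.approx(r_star, rel=0.03)
        assert final.tube.radius_nm.mean() == pytest.approx(equilibrium_radius(), rel=0.01)

    def test_coupled_two_start_constricts_tube(self):
        """Filament with 11.5 nm spontaneous radius pulls the 20 nm tube inward."""
        strands = build_bead_helix(HelixShape(20.0, 20.0), n_start=2, n_beads=10)
        tube = MembraneTube.cylinder(equilibrium_radius(), 20.0, dz_nm=1.0)
        traj = relax(SimSystem(filaments=strands, tube=tube), max_steps=4000)
        assert traj.final_system.tube.radius_nm.mean() < 20.0
        assert traj.energies_kjmol[-1] < traj.energies_kjmol[0]
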