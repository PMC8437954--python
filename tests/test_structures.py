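"""Superposition, hinge-angle and interface-conservation operators."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from dynhelix.fixtures import hinge_domain_definitions, make_helix_trace, make_two_domain_hinge
from dynhelix.helix import HelicalSymmetry
from dynhelix.structures import (
    AtomicStructure,
    DomainDefinition,
    RigidTransform,
    hinge_angle,
    interface_conservation,
    load_domains,
    read_structure,
    superpose,
    write_pdb,
)

DOM_A, DOM_B = hinge_domain_definitions(60)


def _rigidly_moved(s: AtomicStructure, seed: int) -> AtomicStructure:
    rot = Rotation.random(random_state=seed).as_matrix()
    t = RigidTransform(rotation=rot, translation=np.array([7.0, -13.0, 4.0]))
    return s.transformed(t)


class TestIO:
    def test_write_read_roundtrip(self, tmp_path):
        sym = HelicalSymmetry(rise_A=13.58, twist_deg=24.43, n_start=2, cyclic_order=2)
        trace = make_helix_trace(sym, radius_nm=13.5, n_subunits=10)
        path = tmp_path / "trace.pdb"
        write_pdb(trace, path)
        back = read_structure(path)
        assert len(back) == len(trace)
        assert sorted(back.chains) == sorted(trace.chains)
        # PDB coordinate precision is 1e-3 A
        np.testing.assert_allclose(back.xyz, trace.xyz, atol=1.5e-3)

    def test_malformed_file_raises(self, tmp_path):
        bad = tmp_path / "bad.pdb"
        bad.write_text("this is not a structure\n")
        with pytest.raises(ValueError):
            read_structure(bad)

    def test_default_domain_definitions_load(self):
        doms = load_domains()
        assert {"Gdomain", "BSE", "Stalk", "PH"} <= set(doms)
        assert doms["Gdomain"].contains([150]).all()
        assert not doms["Gdomain"].contains([400]).any()


class TestSuperpose:
    def test_identity(self):
        s, _, _ = make_two_domain_hinge(0.0, atoms_per_domain=50, seed=1)
        t, rmsd = superpose(s, s)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert t.angle_deg == pytest.approx(0.0, abs=1e-6)

    def test_recovers_known_rotation(self):
        s, _, _ = make_two_domain_hinge(0.0, atoms_per_domain=50, seed=2)
        rot = Rotation.from_euler("z", 30.0, degrees=True).as_matrix()
        moved = s.transformed(RigidTransform(rotation=rot, translation=np.zeros(3)))
        t, rmsd = superpose(moved, s)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert t.angle_deg == pytest.approx(30.0, abs=1e-6)

    def test_proper_rotation_on_near_planar_points(self, rng):
        """A mirrored near-planar cloud must not be matched by a reflection."""
        n = 40
        xyz = np.column_stack(
            [rng.uniform(-20, 20, n), rng.uniform(-20, 20, n), rng.normal(0, 0.01, n)]
        )
        ref = AtomicStructure(
            chain=["A"] * n, resnum=np.arange(1, n + 1), resname=["ALA"] * n,
            atom_name=["CA"] * n, element=["C"] * n, xyz=xyz,
        )
        mirrored = ref.select()
        mirrored.xyz = xyz * np.array([1.0, 1.0, -1.0])
        t, rmsd = superpose(mirrored, ref)
        assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_beats_random_search_oracle(self, rng):
        s1, s2, _ = make_two_domain_hinge(25.0, atoms_per_domain=30, seed=3)
        _, rmsd = superpose(s2, s1)
        for k in range(200):
            rot = Rotation.random(random_state=k).as_matrix()
            moved = s2.xyz @ rot.T
            moved = moved - moved.mean(axis=0) + s1.xyz.mean(axis=0)
            oracle = math.sqrt(((moved - s1.xyz) ** 2).sum(axis=1).mean())
            assert rmsd <= oracle + 1e-9

    def test_too_few_pairs(self):
        s, _, _ = make_two_domain_hinge(0.0, atoms_per_domain=50, seed=4)
        tiny = s.select(domain=DomainDefinition(name="t", ranges=((1, 2),)))
        with pytest.raises(ValueError):
            superpose(tiny, tiny)

    def test_shuffled_numbering_raises(self, rng):
        """Residue identity mismatch is an error, never a silent mispairing."""
        n = 30
        names = np.array(["ALA", "GLY", "SER", "VAL", "LEU"], dtype=object)
        s1 = AtomicStructure(
            chain=["A"] * n, resnum=np.arange(1, n + 1),
            resname=names[np.arange(n) % 5], atom_name=["CA"] * n,
            element=["C"] * n, xyz=rng.normal(size=(n, 3)) * 10,
        )
        s2 = s1.select()
        s2.resnum = rng.permutation(s2.resnum)
        with pytest.raises(ValueError, match="mismatch"):
            superpose(s2, s1)


class TestHingeAngle:
    @pytest.mark.parametrize("angle", [1.0, 12.0, 34.0, 46.0, 90.0, 135.0, 179.0])
    def test_noiseless_recovery(self, angle):
        s1, s2, _ = make_two_domain_hinge(angle, atoms_per_domain=60, seed=5)
        res = hinge_angle(s1, s2, align_domain=DOM_A, measure_domain=DOM_B)
        assert res.angle_deg == pytest.approx(angle, abs=0.1)
        assert res.align_rmsd_A == pytest.approx(0.0, abs=1e-9)

    def test_identical_structures_zero(self):
        s1, _, _ = make_two_domain_hinge(46.0, atoms_per_domain=60, seed=6)
        res = hinge_angle(s1, s1, align_domain=DOM_A, measure_domain=DOM_B)
        assert res.angle_deg == pytest.approx(0.0, abs=1e-9)

    def test_recovered_axis_matches_truth(self):
        s1, s2, truth = make_two_domain_hinge(46.0, atoms_per_domain=60, seed=7)
        res = hinge_angle(s1, s2, align_domain=DOM_A, measure_domain=DOM_B)
        cosang = abs(float(np.dot(res.axis, np.asarray(truth["axis"]))))
        assert cosang == pytest.approx(1.0, abs=1e-6)

    def test_global_rigid_motion_invariance(self):
        s1, s2, _ = make_two_domain_hinge(34.0, atoms_per_domain=60, seed=8)
        base = hinge_angle(s1, s2, align_domain=DOM_A, measure_domain=DOM_B)
        moved = hinge_angle(
            _rigidly_moved(s1, 11), _rigidly_moved(s2, 12),
            align_domain=DOM_A, measure_domain=DOM_B,
        )
        assert moved.angle_deg == pytest.approx(base.angle_deg, abs=1e-6)

    def test_noisy_recovery_within_one_degree(self):
        for seed in range(5):
            s1, s2, _ = make_two_domain_hinge(
                46.0, atoms_per_domain=60, noise_sigma_A=0.2, seed=seed
            )
            res = hinge_angle(s1, s2, align_domain=DOM_A, measure_domain=DOM_B)
            assert res.angle_deg == pytest.approx(46.0, abs=1.0)

    def test_missing_domain_named_in_error(self):
        s1, s2, _ = make_two_domain_hinge(12.0, atoms_per_domain=20, seed=9)
        absent = DomainDefinition(name="PH", ranges=((900, 950),))
        with pytest.raises(ValueError, match="PH"):
            hinge_angle(s1, s2, align_domain=absent, measure_domain=DOM_B)


def _two_chain_structure(seed: int = 0) -> AtomicStructure:
    # compact two-start trace (12 A from the axis) so the strands touch
    sym = HelicalSymmetry(rise_A=13.58, twist_deg=24.43, n_start=2, cyclic_order=2)
    return make_helix_trace(sym, radius_nm=1.2, n_subunits=12, seed=seed)


class TestInterfaceConservation:
    def test_identical_structures(self):
        s = _two_chain_structure()
        rep = interface_conservation(s, s, chain_pair_1=("A", "B"), cutoff_A=30.0)
        assert rep.jaccard == 1.0
        assert rep.interface_rmsd_A == pytest.approx(0.0, abs=1e-9)
        assert len(rep.contacts_1) > 0

    def test_separated_chain_gives_zero_jaccard(self):
        s1 = _two_chain_structure()
        s2 = s1.select()
        far = s2.chain == "B"
        s2.xyz = s2.xyz.copy()
        s2.xyz[far] += np.array([500.0, 0.0, 0.0])
        rep = interface_conservation(s1, s2, chain_pair_1=("A", "B"), cutoff_A=30.0)
        assert rep.jaccard == 0.0

    def test_empty_interface_reported_as_null(self):
        s1 = _two_chain_structure()
        s2 = s1.select()
        s1 = s1.select()
        for s in (s1, s2):
            far = s.chain == "B"
            s.xyz = s.xyz.copy()
            s.xyz[far] += np.array([500.0, 0.0, 0.0])
        rep = interface_conservation(s1, s2, chain_pair_1=("A", "B"), cutoff_A=10.0)
        assert rep.jaccard is None
        assert rep.contacts_1 == frozenset()

    def test_missing_chain_raises(self):
        s = _two_chain_structure()
        with pytest.raises(ValueError, match="chain"):
            interface_conservation(s, s, chain_pair_1=("A", "Z"))

    def test_invalid_cutoff(self):
        s = _two_chain_structure()
        with pytest.raises(ValueError):
            interface_conservation(s, s, chain_pair_1=("A", "B"), cutoff_A=0.0)
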