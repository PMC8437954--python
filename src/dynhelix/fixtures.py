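"""Synthetic test inputs: helical Cα traces, hinge pairs, perturbed filaments.

Every stochastic generator takes an explicit seed and echoes its full
generating specification (including the seed) into the fixture metadata,
so any fixture can be regenerated bit-identically from its metadata alone.
The decoys are geometric, not physical: random points in spheres stand in
for protein domains, and pseudo-Cα traces for helical subunit positions.
"""

from __future__ import annotations

import math
from dataclasses import asdict

import numpy as np

from .helix import HelicalSymmetry, HelixShape, lattice_points
from .membrane import MembraneTube
from .sim import BeadFilament, build_bead_helix
from .structures import AtomicStructure, RigidTransform

__all__ = [
    "make_helix_trace",
    "make_two_domain_hinge",
    "hinge_domain_definitions",
    "make_perturbed_filament",
    "make_tube_profile",
]

_CHAIN_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
NM_TO_A = 10.0


def make_helix_trace(
    sym: HelicalSymmetry,
    radius_nm: float,
    n_subunits: int,
    noise_sigma_A: float = 0.0,
    seed: int = 0,
) -> AtomicStructure:
    """Pseudo-atomic helical lattice: one Cα per subunit, one chain per strand.

    Coordinates in Å.  Optional isotropic Gaussian noise (σ in Å).
    """
    if noise_sigma_A < 0:
        raise ValueError("noise sigma must be >= 0")
    pts = lattice_points(sym, radius_nm, n_subunits)
    xyz = np.array([p.xyz_nm() for p in pts]) * NM_TO_A
    if noise_sigma_A > 0:
        rng = np.random.default_rng(seed)
        xyz = xyz + rng.normal(0.0, noise_sigma_A, size=xyz.shape)
    n = len(pts)
    return AtomicStructure(
        chain=np.array([_CHAIN_LETTERS[p.strand_index] for p in pts], dtype=object),
        resnum=np.array([p.subunit_index + 1 for p in pts]),
        resname=np.array(["ALA"] * n, dtype=object),
        atom_name=np.array(["CA"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        xyz=xyz,
        label="helix_trace",
        meta={
            "kind": "helix_trace",
            "symmetry": asdict(sym),
            "radius_nm": radius_nm,
            "n_subunits": n_subunits,
            "noise_sigma_A": noise_sigma_A,
            "seed": seed,
        },
    )


def _sphere_points(rng: np.random.Generator, n: int, center: np.ndarray, radius: float) -> np.ndarray:
    """Uniform points in a sphere (rejection-free: radius ∝ u^(1/3))."""
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    rad = radius * rng.random(n) ** (1.0 / 3.0)
    return center + direction * rad[:, None]


def _structure_from_points(xyz: np.ndarray, label: str, meta: dict) -> AtomicStructure:
    n = len(xyz)
    return AtomicStructure(
        chain=np.array(["A"] * n, dtype=object),
        resnum=np.arange(1, n + 1),
        resname=np.array(["ALA"] * n, dtype=object),
        atom_name=np.array(["CA"] * n, dtype=object),
        element=np.array(["C"] * n, dtype=object),
        xyz=xyz,
        label=label,
        meta=meta,
    )


def hinge_domain_definitions(atoms_per_domain: int = 100):
    """Domain definitions matching :func:`make_two_domain_hinge` numbering.

    Domain A covers residues 1..n, domain B residues n+1..2n.
    """
    from .structures import DomainDefinition

    n = atoms_per_domain
    return (
        DomainDefinition(name="domainA", ranges=((1, n),)),
        DomainDefinition(name="domainB", ranges=((n + 1, 2 * n),)),
    )


def make_two_domain_hinge(
    angle_deg: float,
    atoms_per_domain: int = 100,
    noise_sigma_A: float = 0.0,
    seed: int = 0,
) -> tuple[AtomicStructure, AtomicStructure, dict]:
    """Two-domain structure pair related by a known hinge rotation.

    Domain A (residues 1..n) is identical in both structures; domain B
    (residues n+1..2n) of the second structure is rotated by ``angle_deg``
    about a random axis through a hinge point between the domains.  Both
    domains are random points in 15 Å spheres whose centers are 40 Å apart.
    Independent Gaussian coordinate noise (σ in Å) may be added to each
    structure.  Returns (s1, s2, truth) where truth records the applied
    angle, axis and hinge point.
    """
    if not 0 <= angle_deg <= 180:
        raise ValueError("angle must be in [0, 180] degrees")
    if noise_sigma_A < 0:
        raise ValueError("noise sigma must be >= 0")
    rng = np.random.default_rng(seed)
    center_a = np.zeros(3)
    center_b = np.array([40.0, 0.0, 0.0])
    hinge_point = np.array([20.0, 0.0, 0.0])
    dom_a = _sphere_points(rng, atoms_per_domain, center_a, 15.0)
    dom_b = _sphere_points(rng, atoms_per_domain, center_b, 15.0)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)

    from scipy.spatial.transform import Rotation

    rot = Rotation.from_rotvec(math.radians(angle_deg) * axis).as_matrix()
    dom_b_rot = (dom_b - hinge_point) @ rot.T + hinge_point

    xyz1 = np.vstack([dom_a, dom_b])
    xyz2 = np.vstack([dom_a, dom_b_rot])
    if noise_sigma_A > 0:
        xyz1 = xyz1 + rng.normal(0.0, noise_sigma_A, size=xyz1.shape)
        xyz2 = xyz2 + rng.normal(0.0, noise_sigma_A, size=xyz2.shape)
    meta = {
        "kind": "two_domain_hinge",
        "angle_deg": angle_deg,
        "atoms_per_domain": atoms_per_domain,
        "noise_sigma_A": noise_sigma_A,
        "seed": seed,
    }
    truth = dict(meta, axis=axis.tolist(), hinge_point_A=hinge_point.tolist())
    s1 = _structure_from_points(xyz1, "hinge_ref", meta)
    s2 = _structure_from_points(xyz2, "hinge_rot", meta)
    return s1, s2, truth


def make_perturbed_filament(
    shape: HelixShape,
    n_start: int = 1,
    n_beads: int = 20,
    displacement_sigma_nm: float = 0.0,
    seed: int = 0,
    spacing_nm: float = 5.6,
) -> list[BeadFilament]:
    """Bead helix with isotropic Gaussian bead displacement (σ in nm)."""
    if displacement_sigma_nm < 0:
        raise ValueError("displacement sigma must be >= 0")
    strands = build_bead_helix(shape, n_start=n_start, n_beads=n_beads, spacing_nm=spacing_nm)
    if displacement_sigma_nm > 0:
        rng = np.random.default_rng(seed)
        for f in strands:
            f.positions_nm = f.positions_nm + rng.normal(
                0.0, displacement_sigma_nm, size=f.positions_nm.shape
            )
    return strands


def make_tube_profile(
    radius_nm: float = 20.0,
    length_nm: float = 100.0,
    amplitude_nm: float = 0.0,
    n_waves: int = 1,
    dz_nm: float = 0.5,
) -> MembraneTube:
    """Periodic tube profile: constant radius plus an optional sinusoid."""
    n = max(4, int(round(length_nm / dz_nm)))
    z = np.arange(n) * (length_nm / n)
    r = radius_nm + amplitude_nm * np.sin(2.0 * math.pi * n_waves * z / length_nm)
    return MembraneTube(z_nm=z, radius_nm=r)
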