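"""Coarse-grained relaxation of bead filaments on a deformable membrane tube.

The dynamin filament is an elastic polymer of beads, one bead per dimer
(target spacing 5.6 nm).  Discrete curvature at a bead is the Menger
curvature of it and its two neighbours; discrete twist density at a bond
is the dihedral angle between the two flanking bond planes divided by the
local bond arc length.  These feed the quadratic rod energy of
:mod:`dynhelix.elastic`.  The membrane is the axisymmetric Helfrich tube
of :mod:`dynhelix.membrane`, and beads are tied to the tube surface by a
soft radial harmonic.

Dynamics are passive: joint gradient descent (numerical central-difference
gradients, Barzilai–Borwein step with monotone backtracking) on bead
positions and the tube radius profile.  This captures the downhill,
curvature-driven part of constriction; the GTP-powered motor that drives
active sliding of the rungs is not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .elastic import FilamentElasticParams
from .helix import CurvatureTwist, HelixShape, curvature_to_shape
from .membrane import MembraneParams, MembraneTube, _profile_energy_batch

__all__ = [
    "BeadFilament",
    "SimSystem",
    "Trajectory",
    "EnergyBreakdown",
    "build_bead_helix",
    "discrete_curvature",
    "discrete_twist",
    "discrete_curvature_twist",
    "measure_shape",
    "system_energy",
    "relax",
]


@dataclass
class BeadFilament:
    """Ordered bead chain representing one filament strand.

    positions_nm : (n, 3) array; spacing_nm : target bond length
    (5.6 nm = one dynamin dimer along the filament contour).
    """

    positions_nm: np.ndarray
    strand_id: int = 0
    spacing_nm: float = 5.6

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_nm, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise ValueError("positions must be an (n, 3) array")
        if len(pos) < 4:
            raise ValueError("need at least 4 beads for discrete torsion")
        if self.spacing_nm <= 0:
            raise ValueError("spacing must be positive")
        self.positions_nm = pos

    @property
    def n_beads(self) -> int:
        return len(self.positions_nm)

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.positions_nm, axis=0), axis=-1)


def build_bead_helix(
    shape: HelixShape,
    n_start: int = 1,
    n_beads: int = 20,
    spacing_nm: float = 5.6,
) -> list[BeadFilament]:
    """Sample beads at equal arc length along each strand of an n-start helix.

    Strands are phase-offset by 360°/n_start and share z=0 at bead 0 (the
    C2-like arrangement of a two-start filament).  A pitch of 0 gives a
    planar ring arc.
    """
    if n_beads < 4:
        raise ValueError("need at least 4 beads")
    if spacing_nm <= 0:
        raise ValueError("spacing must be positive")
    r = shape.radius_nm
    h = shape.reduced_pitch_nm
    ds_dtheta = math.hypot(r, h)  # arc length per radian of azimuth
    # azimuthal step chosen so the straight-line bead separation (chord)
    # equals the target spacing exactly; beads remain equally spaced in arc
    # length since the step is constant along the helix
    from scipy.optimize import brentq

    def chord_minus_spacing(dth: float) -> float:
        return math.sqrt(2.0 * r * r * (1.0 - math.cos(dth)) + h * h * dth * dth) - spacing_nm

    upper = spacing_nm / ds_dtheta * 2.0 + 1e-9
    if chord_minus_spacing(upper) < 0:
        raise ValueError("spacing too large for this helix radius/pitch")
    dtheta = brentq(chord_minus_spacing, 1e-12, upper, xtol=1e-14)
    k = np.arange(n_beads)
    strands = []
    for s in range(n_start):
        theta = k * dtheta + 2.0 * math.pi * s / n_start
        pos = np.column_stack(
            [r * np.cos(theta), r * np.sin(theta), h * k * dtheta]
        )
        strands.append(BeadFilament(positions_nm=pos, strand_id=s, spacing_nm=spacing_nm))
    return strands


# -- discrete differential geometry (batch-aware: positions[..., n, 3]) -----


def _menger_kappa(pos: np.ndarray) -> np.ndarray:
    """Menger curvature at interior beads: κ_i = 2|b_i × b_{i+1}| / (|b_i||b_{i+1}||c_i|).

    b are consecutive bond vectors and c_i the chord (i-1 → i+1); exact for
    points on a circle (inverse circumradius).  Collinear triples give 0.
    Returns shape [..., n-2] aligned with beads 1 .. n-2.
    """
    b1 = pos[..., 1:-1, :] - pos[..., :-2, :]
    b2 = pos[..., 2:, :] - pos[..., 1:-1, :]
    chord = pos[..., 2:, :] - pos[..., :-2, :]
    cross = np.cross(b1, b2)
    denom = (
        np.linalg.norm(b1, axis=-1)
        * np.linalg.norm(b2, axis=-1)
        * np.linalg.norm(chord, axis=-1)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        kappa = 2.0 * np.linalg.norm(cross, axis=-1) / denom
    return np.where(denom > 0, kappa, 0.0)


def _dihedral_tau(pos: np.ndarray) -> np.ndarray:
    """Signed twist density at interior bonds: dihedral / mean bond length.

    The dihedral at bond (i, i+1) is the angle between planes
    (i-1, i, i+1) and (i, i+1, i+2); positive for a right-handed helix.
    Divided by the mean length of the three bonds involved.
    Returns shape [..., n-3] aligned with bonds 1 .. n-3.
    """
    b0 = pos[..., 1:-2, :] - pos[..., :-3, :]
    b1 = pos[..., 2:-1, :] - pos[..., 1:-2, :]
    b2 = pos[..., 3:, :] - pos[..., 2:-1, :]
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1n = np.linalg.norm(b1, axis=-1)
    x = (n1 * n2).sum(axis=-1) * b1n
    y = (np.cross(n1, n2) * b1).sum(axis=-1)
    phi = np.arctan2(y, x)
    ds = (
        np.linalg.norm(b0, axis=-1) + b1n + np.linalg.norm(b2, axis=-1)
    ) / 3.0
    return phi / ds


def discrete_curvature(filament: BeadFilament) -> np.ndarray:
    """Per-interior-bead curvature estimates, nm⁻¹ (beads 1..n-2)."""
    return _menger_kappa(filament.positions_nm)


def discrete_twist(filament: BeadFilament) -> np.ndarray:
    """Per-interior-bond twist-density estimates, nm⁻¹ (bonds 1..n-3).

    Bonds whose flanking triples are collinear have no defined dihedral
    plane; those entries are flagged as NaN.
    """
    pos = filament.positions_nm
    tau = _dihedral_tau(pos)
    b0 = pos[1:-2] - pos[:-3]
    b1 = pos[2:-1] - pos[1:-2]
    b2 = pos[3:] - pos[2:-1]
    n1 = np.linalg.norm(np.cross(b0, b1), axis=-1)
    n2 = np.linalg.norm(np.cross(b1, b2), axis=-1)
    scale = np.linalg.norm(b1, axis=-1) ** 2
    return np.where((n1 > 1e-12 * scale) & (n2 > 1e-12 * scale), tau, np.nan)


def discrete_curvature_twist(filament: BeadFilament) -> CurvatureTwist:
    """Mean curvature and twist density over the interior of the chain."""
    return CurvatureTwist(
        kappa=float(discrete_curvature(filament).mean()),
        tau=float(discrete_twist(filament).mean()),
    )


def measure_shape(filament: BeadFilament) -> HelixShape:
    """Helix (radius, pitch) inferred from mean discrete curvature/twist.

    Rigid-motion invariant, so usable on relaxed chains that have drifted
    off the original axis.
    """
    return curvature_to_shape(discrete_curvature_twist(filament))


# -- system energy ----------------------------------------------------------


@dataclass(frozen=True)
class EnergyBreakdown:
    """Energy terms in kJ/mol; total is their sum."""

    filament_kjmol: float
    bond_kjmol: float
    membrane_kjmol: float
    coupling_kjmol: float

    @property
    def total_kjmol(self) -> float:
        return (
            self.filament_kjmol
            + self.bond_kjmol
            + self.membrane_kjmol
            + self.coupling_kjmol
        )


@dataclass
class SimSystem:
    """Bead filaments + optional membrane tube + parameters.

    ``k_bond`` keeps bond lengths near the dimer spacing (stiff harmonic
    rather than a hard constraint); ``k_coupling`` ties the bead radial
    distance to the local tube radius (plus ``coupling_offset_nm``).  With
    a tube present, bead z coordinates are wrapped into the periodic axial
    domain for the coupling term only.
    """

    filaments: list[BeadFilament] = field(default_factory=list)
    tube: MembraneTube | None = None
    elastic: FilamentElasticParams = field(default_factory=FilamentElasticParams)
    membrane: MembraneParams = field(default_factory=MembraneParams)
    k_bond: float = 1000.0  # kJ/mol/nm^2
    k_coupling: float = 100.0  # kJ/mol/nm^2
    coupling_offset_nm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.filaments and self.tube is None:
            raise ValueError("system needs at least a filament or a tube")

    # DOF vector layout: all bead coordinates (per filament, row-major),
    # then tube radii if a tube is present.
    def pack(self) -> np.ndarray:
        parts = [f.positions_nm.ravel() for f in self.filaments]
        if self.tube is not None:
            parts.append(self.tube.radius_nm.copy())
        return np.concatenate(parts) if parts else np.empty(0)

    def unpack(self, x: np.ndarray) -> tuple[list[np.ndarray], np.ndarray | None]:
        """Split a batch DOF array [..., D] into per-filament positions and tube radii."""
        offset = 0
        fil_pos = []
        for f in self.filaments:
            n = f.n_beads * 3
            fil_pos.append(x[..., offset : offset + n].reshape(*x.shape[:-1], f.n_beads, 3))
            offset += n
        tube_r = None
        if self.tube is not None:
            tube_r = x[..., offset:]
        return fil_pos, tube_r

    def with_state(self, x: np.ndarray) -> "SimSystem":
        """Copy of the system with DOFs replaced by the 1-D vector x."""
        fil_pos, tube_r = self.unpack(x)
        fils = [
            BeadFilament(positions_nm=p.copy(), strand_id=f.strand_id, spacing_nm=f.spacing_nm)
            for p, f in zip(fil_pos, self.filaments)
        ]
        tube = None
        if self.tube is not None:
            tube = MembraneTube(z_nm=self.tube.z_nm.copy(), radius_nm=tube_r.copy())
        return SimSystem(
            filaments=fils,
            tube=tube,
            elastic=self.elastic,
            membrane=self.membrane,
            k_bond=self.k_bond,
            k_coupling=self.k_coupling,
            coupling_offset_nm=self.coupling_offset_nm,
            seed=self.seed,
        )


def _interp_periodic(grid_r: np.ndarray, z0: float, dz: float, period: float, z: np.ndarray) -> np.ndarray:
    """Linear interpolation of tube radius at axial positions z (periodic).

    grid_r has shape [..., m]; z has shape [..., nb]; broadcasts over
    leading dims.
    """
    m = grid_r.shape[-1]
    u = ((z - z0) % period) / dz
    i0 = np.floor(u).astype(int) % m
    i1 = (i0 + 1) % m
    w = u - np.floor(u)
    r0 = np.take_along_axis(grid_r, i0, axis=-1)
    r1 = np.take_along_axis(grid_r, i1, axis=-1)
    return r0 * (1.0 - w) + r1 * w


def _energy_terms_batch(sys: SimSystem, x: np.ndarray) -> dict[str, np.ndarray]:
    """Energy terms (kJ/mol) for DOF arrays x of shape [..., D]."""
    fil_pos, tube_r = sys.unpack(np.asarray(x, dtype=float))
    lead = np.asarray(x).shape[:-1]
    zeros = np.zeros(lead)
    e_fil = zeros.copy()
    e_bond = zeros.copy()
    e_coup = zeros.copy()
    p = sys.elastic
    for fil, pos in zip(sys.filaments, fil_pos):
        kappa = _menger_kappa(pos)
        tau = _dihedral_tau(pos)
        # per-bead curvature term + per-bond twist term, each weighted by the
        # target spacing as the arc-length element
        e_fil = (
            e_fil
            + p.alpha_kappa * ((kappa - p.kappa0) ** 2).sum(axis=-1) * fil.spacing_nm
            + p.alpha_tau * ((tau - p.tau0) ** 2).sum(axis=-1) * fil.spacing_nm
        )
        bl = np.linalg.norm(np.diff(pos, axis=-2), axis=-1)
        e_bond = e_bond + 0.5 * sys.k_bond * ((bl - fil.spacing_nm) ** 2).sum(axis=-1)
        if sys.tube is not None and sys.k_coupling > 0:
            rho = np.linalg.norm(pos[..., :2], axis=-1)
            r_at = _interp_periodic(
                tube_r,
                float(sys.tube.z_nm[0]),
                sys.tube.dz_nm,
                sys.tube.length_nm,
                pos[..., 2],
            )
            e_coup = e_coup + 0.5 * sys.k_coupling * (
                (rho - (r_at + sys.coupling_offset_nm)) ** 2
            ).sum(axis=-1)
    e_mem = zeros.copy()
    if sys.tube is not None:
        e_mem = _profile_energy_batch(tube_r, sys.tube.dz_nm, sys.membrane) * sys.membrane.kBT_in_kJmol
    return {
        "filament": e_fil,
        "bond": e_bond,
        "membrane": e_mem,
        "coupling": e_coup,
    }


def system_energy(sys: SimSystem) -> EnergyBreakdown:
    """Total system energy and per-term breakdown, kJ/mol."""
    terms = _energy_terms_batch(sys, sys.pack())
    return EnergyBreakdown(
        filament_kjmol=float(terms["filament"]),
        bond_kjmol=float(terms["bond"]),
        membrane_kjmol=float(terms["membrane"]),
        coupling_kjmol=float(terms["coupling"]),
    )


def _total_energy_batch(sys: SimSystem, x: np.ndarray) -> np.ndarray:
    terms = _energy_terms_batch(sys, x)
    return terms["filament"] + terms["bond"] + terms["membrane"] + terms["coupling"]


def _numerical_gradient(sys: SimSystem, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference gradient, evaluated as one vectorized batch."""
    d = len(x)
    eye = np.eye(d) * h
    batch = np.concatenate([x + eye, x - eye], axis=0)
    e = _total_energy_batch(sys, batch)
    return (e[:d] - e[d:]) / (2.0 * h)


@dataclass
class TrajectoryFrame:
    step: int
    energy: EnergyBreakdown
    positions_nm: list[np.ndarray]
    tube_radius_nm: np.ndarray | None

    @property
    def mean_tube_radius_nm(self) -> float | None:
        if self.tube_radius_nm is None:
            return None
        return float(self.tube_radius_nm.mean())


@dataclass
class Trajectory:
    """Relaxation trace: accepted steps with energies and sampled frames."""

    steps: list[int] = field(default_factory=list)
    energies_kjmol: list[float] = field(default_factory=list)
    frames: list[TrajectoryFrame] = field(default_factory=list)
    converged: bool = False
    final_system: SimSystem | None = None
    final_grad_inf_norm: float = float("nan")
    seed: int = 0

    @property
    def energy_array(self) -> np.ndarray:
        return np.asarray(self.energies_kjmol)


def relax(
    sys: SimSystem,
    max_steps: int = 20000,
    tol: float = 1e-10,
    grad_tol: float = 1e-4,
    fd_step: float = 1e-5,
    record_every: int = 100,
) -> Trajectory:
    """Relax bead positions and tube profile by monotone gradient descent.

    Steepest descent with a Barzilai–Borwein step length, backtracking
    (factor 0.5) until the Armijo sufficient-decrease condition holds, so
    the accepted-step energy sequence is non-increasing by construction.
    Terminates when the energy decrease per accepted step falls below
    ``tol`` and the gradient infinity norm below ``grad_tol``, or at
    ``max_steps``.  Gradients are numerical (central differences,
    ``fd_step`` nm).  Deterministic for identical inputs.
    """
    x = sys.pack().astype(float)
    f = float(_total_energy_batch(sys, x))
    if not np.isfinite(f):
        raise FloatingPointError("non-finite initial energy")
    g = _numerical_gradient(sys, x, fd_step)
    traj = Trajectory(seed=sys.seed)

    def record(step: int, xs: np.ndarray) -> None:
        state = sys.with_state(xs)
        terms = system_energy(state)
        traj.frames.append(
            TrajectoryFrame(
                step=step,
                energy=terms,
                positions_nm=[fl.positions_nm.copy() for fl in state.filaments],
                tube_radius_nm=None if state.tube is None else state.tube.radius_nm.copy(),
            )
        )

    traj.steps.append(0)
    traj.energies_kjmol.append(f)
    record(0, x)

    lam = 1e-3
    s_prev = None
    y_prev = None
    for step in range(1, max_steps + 1):
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(
                f"non-finite gradient at step {step}; energy={f:.6g}"
            )
        gnorm = float(np.abs(g).max())
        if gnorm < grad_tol:
            traj.converged = True
            break
        if s_prev is not None:
            sy = float(s_prev @ y_prev)
            if sy > 1e-300:
                lam = float(s_prev @ s_prev) / sy
            lam = min(max(lam, 1e-12), 1e3)
        gg = float(g @ g)
        accepted = False
        lam_try = lam
        for _ in range(60):
            x_new = x - lam_try * g
            f_new = float(_total_energy_batch(sys, x_new))
            if np.isfinite(f_new) and f_new <= f - 1e-4 * lam_try * gg:
                accepted = True
                break
            lam_try *= 0.5
        if not accepted:
            traj.converged = gnorm < 10 * grad_tol
            break
        g_new = _numerical_gradient(sys, x_new, fd_step)
        s_prev = x_new - x
        y_prev = g_new - g
        drop = f - f_new
        x, f, g = x_new, f_new, g_new
        traj.steps.append(step)
        traj.energies_kjmol.append(f)
        if step % record_every == 0:
            record(step, x)
        if drop < tol and float(np.abs(g).max()) < grad_tol:
            traj.converged = True
            break

    if traj.frames[-1].step != traj.steps[-1]:
        record(traj.steps[-1], x)
    traj.final_system = sys.with_state(x)
    traj.final_grad_inf_norm = float(np.abs(g).max())
    return traj
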