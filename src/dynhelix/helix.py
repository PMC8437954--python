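"""Helical symmetry arithmetic and continuous helix geometry.

A helical polymer is described in two interchangeable ways:

* **Discrete cryoEM symmetry** — a rise (axial translation per subunit, Å)
  and twist (azimuthal rotation per subunit, degrees), together with the
  start number (how many intertwined strands) and the point-group order
  (e.g. 2 for a C2 relation between the two strands of a two-start helix).

* **Continuous strand shape** — the radius ``r`` of the strand centerline
  and the pitch ``p`` (axial advance of one strand per full turn).  With the
  reduced pitch ``h = p/(2π)`` the centerline has curvature
  ``κ = r/(h² + r²)`` and torsion (twist density) ``τ = h/(h² + r²)``.

Lengths are nanometres internally; Ångström enters only through the
symmetry rise and atomic coordinates, and is converted at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "HelicalSymmetry",
    "HelixShape",
    "CurvatureTwist",
    "LatticePoint",
    "subunits_per_turn",
    "strand_pitch",
    "rung_spacing",
    "shape_to_curvature",
    "curvature_to_shape",
    "lattice_points",
]

A_PER_NM = 10.0


@dataclass(frozen=True)
class HelicalSymmetry:
    """CryoEM description of a helical filament.

    Parameters
    ----------
    rise_A : float
        Axial translation per subunit, Å. Must be positive.
    twist_deg : float
        Azimuthal rotation per subunit, degrees, in (0, 360].
    n_start : int
        Number of intertwined strands (1 = one-start).
    cyclic_order : int
        Point-group order relating the strands (2 for a C2 two-start helix).
    handedness : str
        ``"right"`` (positive twist advances counterclockwise viewed down
        +z) or ``"left"``.
    """

    rise_A: float
    twist_deg: float
    n_start: int = 1
    cyclic_order: int = 1
    handedness: str = "right"

    def __post_init__(self) -> None:
        if not self.rise_A > 0:
            raise ValueError(f"rise must be positive, got {self.rise_A}")
        if not 0 < self.twist_deg <= 360:
            raise ValueError(
                f"twist must be in (0, 360] degrees, got {self.twist_deg}"
            )
        if self.n_start < 1:
            raise ValueError("n_start must be >= 1")
        if self.cyclic_order < 1:
            raise ValueError("cyclic_order must be >= 1")
        if self.handedness not in ("right", "left"):
            raise ValueError("handedness must be 'right' or 'left'")

    @property
    def rise_nm(self) -> float:
        return self.rise_A / A_PER_NM


@dataclass(frozen=True)
class HelixShape:
    """Continuous shape of one filament strand: radius and pitch, nm.

    The radius is the distance from the helical axis to the filament
    centerline (for the dynamin stalk filament, defined at interface 2).
    ``pitch == 0`` is the planar-ring limit.
    """

    radius_nm: float
    pitch_nm: float

    def __post_init__(self) -> None:
        if not self.radius_nm > 0:
            raise ValueError(f"radius must be positive, got {self.radius_nm}")
        if self.pitch_nm < 0:
            raise ValueError(f"pitch must be >= 0, got {self.pitch_nm}")

    @property
    def reduced_pitch_nm(self) -> float:
        """h = p/(2π), the axial advance per radian."""
        return self.pitch_nm / (2.0 * math.pi)


@dataclass(frozen=True)
class CurvatureTwist:
    """Curvature κ and twist density τ of a filament centerline, nm⁻¹."""

    kappa: float
    tau: float

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")


@dataclass(frozen=True)
class LatticePoint:
    """One subunit position on a helical lattice, cylindrical coordinates."""

    subunit_index: int
    strand_index: int
    radius_nm: float
    azimuth_deg: float
    z_nm: float

    def xyz_nm(self) -> tuple[float, float, float]:
        phi = math.radians(self.azimuth_deg)
        return (
            self.radius_nm * math.cos(phi),
            self.radius_nm * math.sin(phi),
            self.z_nm,
        )


def subunits_per_turn(twist_deg: float) -> float:
    """Number of subunits per helical turn, 360/twist.

    Reported at full precision; round at the presentation layer
    (24.43° → ~14.7, 23.68° → ~15.2).
    """
    if not 0 < twist_deg <= 360:
        raise ValueError(f"twist must be in (0, 360] degrees, got {twist_deg}")
    return 360.0 / twist_deg


def strand_pitch(sym: HelicalSymmetry) -> float:
    """Axial advance of one strand per full turn, nm: rise × (360/twist)."""
    return sym.rise_nm * subunits_per_turn(sym.twist_deg)


def rung_spacing(sym: HelicalSymmetry) -> float:
    """Axial distance between adjacent filament rungs of any strand, nm.

    Equals the strand pitch divided by the start number: the two strands of
    a two-start helix interleave, halving the turn-to-turn spacing.
    """
    return strand_pitch(sym) / sym.n_start


def shape_to_curvature(shape: HelixShape) -> CurvatureTwist:
    """κ = r/(h²+r²), τ = h/(h²+r²) with h = p/2π."""
    r = shape.radius_nm
    h = shape.reduced_pitch_nm
    d = h * h + r * r
    return CurvatureTwist(kappa=r / d, tau=h / d)


def curvature_to_shape(ct: CurvatureTwist) -> HelixShape:
    """Analytic inverse of :func:`shape_to_curvature`.

    r = κ/(κ²+τ²), h = τ/(κ²+τ²).  κ must be strictly positive: a straight
    filament (κ=0) has no finite radius.
    """
    if not ct.kappa > 0:
        raise ValueError(
            f"kappa must be positive to recover a finite radius, got {ct.kappa}"
        )
    d = ct.kappa**2 + ct.tau**2
    return HelixShape(radius_nm=ct.kappa / d, pitch_nm=2.0 * math.pi * ct.tau / d)


def lattice_points(
    sym: HelicalSymmetry, radius_nm: float, n_subunits_per_strand: int
) -> list[LatticePoint]:
    """Generate the helical lattice of an n-start filament.

    Subunit ``k`` of strand ``s`` sits at ``z = k·rise`` and azimuth
    ``±k·twist + s·(360/cyclic_order)`` (sign per handedness).  For a C2
    two-start helix, strand partners share each z level at azimuths 180°
    apart — the C2 relation between the two rungs.
    """
    if n_subunits_per_strand < 1:
        raise ValueError("need at least one subunit per strand")
    if not radius_nm > 0:
        raise ValueError("radius must be positive")
    sign = 1.0 if sym.handedness == "right" else -1.0
    points = []
    for s in range(sym.n_start):
        phase = s * 360.0 / sym.cyclic_order
        for k in range(n_subunits_per_strand):
            points.append(
                LatticePoint(
                    subunit_index=k,
                    strand_index=s,
                    radius_nm=radius_nm,
                    azimuth_deg=(sign * k * sym.twist_deg + phase) % 360.0,
                    z_nm=k * sym.rise_nm,
                )
            )
    return points
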