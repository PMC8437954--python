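"""Elastic energy of the dynamin stalk filament.

The stalk filament is treated as an elastic rod with spontaneous curvature
and twist.  Its energy per unit length is the quadratic form

    E(κ, τ) = α_κ (κ − κ0)² + α_τ (τ − τ0)²         [kJ/mol/nm]

with moduli α_κ, α_τ and spontaneous values κ0, τ0 obtained from molecular
dynamics of the stalk tetramer.  For a constant helix, κ and τ follow from
the strand radius and pitch, so the energy is a landscape over (r, p).
Energies are usually quoted per dimer, i.e. multiplied by the 5.6 nm
contour length a dynamin dimer occupies along the filament.

When neighbouring turns form GTPase (GG) dimers this adds a constant free
energy per unit length g0 (E_total = E + g0); g0 is identical between one-
and two-start helices and therefore drops out of every comparison, so it
defaults to 0.

The global minimum has the closed form

    r* = κ0/(κ0² + τ0²),   p* = 2π τ0/(κ0² + τ0²)

(≈ 11.50 nm and ≈ 51.1 nm for the default parameters): the filament
intrinsically prefers a large pitch, which is why a two-start helix —
doubling the strand pitch at fixed rung spacing — is energetically
favoured over a one-start at the same radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .helix import CurvatureTwist, HelixShape, curvature_to_shape, shape_to_curvature

__all__ = [
    "FilamentElasticParams",
    "EnergyLandscape",
    "energy_per_length",
    "energy_per_dimer",
    "landscape",
    "min_energy_over_radius",
    "global_minimum",
    "multistart_comparison",
    "MultiStartComparison",
    "lumen_mapping",
    "DEFAULT_LUMEN_OFFSET_NM",
]

#: Radial offset (nm) between the filament centerline (interface 2) and the
#: inner leaflet of the membrane tube; calibrated so the 13.5 nm two-start
#: filament radius maps to the ~4 nm super-constricted lumen diameter.
DEFAULT_LUMEN_OFFSET_NM = 11.5


@dataclass(frozen=True)
class FilamentElasticParams:
    """Elastic parameters of the stalk filament.

    Attributes
    ----------
    alpha_kappa, alpha_tau : float
        Bending and twisting moduli, nm·kJ/mol.
    kappa0, tau0 : float
        Spontaneous curvature and twist density, nm⁻¹.
    dimer_length_nm : float
        Filament contour length per dynamin dimer, nm.
    g0 : float
        GG-dimer interaction free energy per unit length, kJ/mol/nm.
        Identical across helical families, hence 0 by default.
    """

    alpha_kappa: float = 3000.0
    alpha_tau: float = 2700.0
    kappa0: float = 0.058
    tau0: float = 0.041
    dimer_length_nm: float = 5.6
    g0: float = 0.0

    def __post_init__(self) -> None:
        if self.alpha_kappa <= 0 or self.alpha_tau <= 0:
            raise ValueError("elastic moduli must be positive")
        if self.dimer_length_nm <= 0:
            raise ValueError("dimer length must be positive")


def energy_per_length(ct: CurvatureTwist, params: FilamentElasticParams | None = None):
    """Elastic energy per unit length, kJ/mol/nm (g0 not included).

    Accepts scalar ``CurvatureTwist`` or ``(kappa, tau)`` arrays via the
    private array form :func:`_energy_density`.
    """
    if params is None:
        params = FilamentElasticParams()
    return _energy_density(ct.kappa, ct.tau, params)


def _energy_density(kappa, tau, params: FilamentElasticParams):
    """Array-friendly quadratic form α_κ(κ−κ0)² + α_τ(τ−τ0)²."""
    return (
        params.alpha_kappa * (np.asarray(kappa) - params.kappa0) ** 2
        + params.alpha_tau * (np.asarray(tau) - params.tau0) ** 2
    )


def _energy_per_dimer_rp(r, p, params: FilamentElasticParams):
    """Per-dimer energy on (radius, pitch) arrays; includes g0."""
    r = np.asarray(r, dtype=float)
    h = np.asarray(p, dtype=float) / (2.0 * math.pi)
    d = h * h + r * r
    e = _energy_density(r / d, h / d, params) + params.g0
    return e * params.dimer_length_nm


def energy_per_dimer(shape: HelixShape, params: FilamentElasticParams | None = None) -> float:
    """Elastic energy per dynamin dimer, kJ/mol: (E + g0) × dimer length."""
    if params is None:
        params = FilamentElasticParams()
    return float(_energy_per_dimer_rp(shape.radius_nm, shape.pitch_nm, params))


@dataclass(frozen=True)
class EnergyLandscape:
    """Per-dimer elastic energy over a (radius, pitch) grid.

    ``energy_kjmol[i, j]`` corresponds to ``radius_nm[i]``, ``pitch_nm[j]``
    (radius varies along rows).
    """

    radius_nm: np.ndarray
    pitch_nm: np.ndarray
    energy_kjmol: np.ndarray
    params: FilamentElasticParams = field(default_factory=FilamentElasticParams)

    def minimum(self) -> tuple[float, float, float]:
        """(radius, pitch, energy) of the lowest grid cell."""
        i, j = np.unravel_index(int(np.argmin(self.energy_kjmol)), self.energy_kjmol.shape)
        return (
            float(self.radius_nm[i]),
            float(self.pitch_nm[j]),
            float(self.energy_kjmol[i, j]),
        )

    def to_frame(self):
        """Long-format DataFrame: radius_nm, pitch_nm, energy_kjmol."""
        import pandas as pd

        rr, pp = np.meshgrid(self.radius_nm, self.pitch_nm, indexing="ij")
        return pd.DataFrame(
            {
                "radius_nm": rr.ravel(),
                "pitch_nm": pp.ravel(),
                "energy_kjmol": self.energy_kjmol.ravel(),
            }
        )


def landscape(
    r_min: float = 5.0,
    r_max: float = 25.0,
    p_min: float = 5.0,
    p_max: float = 80.0,
    n_r: int = 400,
    n_p: int = 400,
    params: FilamentElasticParams | None = None,
) -> EnergyLandscape:
    """Evaluate the per-dimer energy on a regular (radius, pitch) grid.

    Default ranges bracket both experimentally observed helical families and
    the global minimum.
    """
    if params is None:
        params = FilamentElasticParams()
    if not (0 < r_min < r_max and 0 <= p_min < p_max):
        raise ValueError("invalid grid ranges")
    if n_r < 2 or n_p < 2:
        raise ValueError("need at least 2 grid points per axis")
    radius = np.linspace(r_min, r_max, n_r)
    pitch = np.linspace(p_min, p_max, n_p)
    energy = _energy_per_dimer_rp(radius[:, None], pitch[None, :], params)
    return EnergyLandscape(radius_nm=radius, pitch_nm=pitch, energy_kjmol=energy, params=params)


def min_energy_over_radius(
    pitch_nm: float,
    params: FilamentElasticParams | None = None,
    r_bounds: tuple[float, float] = (1.0, 50.0),
) -> tuple[float, float]:
    """Minimize the per-dimer energy over radius at fixed pitch.

    Returns ``(r_argmin, energy)``.  This traces the minimal-energy curve
    of the (r, p) landscape as a function of pitch.  If the minimum sits on
    a bound a warning is emitted and the boundary value returned.
    """
    import warnings

    if params is None:
        params = FilamentElasticParams()
    lo, hi = r_bounds
    if not 0 < lo < hi:
        raise ValueError("r_bounds must be a positive interval")

    def f(r: float) -> float:
        return float(_energy_per_dimer_rp(r, pitch_nm, params))

    res = minimize_scalar(f, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    r_star = float(res.x)
    edge = 1e-6 * (hi - lo)
    if r_star - lo < edge or hi - r_star < edge:
        warnings.warn(
            f"minimum over radius at pitch={pitch_nm} nm lies on the bound r={r_star:.4g}",
            stacklevel=2,
        )
    return r_star, f(r_star)


def global_minimum(
    params: FilamentElasticParams | None = None,
) -> tuple[float, float, float]:
    """Closed-form global minimum of the per-dimer energy.

    The quadratic form vanishes exactly at (κ0, τ0); inverting the
    helix relations gives r* = κ0/(κ0²+τ0²), p* = 2π·τ0/(κ0²+τ0²) and a
    minimum energy of g0 × dimer length.
    """
    if params is None:
        params = FilamentElasticParams()
    shape = curvature_to_shape(CurvatureTwist(kappa=params.kappa0, tau=params.tau0))
    return (
        shape.radius_nm,
        shape.pitch_nm,
        params.g0 * params.dimer_length_nm,
    )


@dataclass(frozen=True)
class MultiStartComparison:
    """Per-dimer energies of k-start helices at one radius and rung spacing."""

    radius_nm: float
    rung_spacing_nm: float
    k_starts: tuple[int, ...]
    energies_kjmol: tuple[float, ...]

    @property
    def delta_one_two_kjmol(self) -> float | None:
        """E(1-start) − E(2-start), kJ/mol per dimer, if both computed."""
        by_k = dict(zip(self.k_starts, self.energies_kjmol))
        if 1 in by_k and 2 in by_k:
            return by_k[1] - by_k[2]
        return None


def multistart_comparison(
    radius_nm: float,
    rung_spacing_nm: float = 10.0,
    k_starts: tuple[int, ...] = (1, 2),
    params: FilamentElasticParams | None = None,
) -> MultiStartComparison:
    """Compare k-start helices at fixed radius and rung spacing.

    A k-start helix with rung spacing d has strand pitch k·d: adding strands
    increases each strand's pitch without changing the turn-to-turn spacing,
    so the GG contacts between neighbouring rungs are preserved while the
    strand moves toward the large-pitch energy minimum.  The default rung
    spacing of 10 nm is the pitch of the one-start dynamin helix.
    """
    if params is None:
        params = FilamentElasticParams()
    if rung_spacing_nm <= 0:
        raise ValueError("rung spacing must be positive")
    if any(k < 1 for k in k_starts):
        raise ValueError("start numbers must be >= 1")
    energies = tuple(
        energy_per_dimer(HelixShape(radius_nm=radius_nm, pitch_nm=k * rung_spacing_nm), params)
        for k in k_starts
    )
    return MultiStartComparison(
        radius_nm=radius_nm,
        rung_spacing_nm=rung_spacing_nm,
        k_starts=tuple(k_starts),
        energies_kjmol=energies,
    )


def lumen_mapping(filament_radius_nm: float, offset_nm: float = DEFAULT_LUMEN_OFFSET_NM) -> float:
    """Inner lumen diameter of the membrane tube under a filament, nm.

    diameter = 2 × (filament radius − offset).  The default offset places
    the membrane inner leaflet 11.5 nm inside the filament centerline.
    """
    if offset_nm < 0:
        raise ValueError("offset must be >= 0")
    if filament_radius_nm <= offset_nm:
        raise ValueError(
            f"filament radius {filament_radius_nm} nm does not exceed offset {offset_nm} nm"
        )
    return 2.0 * (filament_radius_nm - offset_nm)
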