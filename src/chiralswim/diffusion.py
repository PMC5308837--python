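"""Anisotropic Brownian diffusion coefficients for a prolate-spheroid cell.

Translational coefficients follow Stokes–Einstein, D = kT/(6πrμ), with a
different effective radius along the long axis (travel direction t) and
perpendicular to it.  Rotational diffusion starts from the
Stokes–Einstein–Debye coefficient of the equal-volume sphere,
E = kT/(8πμa³), and is adjusted per axis by the Perrin rotational
friction factors of a prolate spheroid of axial ratio e = r_np/r_d.

The Perrin factors are friction *ratios* relative to the equal-volume
sphere, so the effective rotational diffusion coefficients divide by
them: E_i = E/f_i.  Spinning about the long axis is easier than
tumbling (f_d < 1 < f_np for e > 1), so a slender swimmer loses its
heading mainly by tumbling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

BOLTZMANN = 1.380649e-23  # J/K (exact, SI)

__all__ = [
    "BOLTZMANN",
    "SpheroidGeometry",
    "Environment",
    "DiffusionSet",
    "perrin_factors",
    "translational_diffusion",
    "rotational_diffusion",
]


@dataclass(frozen=True)
class SpheroidGeometry:
    """Prolate-spheroid model of the cell body.

    r_d : μm — effective (Stokes) radius for displacement along t.
    r_np : μm — effective radius for displacement along n and b.
    For an elongated cell r_np > r_d; the axial ratio e = r_np/r_d and
    equal-volume-sphere radius a = (r_d²·r_np)^(1/3) follow.
    """

    r_d: float = 1.5
    r_np: float = 8.0

    def __post_init__(self) -> None:
        if not (self.r_d > 0 and self.r_np > 0):
            raise ValueError("spheroid radii must be positive")

    @property
    def aspect(self) -> float:
        return self.r_np / self.r_d

    @property
    def equal_volume_radius(self) -> float:
        return (self.r_d**2 * self.r_np) ** (1.0 / 3.0)


@dataclass(frozen=True)
class Environment:
    """Thermodynamic environment: temperature (K) and viscosity (Pa·s).

    Defaults are ambient imaging conditions: 26 °C and the viscosity of
    water at that temperature.
    """

    temperature: float = 299.15
    viscosity: float = 8.7e-4

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be positive (kelvin)")
        if not self.viscosity > 0:
            raise ValueError("viscosity must be positive")

    @classmethod
    def from_celsius(cls, celsius: float, viscosity: float = 8.7e-4) -> "Environment":
        return cls(temperature=celsius + 273.15, viscosity=viscosity)


@dataclass(frozen=True)
class DiffusionSet:
    """Full set of diffusion coefficients for one spheroid + environment.

    D_d, D_np : μm²/s translational, along t and along n/b.
    E : rad²/s rotational coefficient of the equal-volume sphere.
    f_d, f_np : Perrin friction factors about the long / short axes.
    E_d, E_np : rad²/s effective rotational coefficients about t and n/b.
    """

    D_d: float
    D_np: float
    E: float
    f_d: float
    f_np: float
    E_d: float
    E_np: float


def perrin_factors(e: float) -> tuple[float, float]:
    """Perrin rotational friction factors (f_d, f_np) of a prolate spheroid.

    e is the axial ratio (long/short semi-axis, > 1 for prolate).  With
    ξ = √|e² − 1|/e and S = 2·artanh(ξ)/ξ:

        f_d  = (4/3)·ξ² / (2 − S/e²)
        f_np = (4/3)·(1/e² − e²) / (2 − S·(2 − 1/e²))

    relative to the sphere of equal volume.  The sphere limit e → 1
    returns (1, 1); values within 1e-6 of 1 take that limit to avoid
    0/0 in the closed forms.
    """
    if not e > 0:
        raise ValueError(f"axial ratio must be positive, got {e}")
    if abs(e - 1.0) < 1e-6:
        return 1.0, 1.0
    xi2 = (e * e - 1.0) / (e * e)  # signed; negative for oblate
    xi = math.sqrt(abs(xi2))
    if e > 1.0:
        S = 2.0 * math.atanh(xi) / xi
    else:
        # oblate branch: artanh(iξ)/(iξ) = arctan(ξ)/ξ, ξ² carries its sign
        S = 2.0 * math.atan(xi) / xi
    f_d = (4.0 / 3.0) * xi2 / (2.0 - S / (e * e))
    f_np = (4.0 / 3.0) * (1.0 / (e * e) - e * e) / (2.0 - S * (2.0 - 1.0 / (e * e)))
    return f_d, f_np


def translational_diffusion(
    geom: SpheroidGeometry, env: Environment
) -> tuple[float, float]:
    """Stokes–Einstein translational coefficients (D_d, D_np) in μm²/s."""
    kT = BOLTZMANN * env.temperature

    def _d(radius_um: float) -> float:
        d_m2 = kT / (6.0 * math.pi * radius_um * 1e-6 * env.viscosity)
        return d_m2 * 1e12  # m²/s → μm²/s

    return _d(geom.r_d), _d(geom.r_np)


def rotational_diffusion(
    geom: SpheroidGeometry, env: Environment, perrin_mode: str = "divide"
) -> DiffusionSet:
    """Full diffusion set including Perrin-adjusted rotational coefficients.

    E = kT/(8πμa³) for the equal-volume sphere of radius a; per-axis
    coefficients are E_i = E/f_i (``perrin_mode="divide"``, the friction
    ratio convention, default) or E_i = E·f_i (``"multiply"``, kept as a
    documented alternative reading).
    """
    if perrin_mode not in ("divide", "multiply"):
        raise ValueError(f"perrin_mode must be 'divide' or 'multiply', got {perrin_mode!r}")
    kT = BOLTZMANN * env.temperature
    a_m = geom.equal_volume_radius * 1e-6
    E = kT / (8.0 * math.pi * env.viscosity * a_m**3)  # rad²/s
    f_d, f_np = perrin_factors(geom.aspect)
    if perrin_mode == "divide":
        E_d, E_np = E / f_d, E / f_np
    else:
        E_d, E_np = E * f_d, E * f_np
    D_d, D_np = translational_diffusion(geom, env)
    return DiffusionSet(D_d=D_d, D_np=D_np, E=E, f_d=f_d, f_np=f_np, E_d=E_d, E_np=E_np)
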