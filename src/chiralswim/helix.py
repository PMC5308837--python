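"""Closed-form geometry of helical swimming paths.

A swimming cell with constant speed and constant path curvature κ and
torsion τ follows a helix of radius ``r = κ/(κ² + τ²)`` and pitch
``h = 2πτ/(κ² + τ²)``.  These helpers convert between the kinematic
description of swimming (speed plus angular velocities of the travel
frame) and the geometric one, and compute *directionality* — net
displacement per unit distance travelled — which is the quantity that
distinguishes a futile circular path (directionality → 0) from nearly
straight-line swimming (directionality → 1).

Conventions: τ > 0 is a right-handed helix; the sign of the longitudinal
angular velocity carries through to the sign of τ.  Directionality is
invariant under handedness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "HelixDescriptor",
    "PathKinematics",
    "HelixMetrics",
    "helix_from_curvature_torsion",
    "helix_metrics",
    "directionality_limit",
    "kinematics_to_path",
]


@dataclass(frozen=True)
class HelixDescriptor:
    """A helical path described both by (κ, τ) and by (radius, pitch).

    Parameters are in μm⁻¹ (curvature/torsion) and μm (radius/pitch).
    ``axial_rate`` is the rise per radian of phase, c = h/2π.  The
    straight-line case κ = τ = 0 is carried as an explicit ``degenerate``
    flag with infinite radius, never a silent zero, so downstream code
    cannot divide by zero unwittingly.
    """

    curvature: float
    torsion: float
    radius: float
    pitch: float
    axial_rate: float
    degenerate: bool = False

    def point(self, p: float) -> tuple[float, float, float]:
        """Point on the parametric helix (r cos p, r sin p, c·p)."""
        if self.degenerate:
            raise ValueError("degenerate (straight-line) helix has no parametric form")
        return (
            self.radius * math.cos(p),
            self.radius * math.sin(p),
            self.axial_rate * p,
        )


@dataclass(frozen=True)
class PathKinematics:
    """Kinematic description of steady swimming.

    speed : μm/s, > 0
    omega_kappa : rad/s, rotation of (t, n) about the binormal b — bends
        the path (curvature source).
    omega_tau : rad/s, rotation of (b, n) about the travel direction t —
        longitudinal rotation (torsion source).  Sign sets handedness.
    """

    speed: float
    omega_kappa: float = 0.0
    omega_tau: float = 0.0

    def __post_init__(self) -> None:
        if not self.speed > 0:
            raise ValueError(f"speed must be > 0, got {self.speed}")
        if self.omega_kappa < 0:
            raise ValueError("omega_kappa must be >= 0")

    @property
    def curvature(self) -> float:
        return self.omega_kappa / self.speed

    @property
    def torsion(self) -> float:
        return self.omega_tau / self.speed


@dataclass(frozen=True)
class HelixMetrics:
    arc_length: float
    displacement: float
    directionality: float


def helix_from_curvature_torsion(curvature: float, torsion: float) -> HelixDescriptor:
    """Build a :class:`HelixDescriptor` from curvature and torsion (μm⁻¹).

    r = κ/(κ² + τ²), h = 2πτ/(κ² + τ²).  κ must be ≥ 0; κ = τ = 0 returns
    the flagged degenerate straight line.
    """
    if curvature < 0:
        raise ValueError(f"curvature must be >= 0, got {curvature}")
    norm2 = curvature * curvature + torsion * torsion
    if norm2 == 0.0:
        return HelixDescriptor(
            curvature=0.0,
            torsion=0.0,
            radius=math.inf,
            pitch=math.inf,
            axial_rate=math.inf,
            degenerate=True,
        )
    radius = curvature / norm2
    pitch = 2.0 * math.pi * torsion / norm2
    return HelixDescriptor(
        curvature=curvature,
        torsion=torsion,
        radius=radius,
        pitch=pitch,
        axial_rate=pitch / (2.0 * math.pi),
    )


def helix_metrics(helix: HelixDescriptor, phase: float) -> HelixMetrics:
    """Arc length, chord displacement and directionality over phase P (rad).

    l = P·√(r² + c²); displacement is the chord between the helix points
    at p = 0 and p = P; directionality = displacement / arc length.
    A degenerate (straight-line) helix has directionality 1 by definition,
    with arc length and displacement undefined (NaN) absent a speed scale.
    """
    if not phase > 0:
        raise ValueError(f"phase must be > 0, got {phase}")
    if helix.degenerate:
        return HelixMetrics(math.nan, math.nan, 1.0)
    r, c = helix.radius, helix.axial_rate
    arc = phase * math.hypot(r, c)
    dx = r * math.cos(phase) - r
    dy = r * math.sin(phase)
    dz = c * phase
    disp = math.sqrt(dx * dx + dy * dy + dz * dz)
    return HelixMetrics(arc, disp, disp / arc)


def directionality_limit(curvature: float, torsion: float) -> float:
    """Long-helix limit of directionality, τ/√(κ² + τ²).

    Valid when the helix rise over the evaluated phase dwarfs the radius
    (hP ≫ r).  κ = τ = 0 returns 1 by convention (straight line).
    Handedness does not matter: the magnitude of τ is used.
    """
    if curvature < 0:
        raise ValueError(f"curvature must be >= 0, got {curvature}")
    norm = math.hypot(curvature, torsion)
    if norm == 0.0:
        return 1.0
    return abs(torsion) / norm


def kinematics_to_path(kin: PathKinematics) -> tuple[float, float]:
    """Darboux relation at constant speed: κ = ω_κ/s, τ = ω_τ/s."""
    return kin.curvature, kin.torsion
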