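"""Resistive-force (slender-body) axial torque on a segmented cell shape.

A slender segment tilted at angle θ to a uniform Stokes flow experiences
anisotropic drag (C_perp > C_par), leaving a net force component
perpendicular to the flow of magnitude (C_perp − C_par)·U·sinθ·cosθ per
unit length.  Where the segment midpoint is offset radially from the
cell midline (taken as the z axis, the axis about which the rotation
phase advances), this lateral force exerts a torque about the axis.
Summed over the segments of an effective hydrodynamic shape, the
z-torque measures how strongly chirality of the shape drives
longitudinal rotation under axial flow.

Default drag coefficients are the Gray–Hancock resistive-force forms
with the segment length as the slenderness scale:

    C_par  = 2πμ / (ln(2q/r) − 1/2)
    C_perp = 4πμ / (ln(2q/r) + 1/2)

A Lighthill-style variant is switchable.  Inputs are μm, μm/s and Pa·s;
torques are reported in pN·μm (1 pN·μm = 1e-18 N·m).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .shape import EffectiveShape

__all__ = [
    "FlowSpec",
    "SegmentForce",
    "TorqueResult",
    "resistive_coefficients",
    "segment_lateral_force",
    "axial_torque",
]

PNUM_PER_NM = 1e18  # N·m → pN·μm


@dataclass(frozen=True)
class FlowSpec:
    """Uniform flow of magnitude U (μm/s) along +z, viscosity μ (Pa·s)."""

    U: float = 1.0
    viscosity: float = 8.7e-4

    def __post_init__(self) -> None:
        if self.U < 0:
            raise ValueError("flow speed must be >= 0")
        if not self.viscosity > 0:
            raise ValueError("viscosity must be positive")


@dataclass(frozen=True)
class SegmentForce:
    """Lateral (⊥ flow) force on one segment and its torque about z.

    force : (3,) N, the component of segment drag perpendicular to the
        flow direction.
    lever_arm : (3,) μm, radial offset of the segment midpoint from the
        z axis.
    torque_z : pN·μm.
    """

    force: np.ndarray
    lever_arm: np.ndarray
    torque_z: float


@dataclass
class TorqueResult:
    """Per-segment torques (pN·μm) plus the total about the z axis."""

    segments: list[SegmentForce]
    total: float

    def per_segment(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment": np.arange(len(self.segments)),
                "torque_pN_um": [s.torque_z for s in self.segments],
            }
        )


def resistive_coefficients(
    q: float, r: float, viscosity: float, variant: str = "gray-hancock"
) -> tuple[float, float]:
    """Drag per unit length per unit speed (C_par, C_perp), SI (Pa·s units).

    q : μm segment length; r : μm segment radius; requires q > 2r
    (slenderness).  ``variant`` selects "gray-hancock" (default) or
    "lighthill" (0.18-prefactor slenderness argument).
    """
    if not q > 2.0 * r:
        raise ValueError(f"slenderness violated: need q > 2r (q={q}, r={r})")
    if variant == "gray-hancock":
        log = math.log(2.0 * q / r)
        c_par = 2.0 * math.pi * viscosity / (log - 0.5)
        c_perp = 4.0 * math.pi * viscosity / (log + 0.5)
    elif variant == "lighthill":
        c_par = 2.0 * math.pi * viscosity / math.log(0.36 * q / r)
        c_perp = 4.0 * math.pi * viscosity / (math.log(0.36 * q / r) + 0.5)
    else:
        raise ValueError(f"unknown coefficient variant {variant!r}")
    if c_par <= 0 or c_perp <= 0:
        raise ValueError("segment too thick for the chosen slender-body form")
    return c_par, c_perp


def segment_lateral_force(
    tangent: np.ndarray,
    midpoint: np.ndarray,
    length: float,
    flow: FlowSpec,
    coefficients: tuple[float, float],
) -> SegmentForce:
    """Lateral drag force on one segment and its torque about the z axis.

    The flow U·ẑ is decomposed along/perpendicular to the unit tangent;
    drag per unit length is C_par·U_par + C_perp·U_perp; only the
    component perpendicular to the flow direction contributes torque.
    Magnitude per unit length is (C_perp − C_par)·U·sinθ·cosθ.
    """
    tangent = np.asarray(tangent, dtype=float)
    if not length > 0:
        raise ValueError("zero-length segment")
    norm = np.linalg.norm(tangent)
    if norm == 0:
        raise ValueError("zero tangent vector")
    that = tangent / norm
    c_par, c_perp = coefficients
    u_vec = np.array([0.0, 0.0, flow.U * 1e-6])  # m/s
    u_par = (u_vec @ that) * that
    u_perp = u_vec - u_par
    f_per_len = c_par * u_par + c_perp * u_perp  # N/m
    force = f_per_len * (length * 1e-6)  # N
    lateral = force - np.array([0.0, 0.0, force[2]])
    lever = np.array([midpoint[0], midpoint[1], 0.0])  # μm
    torque_nm = np.cross(lever * 1e-6, lateral)[2]  # N·m
    return SegmentForce(
        force=lateral, lever_arm=lever, torque_z=torque_nm * PNUM_PER_NM
    )


def axial_torque(
    shape: EffectiveShape,
    flow: FlowSpec,
    variant: str = "gray-hancock",
    coefficients: tuple[float, float] | None = None,
) -> TorqueResult:
    """Total axial torque on a segmented shape under uniform axial flow.

    For each segment between consecutive control points the lateral drag
    force (resistive-force theory) is crossed with the segment
    midpoint's radial offset from the z axis; z components are summed.
    Segment radius is the mean of the endpoint radii.  A shape lying
    entirely on the axis (or in one plane containing it) gives zero.

    ``coefficients`` overrides the per-segment (C_par, C_perp), e.g. for
    refining the discretisation of one shape with the drag coefficients
    held fixed (segment length is not a meaningful slenderness scale for
    very fine subdivisions).
    """
    pts = shape.points
    if len(pts) < 2:
        raise ValueError("shape needs at least 2 points")
    segments: list[SegmentForce] = []
    total = 0.0
    for i in range(len(pts) - 1):
        seg = pts[i + 1] - pts[i]
        length = float(np.linalg.norm(seg))
        if length == 0:
            raise ValueError(f"zero-length segment {i}")
        if coefficients is None:
            radius = 0.5 * (shape.radii[i] + shape.radii[i + 1])
            coeff = resistive_coefficients(length, radius, flow.viscosity, variant)
        else:
            coeff = coefficients
        mid = 0.5 * (pts[i] + pts[i + 1])
        sf = segment_lateral_force(seg, mid, length, flow, coeff)
        segments.append(sf)
        total += sf.torque_z
    return TorqueResult(segments=segments, total=total)
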