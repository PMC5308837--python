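"""Analytical model of trypanosomatid cell movement and effective shape.

The lateral displacement of a swimming cell at position z along its long
axis is modelled as the sum of (i) displacement of an underlying
(possibly helical) shape rotating longitudinally at angular velocity
ω_r, and (ii) a planar sinusoid-like flagellar beat whose apparent
magnitude depends on the instantaneous orientation of the beat plane:

    x_r(z, t) = A_r(z) · sin(p_r(z) + ω_r·t)
    y_r(z, t) = A_r(z) · cos(p_r(z) + ω_r·t)
    b(z, t)   = A_b(z) · sin(p_b(z) + ω_b·t),      ω_b = 2π·f_b
    x_c(z, t) = x_r + b · sin(p_r(z) + p_o(z) + ω_r·t)
    y_c(z, t) = y_r + b · cos(p_r(z) + p_o(z) + ω_r·t)

Parameters are defined at 8 control points along the cell and linearly
interpolated between them.  This is a numerical description of movement,
not physically consistent kinematics (e.g. cell length is not preserved
over a beat cycle).  Setting A_b(z) ≡ 0 removes the beat and leaves the
*effective hydrodynamic shape* — the rotating centreline whose chirality
generates axial torque under flow.

Fitting x_c traces at the 8 z positions is exposed statsmodels-style:
``KymographModel(traces, times, z).fit()`` returns a
:class:`KymographFitResults` with parameter estimates, per-trace R² and
a ``summary()`` table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ShapeModelParams",
    "Kymograph",
    "EffectiveShape",
    "eval_model",
    "model_kymograph",
    "goodness_of_fit",
    "KymographModel",
    "KymographFitResults",
    "fit_model",
    "effective_shape",
]

N_CONTROL_POINTS = 8


@dataclass
class ShapeModelParams:
    """Movement-model parameters at 8 control points plus global rates.

    z : μm, strictly increasing control-point positions along the cell.
    A_r, p_r : rotation amplitude (μm) and phase (rad) per point.
    A_b, p_b : beat amplitude (μm) and phase (rad) per point.
    p_o : beat-plane orientation offset (rad) per point.
    omega_r : rad/s cell rotation angular velocity (global).
    f_b : Hz flagellar beat frequency (global); ω_b = 2π·f_b.
    width : μm cell width profile at the control points.

    Phases are stored on a continuous branch: adjacent control points
    should differ by < π after unwrapping, since values 2π apart fit any
    single kymograph equally well and only continuity across z picks the
    correct branch.
    """

    z: np.ndarray
    A_r: np.ndarray
    p_r: np.ndarray
    A_b: np.ndarray
    p_b: np.ndarray
    p_o: np.ndarray
    omega_r: float
    f_b: float
    width: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        for name in ("A_r", "p_r", "A_b", "p_b", "p_o"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.width is None:
            # default tapering profile (synthetic stand-in for image-derived widths)
            frac = (self.z - self.z[0]) / (self.z[-1] - self.z[0])
            self.width = 0.5 + 1.0 * np.sin(np.pi * np.clip(frac, 0, 1)) ** 0.5
        self.width = np.asarray(self.width, dtype=float)
        if np.any(np.diff(self.z) <= 0):
            raise ValueError("control point z values must be strictly increasing")
        if np.any(self.A_r < 0) or np.any(self.A_b < 0):
            raise ValueError("amplitudes must be >= 0")

    @property
    def omega_b(self) -> float:
        return 2.0 * np.pi * self.f_b

    def interp(self, z: np.ndarray) -> dict:
        z = np.asarray(z, dtype=float)
        if np.any(z < self.z[0] - 1e-9) or np.any(z > self.z[-1] + 1e-9):
            raise ValueError("z outside the control-point range")
        return {
            name: np.interp(z, self.z, getattr(self, name))
            for name in ("A_r", "p_r", "A_b", "p_b", "p_o")
        }

    def unwrap_phases(self) -> "ShapeModelParams":
        """Return a copy with p_r, p_b, p_o on continuous 2π branches.

        Also resolves the per-point (p_b, p_o) → (p_b+π, p_o+π) sign
        equivalence of the beat term (it flips b and the beat-plane
        direction simultaneously, leaving the trace unchanged) by
        choosing, point by point from z₁ outward, the branch that keeps
        p_o continuous.
        """
        p_b = self.p_b.copy()
        p_o = self.p_o.copy()
        for i in range(1, len(p_o)):
            delta = np.arctan2(np.sin(p_o[i] - p_o[i - 1]), np.cos(p_o[i] - p_o[i - 1]))
            if abs(delta) > np.pi / 2:
                p_b[i] += np.pi
                p_o[i] += np.pi
        return replace(
            self,
            p_r=np.unwrap(self.p_r),
            p_b=np.unwrap(p_b),
            p_o=np.unwrap(p_o),
            z=self.z.copy(),
            A_r=self.A_r.copy(),
            A_b=self.A_b.copy(),
            width=self.width.copy(),
        )

    # --- serialisation (one row per control point + a globals record) ---

    def to_json(self, path) -> None:
        payload = {
            "globals": {"omega_r": self.omega_r, "f_b": self.f_b},
            "control_points": [
                {
                    "z": float(self.z[i]),
                    "A_r": float(self.A_r[i]),
                    "p_r": float(self.p_r[i]),
                    "A_b": float(self.A_b[i]),
                    "p_b": float(self.p_b[i]),
                    "p_o": float(self.p_o[i]),
                    "width": float(self.width[i]),
                }
                for i in range(len(self.z))
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ShapeModelParams":
        with open(path) as fh:
            payload = json.load(fh)
        pts = pd.DataFrame(payload["control_points"])
        return cls(
            z=pts["z"].to_numpy(),
            A_r=pts["A_r"].to_numpy(),
            p_r=pts["p_r"].to_numpy(),
            A_b=pts["A_b"].to_numpy(),
            p_b=pts["p_b"].to_numpy(),
            p_o=pts["p_o"].to_numpy(),
            omega_r=float(payload["globals"]["omega_r"]),
            f_b=float(payload["globals"]["f_b"]),
            width=pts["width"].to_numpy() if "width" in pts else None,
        )


@dataclass
class Kymograph:
    """Lateral displacement at one z over uniformly sampled times."""

    z: float
    times: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.ptp(steps) > 1e-9 * steps[0]:
                raise ValueError("kymograph time sampling must be uniform")


@dataclass
class EffectiveShape:
    """3-D centreline at the control points, with segment radii.

    points : (8, 3) μm centreline coordinates (x, y, z).
    radii : (8,) μm = width/2 at each control point.
    """

    points: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("non-finite shape points")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")

    def mirrored(self) -> "EffectiveShape":
        """Reflection through the y–z plane (handedness flip)."""
        pts = self.points.copy()
        pts[:, 0] *= -1
        return EffectiveShape(points=pts, radii=self.radii.copy())


def eval_model(params: ShapeModelParams, z, t) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate (x_c, y_c) at position(s) z (μm) and time(s) t (s)."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    t = np.asarray(t, dtype=float)
    p = params.interp(z)
    wr_t = params.omega_r * t
    phase_r = p["p_r"][..., None] + wr_t if t.ndim else p["p_r"] + wr_t
    # broadcast control values against time
    A_r = p["A_r"][..., None] if t.ndim else p["A_r"]
    A_b = p["A_b"][..., None] if t.ndim else p["A_b"]
    p_b = p["p_b"][..., None] if t.ndim else p["p_b"]
    p_o = p["p_o"][..., None] if t.ndim else p["p_o"]
    x_r = A_r * np.sin(phase_r)
    y_r = A_r * np.cos(phase_r)
    beat = A_b * np.sin(p_b + params.omega_b * t)
    x_c = x_r + beat * np.sin(phase_r + p_o)
    y_c = y_r + beat * np.cos(phase_r + p_o)
    return np.squeeze(x_c), np.squeeze(y_c)


def model_kymograph(params: ShapeModelParams, z: float, times: np.ndarray) -> Kymograph:
    """Model trace of x_c(z, ·), e.g. at 200 Hz for overlay on images."""
    x_c, _ = eval_model(params, z, np.asarray(times, dtype=float))
    return Kymograph(z=float(z), times=np.asarray(times, dtype=float), x=np.atleast_1d(x_c))


def goodness_of_fit(model: np.ndarray, observed: np.ndarray) -> float:
    """R² = 1 − SS_res/SS_tot between a model trace and an observed one.

    Requires equal sampling.  A constant observed trace has zero total
    variance and R² is undefined (raises).
    """
    model = np.asarray(model, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if model.shape != observed.shape:
        raise ValueError("traces must share sampling")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("constant observed trace: R^2 undefined")
    ss_res = float(np.sum((observed - model) ** 2))
    return 1.0 - ss_res / ss_tot


class KymographModel:
    """Movement model to be fitted to observed kymograph traces.

    traces : sequence of :class:`Kymograph` (x_c traces at ≥ 2 distinct
        z positions, sharing a uniform time base).
    The time span should cover at least one full beat period for the
    frequencies to be identifiable.
    """

    def __init__(self, traces: Sequence[Kymograph]):
        if len(traces) < 2:
            raise ValueError("need traces at >= 2 distinct z positions")
        zs = [k.z for k in traces]
        if len(set(zs)) < 2:
            raise ValueError("traces must span >= 2 distinct z positions")
        self.traces = sorted(traces, key=lambda k: k.z)
        self.z = np.array([k.z for k in self.traces])

    # parameter vector layout: [A_r(8), p_r(8), A_b(8), p_b(8), p_o(8), omega_r, f_b]
    def _pack(self, params: ShapeModelParams) -> np.ndarray:
        return np.concatenate(
            [params.A_r, params.p_r, params.A_b, params.p_b, params.p_o,
             [params.omega_r, params.f_b]]
        )

    def _unpack(self, x: np.ndarray, z: np.ndarray, width) -> ShapeModelParams:
        n = len(z)
        return ShapeModelParams(
            z=z,
            A_r=np.abs(x[0:n]),
            p_r=x[n : 2 * n],
            A_b=np.abs(x[2 * n : 3 * n]),
            p_b=x[3 * n : 4 * n],
            p_o=x[4 * n : 5 * n],
            omega_r=x[5 * n],
            f_b=x[5 * n + 1],
            width=width,
        )

    def _residuals(self, x: np.ndarray, z_fit: np.ndarray) -> np.ndarray:
        params = self._unpack(x, z_fit, None)
        res = []
        for k in self.traces:
            x_c, _ = eval_model(params, k.z, k.times)
            res.append(np.atleast_1d(x_c) - k.x)
        return np.concatenate(res)

    # --- variable projection over the two frequencies -------------------
    #
    # With (ω_r, ω_b) fixed, the trace at each z is linear in sinusoid
    # coefficients: the beat term A_b sin(p_b+ω_b t)·sin(p_r+p_o+ω_r t)
    # expands into sidebands at ω_b ± ω_r, so
    #   x_c = A_r sin(ω_r t + p_r)
    #       + (A_b/2)·cos((ω_b−ω_r)t + ψ−) − (A_b/2)·cos((ω_b+ω_r)t + ψ+)
    # with ψ∓ = p_b ∓ (p_r + p_o).  The inner problem is solved by
    # linear least squares; the outer search is 2-D and well behaved.

    @staticmethod
    def _design(times: np.ndarray, wr: float, wb: float) -> np.ndarray:
        cols = []
        for w in (wr, wb - wr, wb + wr):
            cols.append(np.sin(w * times))
            cols.append(np.cos(w * times))
        return np.column_stack(cols)

    def _projected(self, wr: float, wb: float):
        """Linear inner solve at fixed frequencies; returns (rss, coeffs)."""
        rss = 0.0
        coeffs = []
        for k in self.traces:
            A = self._design(k.times, wr, wb)
            c, *_ = np.linalg.lstsq(A, k.x, rcond=None)
            r = k.x - A @ c
            rss += float(r @ r)
            coeffs.append(c)
        return rss, coeffs

    def _extract(self, coeffs, wr: float, wb: float, width) -> ShapeModelParams:
        """Per-point parameters from the sinusoid coefficients."""
        n = len(self.traces)
        A_r = np.empty(n)
        p_r = np.empty(n)
        A_b = np.empty(n)
        p_b = np.empty(n)
        p_o = np.empty(n)
        for i, c in enumerate(coeffs):
            a1, b1, am, bm, ap, bp = c
            A_r[i] = np.hypot(a1, b1)
            p_r[i] = np.arctan2(b1, a1)
            amp_m = np.hypot(am, bm)
            amp_p = np.hypot(ap, bp)
            A_b[i] = amp_m + amp_p
            psi_m = np.arctan2(-am, bm)  # (A_b/2)cos((wb−wr)t + ψ−)
            psi_p = np.arctan2(ap, -bp)  # −(A_b/2)cos((wb+wr)t + ψ+)
            p_b[i] = 0.5 * (psi_m + psi_p)
            p_o[i] = 0.5 * (psi_p - psi_m) - p_r[i]
        return ShapeModelParams(
            z=self.z.copy(), A_r=A_r, p_r=p_r, A_b=A_b, p_b=p_b, p_o=p_o,
            omega_r=wr, f_b=wb / (2.0 * np.pi), width=width,
        )

    def fit(
        self,
        start: ShapeModelParams,
        max_nfev: int = 2000,
        freq_search: float = 0.3,
        polish: bool = True,
    ) -> "KymographFitResults":
        """Fit all parameters from an initial guess.

        Automates the manual workflow (iterate parameters, watch R²).
        The two frequencies are located first by a grid scan within
        ±``freq_search`` (fractional) of the start values — the residual
        is oscillatory in frequency, so a pure local search from a
        perturbed guess stalls in a side lobe — then refined locally,
        with every other parameter solved linearly at fixed frequencies
        (variable projection).  A final joint local polish runs over the
        full parameter vector.  Phases are then unwrapped onto
        continuous 2π branches from the first control point outward.
        Non-convergence is reported on the results object with the
        best-so-far parameters rather than raised.
        """
        if not np.allclose(start.z, self.z):
            raise ValueError("start control points must match trace z positions")
        T = max(k.times[-1] - k.times[0] for k in self.traces)
        step = 0.25 * 2.0 * np.pi / T  # rad/s; quarter-cycle over the record
        wr0, wb0 = start.omega_r, start.omega_b

        # A cell that does not rotate over the record cannot constrain
        # A_r/p_r: the beat term can masquerade as "rotation" at
        # ω_r = ±ω_b and fit perfectly.  Pin ω_r in that case and flag.
        rotation_identifiable = abs(wr0) * T > 0.5

        def _grid(center: float) -> np.ndarray:
            half = abs(center) * freq_search
            if half < step:
                return np.array([center])
            offs = np.arange(-half, half + step / 2, step)
            return center + offs

        wr_grid = _grid(wr0) if rotation_identifiable else np.array([wr0])
        best = (np.inf, wr0, wb0)
        for wr in wr_grid:
            for wb in _grid(wb0):
                rss, _ = self._projected(wr, wb)
                if rss < best[0]:
                    best = (rss, wr, wb)
        _, wr, wb = best

        if rotation_identifiable:
            def _outer(x):
                return np.sqrt(self._projected(x[0], x[1])[0])

            sol_freq = least_squares(_outer, [wr, wb], diff_step=1e-6, max_nfev=200)
            wr, wb = sol_freq.x
        else:
            def _outer_b(x):
                return np.sqrt(self._projected(wr, x[0])[0])

            sol_freq = least_squares(_outer_b, [wb], diff_step=1e-6, max_nfev=200)
            wb = sol_freq.x[0]
        _, coeffs = self._projected(wr, wb)
        params = self._extract(coeffs, wr, wb, start.width)

        converged = True
        if polish and rotation_identifiable:
            sol = least_squares(
                self._residuals,
                self._pack(params),
                args=(self.z,),
                max_nfev=max_nfev,
                method="lm",
            )
            params = self._unpack(sol.x, self.z, start.width)
            converged = bool(sol.success)
        params = params.unwrap_phases()
        r2 = {}
        for k in self.traces:
            x_c, _ = eval_model(params, k.z, k.times)
            try:
                r2[k.z] = goodness_of_fit(np.atleast_1d(x_c), k.x)
            except ValueError:
                r2[k.z] = float("nan")
        if not rotation_identifiable:
            warnings.warn(
                "omega_r ~ 0: rotation amplitude/phase are not identifiable "
                "from a non-rotating cell",
                stacklevel=2,
            )
        return KymographFitResults(
            model=self,
            params=params,
            r_squared=r2,
            converged=converged,
            cost=float(0.5 * self._residuals(self._pack(params), self.z) @
                       self._residuals(self._pack(params), self.z)),
            nfev=int(sol_freq.nfev),
            rotation_identifiable=rotation_identifiable,
        )


@dataclass
class KymographFitResults:
    """Fit results: parameters, per-trace R² and diagnostics."""

    model: KymographModel
    params: ShapeModelParams
    r_squared: dict
    converged: bool
    cost: float
    nfev: int
    rotation_identifiable: bool

    @property
    def mean_r_squared(self) -> float:
        return float(np.nanmean(list(self.r_squared.values())))

    def summary(self) -> str:
        p = self.params
        lines = [
            "Cell movement model fit",
            "=" * 55,
            f"converged: {self.converged}   nfev: {self.nfev}   cost: {self.cost:.4g}",
            f"omega_r: {p.omega_r:.4f} rad/s   f_b: {p.f_b:.4f} Hz"
            f"   mean R^2: {self.mean_r_squared:.4f}",
            f"rotation identifiable: {self.rotation_identifiable}",
            "-" * 55,
            f"{'z':>7} {'A_r':>7} {'p_r':>7} {'A_b':>7} {'p_b':>7} {'p_o':>7} {'R^2':>7}",
        ]
        for i, z in enumerate(p.z):
            r2 = self.r_squared.get(float(z), float("nan"))
            lines.append(
                f"{z:7.2f} {p.A_r[i]:7.3f} {p.p_r[i]:7.3f} {p.A_b[i]:7.3f} "
                f"{p.p_b[i]:7.3f} {p.p_o[i]:7.3f} {r2:7.4f}"
            )
        return "\n".join(lines)


def fit_model(
    traces: Sequence[Kymograph], start: ShapeModelParams, **kwargs
) -> KymographFitResults:
    """Functional wrapper: ``KymographModel(traces).fit(start)``."""
    return KymographModel(traces).fit(start, **kwargs)


def effective_shape(params: ShapeModelParams, t: float = 0.0) -> EffectiveShape:
    """Effective hydrodynamic shape: the model with A_b(z) set to zero.

    The centreline at the control points is
    (A_r(z)·sin(p_r(z)+ω_r t), A_r(z)·cos(p_r(z)+ω_r t), z); changing t
    rigidly rotates it about the z axis without changing geometry.
    Segment radii come from width/2.
    """
    phase = params.p_r + params.omega_r * t
    points = np.column_stack(
        [params.A_r * np.sin(phase), params.A_r * np.cos(phase), params.z]
    )
    return EffectiveShape(points=points, radii=params.width / 2.0)
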