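"""Brownian-dynamics simulation of swimming cells with chiral rotation.

Each cell carries a position ``l`` and a right-handed orthonormal body
frame ``(t, n, b)`` with ``t`` the direction of travel (and long axis).
One Euler time step of length δt applies, in order:

1. translation by s·δt along t;
2. rotation of t and n about b by ω_κ·δt  (path curvature);
3. rotation of b and n about t by ω_τ·δt  (longitudinal rotation /
   path torsion);
4. optionally, Brownian motion: independent normal translations along
   t, n, b with standard deviations √(2D_dδt), √(2D_npδt), √(2D_npδt)
   and rotations about t, n, b with standard deviations √(2E_dδt),
   √(2E_npδt), √(2E_npδt), applied sequentially in that order about the
   instantaneous body axes.

The frame is re-orthonormalised every step.  Rotations are computed with
the axis–angle (Rodrigues) form, equivalent to unit-quaternion rotation.

Populations draw each cell's speed and angular velocities from normal
distributions, with three modes for curvature noise: ``fixed`` (ω_κ held
at its mean), ``per_cell`` (one draw per cell — morphogenetic noise) and
``rerandomized`` (redrawn at a fixed interval — propulsion noise).  Each
cell owns an independent RNG stream derived from (seed, cell index), so
results are reproducible and independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diffusion import DiffusionSet, Environment, SpheroidGeometry, rotational_diffusion
from .helix import PathKinematics

__all__ = [
    "CellState",
    "SimulationConfig",
    "PopulationSpec",
    "Trajectory",
    "PopulationResult",
    "step_cell",
    "simulate_cell",
    "simulate_population",
    "path_directionality",
]

_ORTHO_TOL = 1e-9


@dataclass
class CellState:
    """Position (μm) plus right-handed orthonormal frame (t, n, b)."""

    position: np.ndarray
    t: np.ndarray
    n: np.ndarray
    b: np.ndarray

    @classmethod
    def default(cls) -> "CellState":
        """At the origin, travelling along +x with n = +y, b = +z."""
        return cls(
            position=np.zeros(3),
            t=np.array([1.0, 0.0, 0.0]),
            n=np.array([0.0, 1.0, 0.0]),
            b=np.array([0.0, 0.0, 1.0]),
        )

    def validate(self) -> None:
        for v in (self.position, self.t, self.n, self.b):
            if not np.all(np.isfinite(v)):
                raise ValueError("non-finite cell state")
        for name, v in (("t", self.t), ("n", self.n), ("b", self.b)):
            if abs(np.linalg.norm(v) - 1.0) > _ORTHO_TOL:
                raise ValueError(f"{name} is not a unit vector")
        if abs(self.t @ self.n) > _ORTHO_TOL:
            raise ValueError("t and n are not orthogonal")
        if np.linalg.norm(np.cross(self.t, self.n) - self.b) > _ORTHO_TOL:
            raise ValueError("frame is not right-handed (b != t x n)")


@dataclass
class SimulationConfig:
    """Time stepping, environment and boundary settings.

    dt : s, Euler step (default 0.2 s — matches the 5 Hz frame interval).
    duration : s, must be an integer multiple of dt.
    brownian : include Brownian translation and rotation.
    volume : optional (Lx, Ly, Lz) extents in μm; with
        ``cyclic_boundaries`` positions wrap, and population initial
        positions/orientations are randomised inside the volume.
    """

    dt: float = 0.2
    duration: float = 102.4
    n_cells: int = 1
    brownian: bool = True
    environment: Environment = field(default_factory=Environment)
    spheroid: SpheroidGeometry = field(default_factory=SpheroidGeometry)
    perrin_mode: str = "divide"
    volume: Optional[tuple[float, float, float]] = None
    cyclic_boundaries: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        steps = self.duration / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("duration must be an integer multiple of dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def diffusion(self) -> DiffusionSet:
        return rotational_diffusion(self.spheroid, self.environment, self.perrin_mode)


@dataclass
class PopulationSpec:
    """Distributions of swimming parameters across a population.

    Each field is (mean, sd).  Speeds drawn ≤ 0 are redrawn.
    ``kappa_noise_mode``:
      - ``"fixed"``: ω_κ held at its mean for every cell (sd ignored);
      - ``"per_cell"``: one normal draw per cell;
      - ``"rerandomized"``: redrawn from the distribution every
        ``rerandomize_interval`` seconds.
    """

    speed: tuple[float, float] = (5.0, 2.0)
    omega_kappa: tuple[float, float] = (0.6, 0.2)
    omega_tau: tuple[float, float] = (11.0, 3.0)
    kappa_noise_mode: str = "fixed"
    rerandomize_interval: float = 0.2

    def __post_init__(self) -> None:
        for name in ("speed", "omega_kappa", "omega_tau"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name} sd must be >= 0, got {sd}")
        if self.kappa_noise_mode not in ("fixed", "per_cell", "rerandomized"):
            raise ValueError(f"unknown kappa_noise_mode {self.kappa_noise_mode!r}")
        if not self.rerandomize_interval > 0:
            raise ValueError("rerandomize_interval must be positive")


@dataclass
class Trajectory:
    """Uniformly sampled path of one simulated cell."""

    times: np.ndarray  # (T+1,)
    positions: np.ndarray  # (T+1, 3) μm
    t: np.ndarray  # (T+1, 3)
    n: np.ndarray
    b: np.ndarray
    kinematics: Optional[PathKinematics] = None

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def to_dataframe(self, cell_id: int = 0) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "cell_id": cell_id,
                "step": np.arange(len(self.times)),
                "time_s": self.times,
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
                "z_um": self.positions[:, 2],
            }
        )
        for name, arr in (("t", self.t), ("n", self.n), ("b", self.b)):
            for j, ax in enumerate("xyz"):
                df[f"{name}{ax}"] = arr[:, j]
        return df


@dataclass
class PopulationResult:
    """Ensemble of trajectories plus the kinematics drawn per cell.

    ``positions`` has shape (T+1, n_cells, 3); ``tangents`` (same shape)
    is stored when requested.  ``cells`` is a DataFrame with the drawn
    speed/ω_κ/ω_τ per cell.
    """

    times: np.ndarray
    positions: np.ndarray
    cells: pd.DataFrame
    config: SimulationConfig
    spec: PopulationSpec
    tangents: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return self.positions.shape[1]

    def directionality(self) -> np.ndarray:
        """Per-cell |l_end − l_start| / (s·T)."""
        disp = np.linalg.norm(self.positions[-1] - self.positions[0], axis=1)
        T = self.times[-1] - self.times[0]
        return disp / (self.cells["speed"].to_numpy() * T)

    def trajectory(self, i: int) -> Trajectory:
        kin = PathKinematics(
            speed=float(self.cells["speed"].iloc[i]),
            omega_kappa=abs(float(self.cells["omega_kappa"].iloc[i])),
            omega_tau=float(self.cells["omega_tau"].iloc[i]),
        )
        tan = self.tangents[:, i] if self.tangents is not None else np.full_like(self.positions[:, i], np.nan)
        return Trajectory(
            times=self.times,
            positions=self.positions[:, i],
            t=tan,
            n=np.full_like(tan, np.nan),
            b=np.full_like(tan, np.nan),
            kinematics=kin,
        )

    def to_dataframe(self) -> pd.DataFrame:
        T1, N, _ = self.positions.shape
        rec = {
            "cell_id": np.repeat(np.arange(N), T1),
            "step": np.tile(np.arange(T1), N),
            "time_s": np.tile(self.times, N),
        }
        pos = np.swapaxes(self.positions, 0, 1).reshape(-1, 3)
        rec.update({"x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2]})
        return pd.DataFrame(rec)


def _rotate(v: np.ndarray, axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation of rows of v about unit rows of axis by angle."""
    c = np.cos(angle)[..., None]
    s = np.sin(angle)[..., None]
    dot = np.sum(axis * v, axis=-1, keepdims=True)
    return v * c + np.cross(axis, v) * s + axis * dot * (1.0 - c)


def _renormalize(t: np.ndarray, n: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    t = t / np.linalg.norm(t, axis=-1, keepdims=True)
    n = n - np.sum(n * t, axis=-1, keepdims=True) * t
    n = n / np.linalg.norm(n, axis=-1, keepdims=True)
    return t, n, np.cross(t, n)


def _step_ensemble(pos, t, n, b, speed, w_kappa, w_tau, dt, noise=None, volume=None):
    """Advance an ensemble one Euler step.  Arrays are (N, 3) / (N,)."""
    pos = pos + speed[:, None] * dt * t
    # Deterministic frame rotation: curvature rotates (t, n) about b at
    # ω_κ and torsion rotates (b, n) about t at ω_τ.  For constant
    # body-frame angular velocity the exact one-step rotation is the
    # single rotation about the combined (Darboux) axis ω_τ·t + ω_κ·b by
    # |ω|·dt; sequential application of the two rotations agrees to
    # O(dt²) but biases the path at large per-step angles.
    w = w_tau[:, None] * t + w_kappa[:, None] * b
    w_norm = np.linalg.norm(w, axis=-1)
    active = w_norm > 0
    if np.any(active):
        axis = np.zeros_like(w)
        axis[active] = w[active] / w_norm[active, None]
        ang = w_norm * dt
        t = np.where(active[:, None], _rotate(t, axis, ang), t)
        n = np.where(active[:, None], _rotate(n, axis, ang), n)
        b = np.where(active[:, None], _rotate(b, axis, ang), b)
    if noise is not None:
        pos = pos + (
            noise[:, 0:1] * t + noise[:, 1:2] * n + noise[:, 2:3] * b
        )
        # Brownian rotations about the instantaneous body axes, in the
        # order t, n, b (error from non-commutation is O(dt²)).
        n = _rotate(n, t, noise[:, 3])
        b = _rotate(b, t, noise[:, 3])
        t = _rotate(t, n, noise[:, 4])
        b = _rotate(b, n, noise[:, 4])
        t = _rotate(t, b, noise[:, 5])
        n = _rotate(n, b, noise[:, 5])
    t, n, b = _renormalize(t, n)
    if volume is not None:
        pos = np.mod(pos, volume)
    return pos, t, n, b


def _noise_sds(cfg: SimulationConfig) -> np.ndarray:
    d = cfg.diffusion()
    dt = cfg.dt
    return np.sqrt(
        2.0
        * dt
        * np.array([d.D_d, d.D_np, d.D_np, d.E_d, d.E_np, d.E_np])
    )


def step_cell(
    state: CellState,
    kin: PathKinematics,
    cfg: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> CellState:
    """One Euler step of a single cell; returns a new :class:`CellState`."""
    state.validate()
    noise = None
    if cfg.brownian:
        if rng is None:
            raise ValueError("brownian stepping requires an rng")
        noise = (rng.standard_normal((1, 6)) * _noise_sds(cfg)[None, :])
    volume = np.asarray(cfg.volume, dtype=float) if (
        cfg.volume is not None and cfg.cyclic_boundaries
    ) else None
    pos, t, n, b = _step_ensemble(
        state.position[None, :],
        state.t[None, :],
        state.n[None, :],
        state.b[None, :],
        np.array([kin.speed]),
        np.array([kin.omega_kappa]),
        np.array([kin.omega_tau]),
        cfg.dt,
        noise=noise,
        volume=volume,
    )
    return CellState(position=pos[0], t=t[0], n=n[0], b=b[0])


def simulate_cell(
    kin: PathKinematics,
    cfg: SimulationConfig,
    initial: Optional[CellState] = None,
    rng: Optional[np.random.Generator] = None,
) -> Trajectory:
    """Simulate one cell for cfg.duration; deterministic given the rng/seed."""
    if initial is None:
        initial = CellState.default()
    initial.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n_steps = cfg.n_steps
    if n_steps == 0:
        raise ValueError("duration must cover at least one step")
    sds = _noise_sds(cfg) if cfg.brownian else None
    volume = np.asarray(cfg.volume, dtype=float) if (
        cfg.volume is not None and cfg.cyclic_boundaries
    ) else None

    pos = np.empty((n_steps + 1, 3))
    tt = np.empty((n_steps + 1, 3))
    nn = np.empty((n_steps + 1, 3))
    bb = np.empty((n_steps + 1, 3))
    pos[0], tt[0], nn[0], bb[0] = initial.position, initial.t, initial.n, initial.b
    p, t, n, b = (initial.position[None, :], initial.t[None, :],
                  initial.n[None, :], initial.b[None, :])
    speed = np.array([kin.speed])
    wk = np.array([kin.omega_kappa])
    wt = np.array([kin.omega_tau])
    for i in range(n_steps):
        noise = rng.standard_normal((1, 6)) * sds[None, :] if sds is not None else None
        p, t, n, b = _step_ensemble(p, t, n, b, speed, wk, wt, cfg.dt, noise, volume)
        pos[i + 1], tt[i + 1], nn[i + 1], bb[i + 1] = p[0], t[0], n[0], b[0]
    times = np.arange(n_steps + 1) * cfg.dt
    return Trajectory(times=times, positions=pos, t=tt, n=nn, b=bb, kinematics=kin)


def path_directionality(traj: Trajectory, speed: Optional[float] = None) -> float:
    """Net displacement per distance swum, |Δl|/(s·T)."""
    if traj.duration <= 0:
        raise ValueError("trajectory has zero duration")
    if speed is None:
        if traj.kinematics is None:
            raise ValueError("speed not given and trajectory has no kinematics")
        speed = traj.kinematics.speed
    disp = float(np.linalg.norm(traj.positions[-1] - traj.positions[0]))
    return disp / (speed * traj.duration)


def _draw_cell(
    rng: np.random.Generator, pop: PopulationSpec, cfg: SimulationConfig
) -> tuple[float, float, float, Optional[CellState]]:
    """Per-cell parameter draws, in a fixed documented order.

    Order: initial state (only when a volume is set), speed (redrawn
    while ≤ 0), ω_κ (mode-dependent), ω_τ.  Rerandomised ω_κ series are
    drawn lazily later from the same stream.
    """
    initial = None
    if cfg.volume is not None:
        lo = np.zeros(3)
        extents = np.asarray(cfg.volume, dtype=float)
        position = lo + rng.random(3) * extents
        # uniform random orientation: random t, then random n in its plane
        while True:
            v = rng.standard_normal(3)
            norm = np.linalg.norm(v)
            if norm > 1e-12:
                break
        t = v / norm
        while True:
            w = rng.standard_normal(3)
            w = w - (w @ t) * t
            norm = np.linalg.norm(w)
            if norm > 1e-12:
                break
        n = w / norm
        initial = CellState(position=position, t=t, n=n, b=np.cross(t, n))
    mean, sd = pop.speed
    if sd > 0:
        speed = rng.normal(mean, sd)
        while speed <= 0:  # truncate: negative speeds are redrawn
            speed = rng.normal(mean, sd)
    else:
        if mean < 0:
            raise ValueError("speed mean must be >= 0")
        speed = mean  # mean 0, sd 0: passive (diffusion-only) cells
    km, ks = pop.omega_kappa
    if pop.kappa_noise_mode == "fixed":
        w_kappa = km
    else:
        w_kappa = rng.normal(km, ks) if ks > 0 else km
    tm, ts = pop.omega_tau
    w_tau = rng.normal(tm, ts) if ts > 0 else tm
    return speed, w_kappa, w_tau, initial


def simulate_population(
    pop: PopulationSpec,
    cfg: SimulationConfig,
    store_positions: bool = True,
    store_tangents: bool = False,
) -> PopulationResult:
    """Simulate ``cfg.n_cells`` cells drawn from ``pop``.

    Each cell uses its own RNG stream seeded from (cfg.seed, cell index),
    so the result is independent of iteration order and the same seed
    and cell count always reproduce it exactly.  With
    ``store_positions=False`` only the first and last positions are kept
    (enough for directionality), which bounds memory for large runs.
    """
    N = cfg.n_cells
    if N < 1:
        raise ValueError("n_cells must be >= 1")
    n_steps = cfg.n_steps
    dt = cfg.dt
    sds = _noise_sds(cfg) if cfg.brownian else None
    volume = np.asarray(cfg.volume, dtype=float) if (
        cfg.volume is not None and cfg.cyclic_boundaries
    ) else None

    rngs = [np.random.default_rng(np.random.SeedSequence([cfg.seed, i])) for i in range(N)]
    speeds = np.empty(N)
    w_kappas = np.empty(N)
    w_taus = np.empty(N)
    pos = np.zeros((N, 3))
    t = np.tile(np.array([1.0, 0.0, 0.0]), (N, 1))
    n = np.tile(np.array([0.0, 1.0, 0.0]), (N, 1))
    b = np.tile(np.array([0.0, 0.0, 1.0]), (N, 1))
    for i, rng in enumerate(rngs):
        s_i, wk_i, wt_i, init = _draw_cell(rng, pop, cfg)
        speeds[i], w_kappas[i], w_taus[i] = s_i, wk_i, wt_i
        if init is not None:
            pos[i], t[i], n[i], b[i] = init.position, init.t, init.n, init.b

    # pre-draw Brownian noise per cell from its own stream
    noise_all = None
    if sds is not None:
        noise_all = np.empty((N, n_steps, 6))
        for i, rng in enumerate(rngs):
            noise_all[i] = rng.standard_normal((n_steps, 6)) * sds[None, :]

    rerandomize = pop.kappa_noise_mode == "rerandomized"
    if rerandomize:
        interval_steps = max(1, int(round(pop.rerandomize_interval / dt)))
        n_blocks = -(-n_steps // interval_steps)
        km, ks = pop.omega_kappa
        wk_blocks = np.empty((N, n_blocks))
        for i, rng in enumerate(rngs):
            # first block reuses the initial draw; subsequent blocks redrawn
            wk_blocks[i, 0] = w_kappas[i]
            if n_blocks > 1:
                wk_blocks[i, 1:] = rng.normal(km, ks, size=n_blocks - 1) if ks > 0 else km

    n_keep = n_steps + 1 if store_positions else 2
    positions = np.empty((n_keep, N, 3))
    positions[0] = pos
    tangents = None
    if store_tangents:
        tangents = np.empty((n_steps + 1, N, 3))
        tangents[0] = t

    for step in range(n_steps):
        wk = (
            wk_blocks[:, step // interval_steps] if rerandomize else w_kappas
        )
        noise = noise_all[:, step] if noise_all is not None else None
        # signed ω_κ: a negative draw curves the path the opposite way
        # about b (essential for re-randomised noise to stay unbiased)
        pos, t, n, b = _step_ensemble(
            pos, t, n, b, speeds, wk, w_taus, dt, noise, volume
        )
        if store_positions:
            positions[step + 1] = pos
        if store_tangents:
            tangents[step + 1] = t
    if not store_positions:
        positions[1] = pos

    times = (
        np.arange(n_steps + 1) * dt
        if store_positions
        else np.array([0.0, n_steps * dt])
    )
    cells = pd.DataFrame(
        {"cell_id": np.arange(N), "speed": speeds, "omega_kappa": w_kappas, "omega_tau": w_taus}
    )
    return PopulationResult(
        times=times,
        positions=positions,
        cells=cells,
        config=cfg,
        spec=pop,
        tangents=tangents,
    )
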