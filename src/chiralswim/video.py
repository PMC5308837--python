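"""Synthetic dark-field videomicrograph rendering.

Simulated 3-D trajectories are turned into multi-page 16-bit grayscale
image stacks that look like low-magnification dark-field movies: each
cell is a point-like bright spot (a Gaussian, broadened with defocus)
whose brightness is constant within ±``in_focus_halfwidth`` of the focal
plane and decays exponentially beyond it, emulating the measured
plateau-then-exponential detectability of cells away from focus.

Defaults emulate the acquisition geometry of the tracking experiments:
0.65 μm pixels, 5 Hz, 512 frames (102.4 s).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import tifffile

__all__ = ["OpticsModel", "ImageStack", "render_frame", "render_stack"]


@dataclass(frozen=True)
class OpticsModel:
    """Synthetic optics: geometry, depth-detectability and noise.

    pixel_size : μm/px.
    frame_rate : Hz.
    image_size : (height, width) px.
    focal_plane_z : μm, z of the focal plane in the simulation frame.
    in_focus_halfwidth : μm — plateau half-depth of full detectability.
    detectability_decay_length : μm — e-folding length of the spot
        amplitude beyond the plateau.
    psf_sigma0 : px — in-focus Gaussian spot sigma.
    psf_defocus_coefficient : px/μm — extra sigma per μm of defocus
        beyond the plateau.
    noise_model : "none", "gaussian" (sd = noise_sd counts) or "poisson".
    """

    pixel_size: float = 0.65
    frame_rate: float = 5.0
    image_size: tuple[int, int] = (512, 512)
    focal_plane_z: float = 0.0
    in_focus_halfwidth: float = 10.0
    detectability_decay_length: float = 5.0
    psf_sigma0: float = 2.0
    psf_defocus_coefficient: float = 0.2
    peak_intensity: float = 2000.0
    background_level: float = 100.0
    noise_model: str = "none"
    noise_sd: float = 20.0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.frame_rate <= 0:
            raise ValueError("pixel_size and frame_rate must be positive")
        if self.noise_model not in ("none", "gaussian", "poisson"):
            raise ValueError(f"unknown noise_model {self.noise_model!r}")

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    def defocus_amplitude(self, z: np.ndarray) -> np.ndarray:
        """Relative spot amplitude vs z: 1 on the plateau, exp decay beyond."""
        excess = np.maximum(np.abs(np.asarray(z, dtype=float) - self.focal_plane_z)
                            - self.in_focus_halfwidth, 0.0)
        return np.exp(-excess / self.detectability_decay_length)

    def spot_sigma(self, z: float) -> float:
        excess = max(abs(z - self.focal_plane_z) - self.in_focus_halfwidth, 0.0)
        return self.psf_sigma0 + self.psf_defocus_coefficient * excess


@dataclass
class ImageStack:
    """Time series of grayscale frames with acquisition metadata."""

    frames: np.ndarray  # (T, H, W) uint16
    optics: OpticsModel

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.optics.frame_rate

    def save_tiff(self, path) -> None:
        meta = {
            "pixel_size_um": self.optics.pixel_size,
            "frame_rate_hz": self.optics.frame_rate,
        }
        tifffile.imwrite(
            path,
            self.frames,
            photometric="minisblack",  # one grayscale page per frame
            description=json.dumps(meta),
        )

    @classmethod
    def load_tiff(cls, path, optics: Optional[OpticsModel] = None) -> "ImageStack":
        """Read any multi-page grayscale TIFF; metadata tags are optional."""
        with tifffile.TiffFile(path) as tif:
            frames = tif.asarray()
            desc = tif.pages[0].description
        if frames.ndim == 2:
            frames = frames[None, ...]
        if optics is None:
            kwargs = {"image_size": frames.shape[1:]}
            try:
                meta = json.loads(desc)
                kwargs["pixel_size"] = float(meta["pixel_size_um"])
                kwargs["frame_rate"] = float(meta["frame_rate_hz"])
            except (TypeError, ValueError, KeyError):
                pass
            optics = OpticsModel(**kwargs)
        return cls(frames=frames.astype(np.uint16), optics=optics)


def render_frame(
    positions: np.ndarray,
    optics: OpticsModel,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one frame from cell positions ((N, 3) μm) as uint16.

    Cells outside the field of view are simply not drawn.  Spot
    amplitude follows :meth:`OpticsModel.defocus_amplitude`; the spot
    sigma broadens with defocus.
    """
    positions = np.asarray(positions, dtype=float).reshape(-1, 3)
    if positions.size and not np.all(np.isfinite(positions)):
        raise ValueError("non-finite cell positions")
    H, W = optics.image_size
    img = np.full((H, W), optics.background_level, dtype=float)
    for x_um, y_um, z_um in positions:
        amp = optics.peak_intensity * float(optics.defocus_amplitude(z_um))
        if amp < 1e-3:
            continue
        sigma = optics.spot_sigma(z_um)
        cx = x_um / optics.pixel_size
        cy = y_um / optics.pixel_size
        r = int(np.ceil(4 * sigma))
        x0, x1 = int(np.floor(cx)) - r, int(np.floor(cx)) + r + 1
        y0, y1 = int(np.floor(cy)) - r, int(np.floor(cy)) + r + 1
        if x1 <= 0 or y1 <= 0 or x0 >= W or y0 >= H:
            continue
        x0c, x1c = max(x0, 0), min(x1, W)
        y0c, y1c = max(y0, 0), min(y1, H)
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c]
        img[y0c:y1c, x0c:x1c] += amp * np.exp(
            -((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)
        )
    if optics.noise_model == "gaussian":
        if rng is None:
            raise ValueError("gaussian noise requires an rng")
        img = img + rng.normal(0.0, optics.noise_sd, size=img.shape)
    elif optics.noise_model == "poisson":
        if rng is None:
            raise ValueError("poisson noise requires an rng")
        img = rng.poisson(np.maximum(img, 0.0)).astype(float)
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def render_stack(
    positions: np.ndarray,
    optics: OpticsModel,
    trajectory_dt: float,
    rng: Optional[np.random.Generator] = None,
) -> ImageStack:
    """Render a trajectory ensemble into an image stack.

    positions : (T+1, N, 3) μm, sampled every ``trajectory_dt`` seconds.
    The trajectory sampling interval must divide the frame interval
    (with δt = 0.2 s and 5 Hz they match exactly); the trajectory is
    subsampled to one frame per 1/frame_rate.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.ndim == 2:
        positions = positions[:, None, :]
    interval = optics.frame_interval
    ratio = interval / trajectory_dt
    if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
        raise ValueError(
            f"trajectory dt {trajectory_dt} s does not divide frame interval {interval} s"
        )
    stride = int(round(ratio))
    # one frame per 1/frame_rate: a trajectory of duration T yields
    # T * frame_rate frames (frames at t = 0 .. T - 1/frame_rate)
    n_frames = (positions.shape[0] - 1) // stride
    if n_frames < 1:
        raise ValueError("trajectory shorter than one frame interval")
    sub = positions[: n_frames * stride : stride]
    frames = np.empty((sub.shape[0], *optics.image_size), dtype=np.uint16)
    for i, pts in enumerate(sub):
        frames[i] = render_frame(pts, optics, rng=rng)
    return ImageStack(frames=frames, optics=optics)
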