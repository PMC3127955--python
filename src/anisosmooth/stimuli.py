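"""Gaussian luminance profile (GLP) stimuli and the adjustment-task design.

A GLP is an elliptical 2-D Gaussian luminance blob; its orientation is the
direction of the major principal axis of the luminance density.  The
adjustment experiment presents GLPs at twelve orientations (15-degree grid,
cardinals excluded) and three aspect ratios, under two viewing-frame
conditions, and the observer rotates a probe line to match the perceived
orientation.

All geometry is in degrees of visual angle; pixels appear only inside
:func:`render_glp`.  Radii are interpreted as standard deviations of the
Gaussian density, which makes covariance addition under smoothing exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .angles import wrap_orientation

__all__ = [
    "GLPSpec",
    "DesignSchedule",
    "InvalidStimulusError",
    "TruncationWarning",
    "glp_covariance",
    "make_glp",
    "build_schedule",
    "render_glp",
    "write_pgm",
]

#: Display geometry of the original apparatus, retained as config constants
#: only (all computation is in degrees of visual angle).
DISPLAY_CONSTANTS = {
    "viewing_distance_cm": 40.0,
    "resolution_px": (1024, 768),
    "center_luminance_cd_m2": 2.70,
    "background_luminance_cd_m2": 1.54,
}

DEFAULT_ORIENTATIONS = tuple(7.5 + 15.0 * k for k in range(12))
DEFAULT_ASPECT_RATIOS = (0.5, 0.65, 0.8)
DEFAULT_MAJOR_RADIUS = 1.9


class InvalidStimulusError(ValueError):
    """A GLP specification with degenerate or inconsistent geometry."""


class TruncationWarning(UserWarning):
    """Rendered extent does not contain the 4-sigma support of the GLP."""


@dataclass(frozen=True)
class GLPSpec:
    """An elongated 2-D Gaussian luminance profile.

    ``major_radius`` and ``minor_radius`` are the standard deviations along
    the principal axes (degrees of visual angle); ``orientation`` is the
    direction of the major axis, counterclockwise from horizontal, reduced
    modulo 180.  ``amplitude`` is the peak luminance above ``background``
    (arbitrary units).
    """

    major_radius: float
    minor_radius: float
    orientation: float
    amplitude: float = 1.0
    background: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not (self.minor_radius > 0.0 and self.major_radius > 0.0):
            raise InvalidStimulusError(
                f"radii must be positive, got major={self.major_radius}, "
                f"minor={self.minor_radius}"
            )
        if self.minor_radius > self.major_radius:
            raise InvalidStimulusError(
                f"minor radius {self.minor_radius} exceeds major radius "
                f"{self.major_radius}"
            )
        object.__setattr__(self, "orientation", wrap_orientation(self.orientation))
        object.__setattr__(self, "center", tuple(float(c) for c in self.center))

    @property
    def aspect_ratio(self) -> float:
        """minor_radius / major_radius, in (0, 1]."""
        return self.minor_radius / self.major_radius


def make_glp(
    aspect_ratio: float,
    orientation: float,
    major_radius: float = DEFAULT_MAJOR_RADIUS,
    **kwargs,
) -> GLPSpec:
    """Convenience constructor from (aspect ratio, orientation)."""
    return GLPSpec(
        major_radius=major_radius,
        minor_radius=aspect_ratio * major_radius,
        orientation=orientation,
        **kwargs,
    )


def glp_covariance(glp: GLPSpec) -> np.ndarray:
    """Covariance matrix (degrees squared) of the GLP's Gaussian density.

    ``R(theta) @ diag(major**2, minor**2) @ R(theta).T`` — symmetric positive
    definite with trace ``major**2 + minor**2``.
    """
    th = math.radians(glp.orientation)
    c, s = math.cos(th), math.sin(th)
    rot = np.array([[c, -s], [s, c]])
    return rot @ np.diag([glp.major_radius**2, glp.minor_radius**2]) @ rot.T


@dataclass(frozen=True)
class DesignSchedule:
    """Factorial design of the adjustment experiment.

    Defaults reproduce the study design: 12 orientations x 3 aspect ratios
    x 2 frame conditions x 3 blocks x 5 repetitions = 1080 trials per
    participant; the frame (circular vs square viewing aperture) is a
    control label with no effect in the generator.
    """

    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS
    aspect_ratios: tuple[float, ...] = DEFAULT_ASPECT_RATIOS
    frame_conditions: tuple[str, ...] = ("circular", "square")
    blocks_per_session: int = 3
    reps_per_block: int = 5
    participants: int = 6
    major_radius: float = DEFAULT_MAJOR_RADIUS

    def __post_init__(self) -> None:
        if min(self.blocks_per_session, self.reps_per_block, self.participants) < 1:
            raise ValueError("all design counts must be positive")
        if not self.orientations or not self.aspect_ratios or not self.frame_conditions:
            raise ValueError("design factors must be non-empty")

    @property
    def trials_per_block(self) -> int:
        return len(self.orientations) * len(self.aspect_ratios) * self.reps_per_block

    @property
    def trials_per_participant(self) -> int:
        return (
            len(self.frame_conditions)
            * self.blocks_per_session
            * self.trials_per_block
        )


def build_schedule(design: DesignSchedule, seed: int) -> pd.DataFrame:
    """Ordered trial stubs for every participant of the design.

    Within each block every (orientation, aspect ratio) cell appears
    ``reps_per_block`` times in a seeded uniform-random order.  Columns:
    ``participant, frame, block, trial, orientation_deg, aspect_ratio``.
    """
    cells = [
        (o, a)
        for _ in range(design.reps_per_block)
        for o in design.orientations
        for a in design.aspect_ratios
    ]
    frames: list[dict] = []
    for p in range(design.participants):
        for fi, frame in enumerate(design.frame_conditions):
            for b in range(design.blocks_per_session):
                rng = np.random.default_rng([int(seed), p, fi, b])
                order = rng.permutation(len(cells))
                frames.append(
                    pd.DataFrame(
                        {
                            "participant": p,
                            "frame": frame,
                            "block": b,
                            "trial": np.arange(len(cells)),
                            "orientation_deg": [cells[i][0] for i in order],
                            "aspect_ratio": [cells[i][1] for i in order],
                        }
                    )
                )
    return pd.concat(frames, ignore_index=True)


def render_glp(
    glp: GLPSpec,
    resolution: float = 32.0,
    extent: float | None = None,
    noise_fraction: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Render a GLP to a luminance image.

    Pixel value = ``background + amplitude * exp(-0.5 d' Sigma^-1 d)`` plus
    zero-mean uniform pixel noise of peak-to-peak width
    ``noise_fraction * amplitude`` (the luminance range of the GLP).  The
    image is square with side ``extent`` degrees (default: 8 major radii,
    the 4-sigma support); the first axis is y increasing upward, matching
    :func:`anisosmooth.scalespace.pixel_coords`.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    if extent is None:
        extent = 8.0 * glp.major_radius
    if extent < 8.0 * glp.major_radius:
        warnings.warn(
            f"extent {extent} deg does not contain the 4-sigma support "
            f"({8 * glp.major_radius} deg); moments will be truncated",
            TruncationWarning,
            stacklevel=2,
        )
    n = int(round(extent * resolution))
    coords = (np.arange(n) - (n - 1) / 2.0) / resolution
    x, y = np.meshgrid(coords, coords)
    inv = np.linalg.inv(glp_covariance(glp))
    dx = x - glp.center[0]
    dy = y - glp.center[1]
    q = inv[0, 0] * dx**2 + 2.0 * inv[0, 1] * dx * dy + inv[1, 1] * dy**2
    image = glp.background + glp.amplitude * np.exp(-0.5 * q)
    if noise_fraction > 0.0:
        rng = np.random.default_rng(seed)
        image = image + (rng.random(image.shape) - 0.5) * noise_fraction * glp.amplitude
    return image


def write_pgm(
    path,
    image: np.ndarray,
    resolution: float,
    extent: float,
    maxval: int = 65535,
) -> None:
    """Write an image as plain-text PGM (P2) with grid metadata in a comment."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    scale = (maxval / (hi - lo)) if hi > lo else 0.0
    quantized = np.rint((img - lo) * scale).astype(int)
    with open(path, "w") as fh:
        fh.write("P2\n")
        fh.write(f"# px_per_deg={resolution} extent_deg={extent}\n")
        fh.write(f"{img.shape[1]} {img.shape[0]}\n{maxval}\n")
        for row in quantized[::-1]:  # top raster row = largest y
            fh.write(" ".join(str(v) for v in row) + "\n")
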