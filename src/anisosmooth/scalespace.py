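"""Elliptical Gaussian scale-space smoothing.

The visual system is modelled as observing images at finite resolution:
the retinal image is convolved with a Gaussian kernel.  Here the kernel is
an *elliptical* Gaussian, typically elongated vertically (a_h < a_v), which
makes the effective resolution anisotropic.  Because the convolution of two
Gaussians is again a Gaussian whose covariance is the sum of the two input
covariances, smoothing a Gaussian luminance profile reduces to a single
2x2 matrix addition; the perceived orientation is the principal axis of the
summed covariance.

This module provides both the analytic route (covariance addition +
principal-axis extraction) and an independent numeric route (discrete
convolution of rendered images + second central moments) that serves as an
oracle for the analytic one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .angles import wrap_orientation

__all__ = [
    "KernelSpec",
    "InvalidCovarianceError",
    "UndersampledKernelError",
    "smooth_covariance",
    "orientation_of",
    "is_degenerate_orientation",
    "sample_kernel",
    "numeric_convolve",
    "pixel_coords",
    "image_moments",
]

# Relative eccentricity below which a covariance is treated as isotropic and
# its principal-axis orientation as undefined.
_DEGENERACY_RTOL = 1e-12


class InvalidCovarianceError(ValueError):
    """A matrix that is not a valid (symmetric, PSD) 2x2 covariance."""


class UndersampledKernelError(ValueError):
    """Kernel standard deviation below one pixel at the requested resolution."""


@dataclass(frozen=True)
class KernelSpec:
    """An elliptical Gaussian smoothing aperture.

    Parameters
    ----------
    a_h, a_v:
        Horizontal and vertical radii (standard deviations) of the Gaussian
        aperture, in degrees of visual angle.
    r:
        Covariance term in degrees squared.  ``r = 0`` gives an axis-aligned
        kernel; a nonzero ``r`` tilts the kernel's principal axes.

    The covariance matrix of the kernel is ``[[a_h**2, r], [r, a_v**2]]``,
    which must be positive definite (``|r| < a_h * a_v``).
    """

    a_h: float
    a_v: float
    r: float = 0.0

    def __post_init__(self) -> None:
        if not (self.a_h > 0.0 and self.a_v > 0.0):
            raise ValueError(
                f"kernel radii must be positive, got a_h={self.a_h}, a_v={self.a_v}"
            )
        if not abs(self.r) < self.a_h * self.a_v:
            raise ValueError(
                f"|r|={abs(self.r)} must be < a_h*a_v={self.a_h * self.a_v} "
                "for a positive-definite kernel covariance"
            )

    @property
    def covariance(self) -> np.ndarray:
        """2x2 covariance matrix of the kernel, degrees squared."""
        return np.array(
            [[self.a_h**2, self.r], [self.r, self.a_v**2]], dtype=float
        )

    @classmethod
    def from_principal(
        cls, radius1: float, radius2: float, phi_deg: float
    ) -> "KernelSpec":
        """Build a kernel from principal radii and the orientation of radius1.

        ``radius1`` is the standard deviation along the axis at ``phi_deg``
        (counterclockwise from horizontal), ``radius2`` the one orthogonal
        to it.
        """
        phi = math.radians(phi_deg)
        c, s = math.cos(phi), math.sin(phi)
        rot = np.array([[c, -s], [s, c]])
        cov = rot @ np.diag([radius1**2, radius2**2]) @ rot.T
        return cls(a_h=math.sqrt(cov[0, 0]), a_v=math.sqrt(cov[1, 1]), r=cov[0, 1])

    def to_principal(self) -> tuple[float, float, float]:
        """Return (major_radius, minor_radius, phi_deg of the major axis).

        For an isotropic kernel the orientation is undefined and NaN is
        returned for ``phi_deg``.
        """
        evals = np.linalg.eigvalsh(self.covariance)  # ascending
        phi = orientation_of(self.covariance)
        return float(math.sqrt(evals[1])), float(math.sqrt(evals[0])), phi


def _check_covariance(cov: np.ndarray, *, psd: bool = True) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (2, 2):
        raise InvalidCovarianceError(f"expected a 2x2 matrix, got shape {cov.shape}")
    if not np.isfinite(cov).all():
        raise InvalidCovarianceError("covariance contains non-finite entries")
    scale = max(abs(cov).max(), 1.0)
    if abs(cov[0, 1] - cov[1, 0]) > 1e-9 * scale:
        raise InvalidCovarianceError(f"covariance is not symmetric: {cov!r}")
    if psd:
        tr = cov[0, 0] + cov[1, 1]
        det = cov[0, 0] * cov[1, 1] - cov[0, 1] * cov[1, 0]
        if cov[0, 0] < -1e-12 * scale or cov[1, 1] < -1e-12 * scale or det < -1e-9 * scale**2:
            raise InvalidCovarianceError(f"covariance is not positive semidefinite: {cov!r}")
    return cov


def smooth_covariance(glp_cov: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Covariance of a Gaussian profile after Gaussian smoothing.

    Convolving two Gaussian densities adds their covariance matrices, so the
    smoothed (perceived) profile has covariance ``glp_cov + kernel.covariance``.
    """
    glp_cov = _check_covariance(glp_cov)
    return glp_cov + kernel.covariance


def orientation_of(cov: np.ndarray) -> float:
    """Orientation of the principal (largest-variance) axis, degrees in [0, 180).

    Computed as ``0.5 * atan2(2*s_xy, s_xx - s_yy)``.  For an isotropic
    covariance the principal axis is undefined; NaN is returned as a
    degeneracy sentinel (see :func:`is_degenerate_orientation`).
    """
    cov = _check_covariance(cov)
    num = 2.0 * cov[0, 1]
    den = cov[0, 0] - cov[1, 1]
    trace = cov[0, 0] + cov[1, 1]
    if math.hypot(num, den) <= _DEGENERACY_RTOL * max(trace, 1e-300):
        return float("nan")
    return wrap_orientation(0.5 * math.degrees(math.atan2(num, den)))


def is_degenerate_orientation(angle: float) -> bool:
    """True if ``angle`` is the NaN sentinel returned for isotropic covariances."""
    return bool(np.isnan(angle))


def pixel_coords(n: int, resolution: float) -> np.ndarray:
    """Coordinates (degrees) of ``n`` pixel centers, symmetric about zero.

    The same convention is used for rendering and for moment estimation so
    that the two stay aligned; the first image axis is y, increasing upward.
    """
    return (np.arange(n) - (n - 1) / 2.0) / float(resolution)


def sample_kernel(kernel: KernelSpec, resolution: float) -> np.ndarray:
    """Sample a unit-mass elliptical Gaussian on the pixel grid.

    The support is truncated at 4 standard deviations of the *largest*
    principal radius and the discrete kernel renormalized to sum to one, so
    that convolution conserves total image mass.
    """
    major, minor, _ = kernel.to_principal()
    if minor * resolution < 1.0:
        raise UndersampledKernelError(
            f"kernel SD {minor:.3g} deg is below one pixel at {resolution} px/deg"
        )
    half = int(math.ceil(4.0 * major * resolution))
    coords = np.arange(-half, half + 1) / float(resolution)
    x, y = np.meshgrid(coords, coords)
    inv = np.linalg.inv(kernel.covariance)
    q = inv[0, 0] * x**2 + 2.0 * inv[0, 1] * x * y + inv[1, 1] * y**2
    k = np.exp(-0.5 * q)
    return k / k.sum()


def numeric_convolve(
    image: np.ndarray, kernel: KernelSpec, resolution: float
) -> np.ndarray:
    """Discrete linear convolution of an image with a sampled Gaussian kernel.

    Returns the full linear convolution (the output grows by the kernel
    support), so no mass is lost at the borders; the centered pixel-grid
    convention of :func:`pixel_coords` still applies to the output.
    """
    k = sample_kernel(kernel, resolution)
    return signal.fftconvolve(np.asarray(image, dtype=float), k, mode="full")


def image_moments(
    image: np.ndarray, resolution: float, background: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and second central moments of an image treated as a density.

    ``image - background`` is used as the (unnormalized) density.  Returns
    ``(centroid, cov)`` in degrees / degrees squared on the centered grid of
    :func:`pixel_coords`.
    """
    w = np.asarray(image, dtype=float) - background
    total = w.sum()
    if total <= 0:
        raise ValueError("image has no mass above background")
    ys = pixel_coords(w.shape[0], resolution)
    xs = pixel_coords(w.shape[1], resolution)
    x, y = np.meshgrid(xs, ys)
    mx = (w * x).sum() / total
    my = (w * y).sum() / total
    dx, dy = x - mx, y - my
    sxx = (w * dx * dx).sum() / total
    syy = (w * dy * dy).sum() / total
    sxy = (w * dx * dy).sum() / total
    return np.array([mx, my]), np.array([[sxx, sxy], [sxy, syy]])
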