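"""Predicted orientation biases under nested anisotropic-smoothing models.

Smoothing an elongated Gaussian luminance profile (GLP) with an elliptical
Gaussian kernel rotates the principal axis of the perceived profile.  With a
vertically elongated kernel (a_h < a_v) the perceived orientation is pulled
toward vertical: the bias is positive (counterclockwise) for stimulus
orientations in (0, 90) and negative in (90, 180), and vanishes at the
cardinals and for isotropic kernels.

Model hierarchy (each earlier model nested in the later ones):

- ``isotropic``              — a_h = a_v; predicts zero bias, 0 free parameters.
- ``homogeneous``            — one (a_h, a_v) kernel everywhere; 2 parameters.
- ``homogeneous_oriented``   — one (a_h, a_v, r) kernel (r tilts it); 3.
- ``radial_heterogeneous``   — one (a_h, a_v) per stimulus thickness; 6.
- ``angular_heterogeneous``  — one (a_h, a_v, r) per stimulus-orientation
  subset; 36 parameters on the raw 12-orientation grid, 18 after mirror-pair
  aggregation to 6 orientations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np

from .angles import canonical_orientation, wrap_bias
from .scalespace import KernelSpec, orientation_of, smooth_covariance
from .stimuli import (
    DEFAULT_ASPECT_RATIOS,
    DEFAULT_MAJOR_RADIUS,
    DEFAULT_ORIENTATIONS,
    GLPSpec,
    glp_covariance,
)

__all__ = [
    "MODEL_KINDS",
    "ConditionGrid",
    "ModelSpec",
    "ModelSpecificationError",
    "DegenerateOrientationWarning",
    "predict_bias",
    "predict_grid",
    "predict_for_conditions",
    "model_to_json",
    "model_from_json",
]

MODEL_KINDS = (
    "isotropic",
    "homogeneous",
    "homogeneous_oriented",
    "radial_heterogeneous",
    "angular_heterogeneous",
)

#: free parameters per kernel group
_PARAMS_PER_GROUP = {
    "isotropic": 0,
    "homogeneous": 2,
    "homogeneous_oriented": 3,
    "radial_heterogeneous": 2,
    "angular_heterogeneous": 3,
}


class ModelSpecificationError(ValueError):
    """A condition not covered by any kernel group of the model."""


class DegenerateOrientationWarning(UserWarning):
    """The smoothed covariance is isotropic; bias is reported as zero."""


@dataclass(frozen=True)
class ConditionGrid:
    """The (orientation, aspect ratio) cells a model predicts for.

    ``aggregated=True`` means the grid holds only the canonical member of
    each mirror pair (orientations in (0, 90)); biases at the mirrored
    member are the negatives of the canonical ones.
    """

    cells: tuple[tuple[float, float], ...]
    major_radius: float = DEFAULT_MAJOR_RADIUS
    aggregated: bool = False

    def __post_init__(self) -> None:
        if len(set(self.cells)) != len(self.cells):
            raise ValueError("grid cells must be unique")

    @classmethod
    def default(cls, aggregated: bool = False) -> "ConditionGrid":
        """The experiment's grid: 12 (or 6 aggregated) orientations x 3 ratios."""
        if aggregated:
            orientations = tuple(o for o in DEFAULT_ORIENTATIONS if o < 90.0)
        else:
            orientations = DEFAULT_ORIENTATIONS
        cells = tuple((o, a) for o in orientations for a in DEFAULT_ASPECT_RATIOS)
        return cls(cells=cells, aggregated=aggregated)

    @property
    def orientations(self) -> tuple[float, ...]:
        return tuple(sorted({c[0] for c in self.cells}))

    @property
    def aspect_ratios(self) -> tuple[float, ...]:
        return tuple(sorted({c[1] for c in self.cells}))


def _bias_core(theta_deg, major, minor, a_h, a_v, r):
    """Vectorized bias of GLP(major, minor, theta) under kernel (a_h, a_v, r).

    Returns the signed bias in (-90, 90]; isotropic smoothed covariances
    (undefined principal axis) yield 0.
    """
    theta = np.radians(np.asarray(theta_deg, dtype=float))
    major2 = np.asarray(major, dtype=float) ** 2
    minor2 = np.asarray(minor, dtype=float) ** 2
    c, s = np.cos(theta), np.sin(theta)
    cxx = major2 * c**2 + minor2 * s**2
    cyy = major2 * s**2 + minor2 * c**2
    cxy = (major2 - minor2) * c * s
    sxx = cxx + np.asarray(a_h, dtype=float) ** 2
    syy = cyy + np.asarray(a_v, dtype=float) ** 2
    sxy = cxy + np.asarray(r, dtype=float)
    num = 2.0 * sxy
    den = sxx - syy
    degenerate = np.hypot(num, den) <= 1e-12 * (sxx + syy)
    perceived = 0.5 * np.degrees(np.arctan2(num, den))
    bias = wrap_bias(perceived - np.asarray(theta_deg, dtype=float))
    return np.where(degenerate, 0.0, bias)


def predict_bias(glp: GLPSpec, kernel: KernelSpec) -> float:
    """Signed perceived-orientation bias of one GLP under one kernel.

    The perceived orientation is the principal axis of
    ``glp_covariance(glp) + kernel.covariance``; the bias is its difference
    from the physical orientation, wrapped to (-90, 90], counterclockwise
    positive.  A degenerate (isotropic) smoothed covariance gives bias 0
    with a :class:`DegenerateOrientationWarning`.
    """
    smoothed = smooth_covariance(glp_covariance(glp), kernel)
    perceived = orientation_of(smoothed)
    if np.isnan(perceived):
        warnings.warn(
            "smoothed covariance is isotropic; orientation undefined, bias set to 0",
            DegenerateOrientationWarning,
            stacklevel=2,
        )
        return 0.0
    return wrap_bias(perceived - glp.orientation)


@dataclass
class ModelSpec:
    """One of the nested smoothing models, with its kernel-group layout.

    ``group_labels`` identifies the condition subsets sharing a kernel
    (a single ``"all"`` group, the aspect ratios, or the orientation
    labels); ``params`` is the flat parameter vector, ``params_per_group``
    consecutive entries per group in ``group_labels`` order, each group laid
    out as ``(a_h, a_v)`` or ``(a_h, a_v, r)``.
    """

    kind: str
    group_labels: tuple = ("all",)
    major_radius: float = DEFAULT_MAJOR_RADIUS
    canonical: bool = False
    params: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.params is not None:
            self.params = np.asarray(self.params, dtype=float)
            if self.params.size != self.n_free:
                raise ValueError(
                    f"expected {self.n_free} parameters for {self.kind} with "
                    f"{len(self.group_labels)} groups, got {self.params.size}"
                )

    @classmethod
    def for_grid(cls, kind: str, grid: ConditionGrid) -> "ModelSpec":
        """Build the model's group layout for a condition grid."""
        if kind in ("isotropic", "homogeneous", "homogeneous_oriented"):
            labels: tuple = ("all",)
        elif kind == "radial_heterogeneous":
            labels = grid.aspect_ratios
        elif kind == "angular_heterogeneous":
            labels = grid.orientations
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        return cls(
            kind=kind,
            group_labels=labels,
            major_radius=grid.major_radius,
            canonical=grid.aggregated,
        )

    @property
    def params_per_group(self) -> int:
        return _PARAMS_PER_GROUP[self.kind]

    @property
    def n_free(self) -> int:
        """Free parameters: 0 / 2 / 3, or 2-3 per group for grouped models."""
        return self.params_per_group * len(self.group_labels)

    def group_index(self, orientation_deg: float, aspect_ratio: float) -> int:
        """Index of the kernel group covering a condition."""
        if self.kind in ("isotropic", "homogeneous", "homogeneous_oriented"):
            return 0
        if self.kind == "radial_heterogeneous":
            key, values = aspect_ratio, self.group_labels
        else:  # angular_heterogeneous
            key = orientation_deg
            if self.canonical:
                key, _ = canonical_orientation(key)
            values = self.group_labels
        matches = np.flatnonzero(np.isclose(values, key, atol=1e-9))
        if matches.size == 0:
            raise ModelSpecificationError(
                f"condition (orientation={orientation_deg}, "
                f"aspect_ratio={aspect_ratio}) not covered by {self.kind} "
                f"groups {self.group_labels}"
            )
        return int(matches[0])

    def kernel_for_group(self, index: int) -> KernelSpec | None:
        """Kernel of one group (None for the isotropic reference model)."""
        if self.kind == "isotropic":
            return None
        if self.params is None:
            raise ValueError("model parameters are not set")
        ppg = self.params_per_group
        block = self.params[index * ppg : (index + 1) * ppg]
        r = float(block[2]) if ppg == 3 else 0.0
        return KernelSpec(a_h=float(block[0]), a_v=float(block[1]), r=r)


def predict_grid(model: ModelSpec, grid: ConditionGrid) -> np.ndarray:
    """Predicted bias for every cell of ``grid`` under ``model``.

    Grouped models must cover every cell; the isotropic reference predicts
    zero bias everywhere.
    """
    theta = np.array([c[0] for c in grid.cells], dtype=float)
    ratio = np.array([c[1] for c in grid.cells], dtype=float)
    return predict_for_conditions(model, theta, ratio, major_radius=grid.major_radius)


def predict_for_conditions(
    model: ModelSpec,
    orientation_deg,
    aspect_ratio,
    major_radius: float | None = None,
) -> np.ndarray:
    """Vectorized bias predictions for arbitrary condition arrays.

    For a model fitted on the aggregated (canonical) grid, predictions at a
    mirrored orientation (theta > 90) are computed on the canonical member
    and sign-flipped, consistent with the mirror-pair aggregation rule.
    """
    theta = np.atleast_1d(np.asarray(orientation_deg, dtype=float))
    ratio = np.atleast_1d(np.asarray(aspect_ratio, dtype=float))
    theta, ratio = np.broadcast_arrays(theta, ratio)
    major = model.major_radius if major_radius is None else major_radius
    if model.kind == "isotropic":
        return np.zeros(theta.shape)

    if model.canonical:
        theta_eval, sign = canonical_orientation(theta)
    else:
        theta_eval, sign = theta, np.ones_like(theta)

    out = np.empty(theta.shape, dtype=float)
    groups = np.array(
        [model.group_index(t, a) for t, a in zip(theta.ravel(), ratio.ravel())]
    ).reshape(theta.shape)
    for g in np.unique(groups):
        kernel = model.kernel_for_group(int(g))
        mask = groups == g
        out[mask] = _bias_core(
            theta_eval[mask],
            major,
            ratio[mask] * major,
            kernel.a_h,
            kernel.a_v,
            kernel.r,
        )
    return sign * out


def model_to_json(model: ModelSpec) -> str:
    """Serialize a model and its parameter vector with an explicit layout."""
    return json.dumps(
        {
            "kind": model.kind,
            "group_labels": list(model.group_labels),
            "major_radius": model.major_radius,
            "canonical": model.canonical,
            "params_per_group": model.params_per_group,
            "param_layout": ["a_h", "a_v", "r"][: model.params_per_group],
            "params": None if model.params is None else model.params.tolist(),
        },
        indent=2,
    )


def model_from_json(text: str) -> ModelSpec:
    data = json.loads(text)
    labels = tuple(
        lab if isinstance(lab, str) else float(lab) for lab in data["group_labels"]
    )
    return ModelSpec(
        kind=data["kind"],
        group_labels=labels,
        major_radius=data["major_radius"],
        canonical=data["canonical"],
        params=None if data["params"] is None else np.asarray(data["params"]),
    )
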