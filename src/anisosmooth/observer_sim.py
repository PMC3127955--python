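"""Synthetic adjustment-task observers.

Simulates the psychophysical experiment: on each trial the observer sees an
elongated Gaussian luminance profile and rotates a 1-degree-step probe line
to its perceived orientation.  The simulated response is the stimulus
orientation plus the smoothing-model bias plus orientation-dependent
Gaussian response noise (wrapped onto the 180-degree circle) and quantized
to the probe lattice.

The response-noise scale follows the roundness of the *smoothed* profile:
the rounder the perceived blob, the harder the adjustment and the larger
the spread.  With a vertically elongated kernel, horizontal stimuli are
smoothed roundest, so dispersion is largest near horizontal and smallest
near vertical — the pattern observed empirically.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .angles import wrap_bias, wrap_orientation
from .bias_model import _bias_core
from .scalespace import KernelSpec, smooth_covariance
from .stimuli import DesignSchedule, GLPSpec, build_schedule, glp_covariance, make_glp

__all__ = ["ObserverSpec", "response_sd", "simulate_experiment", "TRIAL_COLUMNS"]

TRIAL_COLUMNS = (
    "participant",
    "frame",
    "block",
    "trial",
    "orientation_deg",
    "aspect_ratio",
    "response_deg",
    "bias_deg",
)

#: floor on (1 - eigenvalue ratio) when the smoothed profile is nearly
#: circular, capping the response SD at 10x the anisotropy-free scale
_ROUNDNESS_FLOOR = 1e-2


@dataclass(frozen=True)
class ObserverSpec:
    """Generating truth and noise parameters of one synthetic observer.

    ``sigma_base`` (degrees) scales the response noise; ``kappa`` is the
    dimensionless exponent coupling noise to the roundness of the smoothed
    profile; ``lapse_rate`` is the probability of an off-task uniform
    response (0 by default so the noiseless limit is exact).
    """

    kernel: KernelSpec = KernelSpec(0.84, 2.08, 0.0)
    sigma_base: float = 4.0
    kappa: float = 0.5
    lapse_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sigma_base > 0.0:
            raise ValueError("sigma_base must be positive")
        if self.kappa < 0.0:
            raise ValueError("kappa must be non-negative")
        if not 0.0 <= self.lapse_rate <= 0.1:
            raise ValueError("lapse_rate must lie in [0, 0.1]")


def response_sd(glp: GLPSpec, observer: ObserverSpec) -> float:
    """Standard deviation (degrees) of the adjustment response for one GLP.

    With q = lambda_min / lambda_max of the smoothed covariance,

        sd = sigma_base * q**kappa * (1 - q)**(-1/2),

    strictly increasing in q: a needle (q -> 0, kappa = 0) gives
    ``sigma_base``; a nearly circular smoothed profile diverges and is
    capped via a floor on (1 - q).
    """
    smoothed = smooth_covariance(glp_covariance(glp), observer.kernel)
    evals = np.linalg.eigvalsh(smoothed)
    q = float(evals[0] / evals[1])
    return float(
        observer.sigma_base * q**observer.kappa / np.sqrt(max(1.0 - q, _ROUNDNESS_FLOOR))
    )


def _condition_stats(
    design: DesignSchedule, observer: ObserverSpec
) -> dict[tuple[float, float], tuple[float, float]]:
    """(bias, response SD) per (orientation, aspect ratio) condition."""
    stats = {}
    for theta in design.orientations:
        for ratio in design.aspect_ratios:
            glp = make_glp(ratio, theta, design.major_radius)
            bias = float(
                _bias_core(
                    theta,
                    design.major_radius,
                    ratio * design.major_radius,
                    observer.kernel.a_h,
                    observer.kernel.a_v,
                    observer.kernel.r,
                )
            )
            stats[(theta, ratio)] = (bias, response_sd(glp, observer))
    return stats


def simulate_experiment(
    design: DesignSchedule,
    observers: list[ObserverSpec],
    quantize: bool = True,
) -> pd.DataFrame:
    """Simulate the full adjustment experiment for a list of observers.

    Each observer is one participant; observer seeds must be distinct so
    that trial orders and noise streams are independent.  Responses are
    wrapped to [0, 180) and (by default) quantized to the 1-degree probe
    lattice; ``bias_deg`` is the response minus the stimulus orientation
    wrapped to (-90, 90].  Identical seeds reproduce the table bit for bit.
    """
    seeds = [obs.seed for obs in observers]
    if len(set(seeds)) != len(seeds):
        raise ValueError("observer seeds must be distinct")

    tables = []
    for participant, observer in enumerate(observers):
        schedule = build_schedule(
            replace(design, participants=1), seed=observer.seed
        )
        schedule["participant"] = participant
        rng = np.random.default_rng([int(observer.seed), 0xB1A5])

        key = list(zip(schedule["orientation_deg"], schedule["aspect_ratio"]))
        stats = _condition_stats(design, observer)
        bias = np.array([stats[k][0] for k in key])
        sd = np.array([stats[k][1] for k in key])

        raw = schedule["orientation_deg"].to_numpy() + bias
        raw = raw + rng.normal(0.0, 1.0, size=len(raw)) * sd
        if observer.lapse_rate > 0.0:
            lapses = rng.random(len(raw)) < observer.lapse_rate
            raw = np.where(lapses, rng.uniform(0.0, 180.0, size=len(raw)), raw)
        response = wrap_orientation(np.rint(raw) if quantize else raw)
        schedule["response_deg"] = response
        schedule["bias_deg"] = wrap_bias(
            response - schedule["orientation_deg"].to_numpy()
        )
        tables.append(schedule)

    table = pd.concat(tables, ignore_index=True)
    return table[list(TRIAL_COLUMNS)]
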