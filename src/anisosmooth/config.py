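"""Run configuration: YAML round-trip and validation.

A :class:`RunConfig` names every seed and parameter the pipeline uses so a
run is reproducible from its config file alone.  Observer entries may be
given explicitly; a single observer entry is expanded to one observer per
participant with per-participant seeds spawned from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .observer_sim import ObserverSpec
from .scalespace import KernelSpec
from .stimuli import DesignSchedule

__all__ = ["RunConfig", "ConfigError"]

_DEFAULT_MODELS = (
    "isotropic",
    "homogeneous",
    "homogeneous_oriented",
    "radial_heterogeneous",
    "angular_heterogeneous",
)


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass(frozen=True)
class RunConfig:
    seed: int = 1
    outdir: str = "runs/run"
    design: DesignSchedule = field(default_factory=DesignSchedule)
    observers: tuple[ObserverSpec, ...] = ()
    models: tuple[str, ...] = _DEFAULT_MODELS
    aggregated: bool = True
    quantize: bool = True
    resolution: float = 32.0

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(_DEFAULT_MODELS)
        if unknown:
            raise ConfigError(f"unknown model kinds: {sorted(unknown)}")
        if self.observers and len(self.observers) != self.design.participants:
            raise ConfigError(
                f"{len(self.observers)} observers for "
                f"{self.design.participants} participants"
            )

    def resolve_observers(self) -> tuple[ObserverSpec, ...]:
        """Observers with distinct seeds, one per participant.

        If no observers are configured, defaults are expanded across
        participants with seeds spawned from the master seed (kept below
        2**31 so they serialize portably).
        """
        if self.observers:
            return self.observers
        seeds = np.random.default_rng(self.seed).integers(
            2**31, size=self.design.participants
        )
        return tuple(ObserverSpec(seed=int(s)) for s in seeds)

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        data = {
            "seed": self.seed,
            "outdir": self.outdir,
            "models": list(self.models),
            "aggregated": self.aggregated,
            "quantize": self.quantize,
            "resolution": self.resolution,
            "design": {
                "orientations": list(self.design.orientations),
                "aspect_ratios": list(self.design.aspect_ratios),
                "frame_conditions": list(self.design.frame_conditions),
                "blocks_per_session": self.design.blocks_per_session,
                "reps_per_block": self.design.reps_per_block,
                "participants": self.design.participants,
                "major_radius": self.design.major_radius,
            },
            "observers": [
                {
                    "kernel": {
                        "a_h": o.kernel.a_h,
                        "a_v": o.kernel.a_v,
                        "r": o.kernel.r,
                    },
                    "sigma_base": o.sigma_base,
                    "kappa": o.kappa,
                    "lapse_rate": o.lapse_rate,
                    "seed": o.seed,
                }
                for o in self.observers
            ],
        }
        return data

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {
            "seed",
            "outdir",
            "models",
            "aggregated",
            "quantize",
            "resolution",
            "design",
            "observers",
        }
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        design_data = dict(data.get("design", {}))
        for key in ("orientations", "aspect_ratios", "frame_conditions"):
            if key in design_data:
                design_data[key] = tuple(design_data[key])
        try:
            design = DesignSchedule(**design_data)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid design: {exc}") from exc
        observers = []
        for entry in data.get("observers", []):
            kernel = KernelSpec(**entry.get("kernel", {}))
            observers.append(
                ObserverSpec(
                    kernel=kernel,
                    sigma_base=entry.get("sigma_base", 4.0),
                    kappa=entry.get("kappa", 0.5),
                    lapse_rate=entry.get("lapse_rate", 0.0),
                    seed=entry.get("seed", 0),
                )
            )
        if len(observers) == 1 and design.participants > 1:
            template = observers[0]
            seeds = np.random.default_rng(data.get("seed", 1)).integers(
                2**31, size=design.participants
            )
            observers = [replace(template, seed=int(s)) for s in seeds]
        return cls(
            seed=data.get("seed", 1),
            outdir=data.get("outdir", "runs/run"),
            design=design,
            observers=tuple(observers),
            models=tuple(data.get("models", _DEFAULT_MODELS)),
            aggregated=data.get("aggregated", True),
            quantize=data.get("quantize", True),
            resolution=data.get("resolution", 32.0),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
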