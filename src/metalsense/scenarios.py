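"""Scenario configuration: enums, field parameters and run parameters.

A :class:`ScenarioConfig` pins everything a population-level run needs —
which sensor, which regime (growing colony with a central metal source, or a
stationary population immersed in a homogeneous bath), the environmental
metal concentration, the activation threshold, population counts, the
induced per-step error rate and the RNG seed.  The twelve built-in
scenarios (three sensors x four conditions) are constructed in
:mod:`metalsense.fixtures`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import StrEnum

from ._defaults import load_defaults
from .errors import ConfigError


class Metal(StrEnum):
    ARSENIC = "arsenic"
    MERCURY = "mercury"
    LEAD = "lead"


class Regime(StrEnum):
    GROWING = "growing"
    STATIONARY = "stationary"


class FieldMode(StrEnum):
    HOMOGENEOUS = "homogeneous"
    CENTRAL_SOURCE = "central_source"


class Boundary(StrEnum):
    ZERO_FLUX = "zero_flux"
    ABSORBING = "absorbing"


#: reporter chromoprotein colour of each sensor
REPORTER_COLOR: dict[Metal, str] = {
    Metal.ARSENIC: "red",
    Metal.MERCURY: "blue",
    Metal.LEAD: "yellow",
}

#: activation threshold of each sensor, ug/L
ACTIVATION_THRESHOLD: dict[Metal, float] = {
    Metal(k): float(v) for k, v in load_defaults()["thresholds"].items()
}

#: environmental concentrations tested per sensor (threshold, half, zero), ug/L
TESTED_CONCENTRATIONS: dict[Metal, tuple[float, ...]] = {
    Metal(k): tuple(float(c) for c in v)
    for k, v in load_defaults()["concentrations"].items()
}


@dataclass(frozen=True)
class FieldParams:
    """Geometry and transport parameters of the extracellular metal field.

    The domain is a square of side ``domain_size`` centred on the origin,
    so coordinates run from -domain_size/2 to +domain_size/2 in microns.
    """

    mode: FieldMode = FieldMode.HOMOGENEOUS
    domain_size: float = load_defaults()["field"]["domain_size"]
    dx: float = load_defaults()["field"]["dx"]
    D_coeff: float = load_defaults()["field"]["D_coeff"]
    source_radius: float = load_defaults()["field"]["source_radius"]
    boundary: Boundary = Boundary.ZERO_FLUX

    def __post_init__(self) -> None:
        if self.domain_size <= 0:
            raise ConfigError("domain_size must be positive")
        if self.mode is FieldMode.CENTRAL_SOURCE:
            if self.dx <= 0:
                raise ConfigError("dx must be positive in central_source mode")
            if self.D_coeff <= 0:
                raise ConfigError("D_coeff must be positive in central_source mode")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterisation of one population-level biosensor run."""

    name: str
    sensor_metal: Metal
    regime: Regime
    metal_conc: float            # ug/L
    threshold: float             # ug/L
    initial_pop: int
    max_pop: int
    error_rate: float            # per-cell per-step probability
    growth_rate: float           # 1/min
    t_end: float                 # min
    dt: float                    # min
    seed: int = 0
    maturation_delay: float = load_defaults()["population"]["maturation_delay"]
    colony_radius: float = load_defaults()["population"]["colony_radius_growing"]
    field_params: FieldParams = field(default_factory=FieldParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate <= 1.0:
            raise ConfigError(f"error_rate must lie in [0, 1], got {self.error_rate}")
        if self.initial_pop < 1 or self.initial_pop > self.max_pop:
            raise ConfigError(
                f"need 1 <= initial_pop <= max_pop, got {self.initial_pop} > {self.max_pop}"
            )
        if self.metal_conc < 0:
            raise ConfigError("metal_conc must be non-negative")
        if self.threshold <= 0:
            raise ConfigError("threshold must be positive")
        if self.t_end <= 0 or self.dt <= 0:
            raise ConfigError("t_end and dt must be positive")
        if self.growth_rate < 0:
            raise ConfigError("growth_rate must be non-negative")
        if not 0 < self.maturation_delay:
            raise ConfigError("maturation_delay must be positive")

    def with_seed(self, seed: int) -> "ScenarioConfig":
        """Copy of this config with a different RNG seed."""
        return replace(self, seed=seed)
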