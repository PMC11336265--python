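"""Time-series capture: CSV output, expressing-count plots, colony
snapshots and scenario-file parsing."""

from __future__ import annotations

import tomllib
import warnings
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from .colony import Colony, TimeSeriesRecord
from .errors import ConfigError, TimeSeriesError
from .metal_field import MetalField
from .scenarios import (
    ACTIVATION_THRESHOLD,
    Boundary,
    FieldMode,
    FieldParams,
    Metal,
    Regime,
    REPORTER_COLOR,
    ScenarioConfig,
)

_CSV_COLUMNS = ["time_min", "live_count", "expressing_count", "scenario"]


def _validate(records: Sequence[TimeSeriesRecord]) -> None:
    if not records:
        raise TimeSeriesError("no records to write")
    times = [r.time for r in records]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise TimeSeriesError("record times must be strictly increasing")


def write_timeseries_csv(
    records: Sequence[TimeSeriesRecord], destination: str | Path
) -> None:
    """Write records as CSV with columns time_min, live_count,
    expressing_count, scenario."""
    _validate(records)
    frame = pd.DataFrame(
        {
            "time_min": [r.time for r in records],
            "live_count": [r.live_count for r in records],
            "expressing_count": [r.expressing_count for r in records],
            "scenario": [r.scenario_name for r in records],
        }
    )
    frame.to_csv(destination, index=False)


def read_timeseries_csv(source: str | Path) -> list[TimeSeriesRecord]:
    """Parse a CSV written by :func:`write_timeseries_csv`."""
    frame = pd.read_csv(source)
    missing = set(_CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise TimeSeriesError(f"CSV missing columns: {sorted(missing)}")
    return [
        TimeSeriesRecord(
            float(row.time_min),
            int(row.live_count),
            int(row.expressing_count),
            str(row.scenario),
        )
        for row in frame.itertuples()
    ]


def plot_timeseries(
    records: Sequence[TimeSeriesRecord], destination: str | Path
) -> None:
    """Plot expressing-cell count vs. time; deterministic PNG output."""
    _validate(records)
    times = [r.time for r in records]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(times, [r.expressing_count for r in records], label="expressing")
    ax.plot(
        times, [r.live_count for r in records], linestyle="--", label="live"
    )
    ax.set_xlabel("time (min)")
    ax.set_ylabel("bacteria")
    ax.set_title(records[0].scenario_name)
    ax.legend()
    fig.tight_layout()
    # strip the software tag so identical inputs give identical bytes
    fig.savefig(destination, dpi=100, metadata={"Software": None})
    plt.close(fig)


def snapshot(
    colony: Colony, field: MetalField, destination: str | Path
) -> None:
    """Render the colony over the metal field: expressing cells in the
    sensor's reporter colour, dark otherwise, field as background heatmap."""
    half = field.half_extent
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(
        field.grid.T,
        origin="lower",
        extent=(-half, half, -half, half),
        cmap="magma",
        vmin=0.0,
    )
    live = colony.alive
    on = live & colony.expressing
    off = live & ~colony.expressing
    color = REPORTER_COLOR[colony.config.sensor_metal]
    ax.scatter(*colony.positions[off].T, s=2, c="0.25", linewidths=0)
    ax.scatter(*colony.positions[on].T, s=2, c=color, linewidths=0)
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title(f"{colony.config.name}  t={colony.t:.1f} min")
    fig.tight_layout()
    fig.savefig(destination, dpi=100, metadata={"Software": None})
    plt.close(fig)


_REQUIRED_KEYS = ("sensor", "regime", "metal_conc")

_DEFAULT_POP = {
    Regime.GROWING: dict(
        initial_pop="growing_initial",
        max_pop="growing_max",
        growth_rate="growth_rate_growing",
        t_end="t_end_growing",
    ),
    Regime.STATIONARY: dict(
        initial_pop="stationary_initial",
        max_pop="stationary_max",
        growth_rate="growth_rate_stationary",
        t_end="t_end_stationary",
    ),
}

_KNOWN_KEYS = {
    "name", "sensor", "regime", "metal_conc", "threshold", "initial_pop",
    "max_pop", "error_rate", "growth_rate", "t_end", "dt", "seed",
    "maturation_delay", "colony_radius", "field",
}


def parse_config(path: str | Path) -> ScenarioConfig:
    """Parse a TOML scenario file into a validated :class:`ScenarioConfig`.

    Required keys: ``sensor``, ``regime``, ``metal_conc``.  Everything else
    defaults to the study values for that regime (the activation threshold
    defaults per sensor: arsenic 10, mercury 6, lead 10 ug/L).  Unknown keys
    draw a warning; invariant violations raise :class:`ConfigError`."""
    from ._defaults import load_defaults

    path = Path(path)
    try:
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"{path}: malformed TOML: {exc}") from exc

    missing = [k for k in _REQUIRED_KEYS if k not in raw]
    if missing:
        raise ConfigError(f"{path}: missing required keys: {missing}")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        warnings.warn(
            f"{path}: ignoring unknown keys {sorted(unknown)}", stacklevel=2
        )

    try:
        metal = Metal(raw["sensor"])
        regime = Regime(raw["regime"])
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc

    pop = load_defaults()["population"]
    keymap = _DEFAULT_POP[regime]
    field_raw = dict(raw.get("field", {}))
    default_mode = (
        FieldMode.CENTRAL_SOURCE if regime is Regime.GROWING else FieldMode.HOMOGENEOUS
    )
    try:
        field_params = FieldParams(
            mode=FieldMode(field_raw.pop("mode", default_mode)),
            domain_size=float(field_raw.pop("domain_size", load_defaults()["field"]["domain_size"])),
            dx=float(field_raw.pop("dx", load_defaults()["field"]["dx"])),
            D_coeff=float(field_raw.pop("D_coeff", load_defaults()["field"]["D_coeff"])),
            source_radius=float(field_raw.pop("source_radius", load_defaults()["field"]["source_radius"])),
            boundary=Boundary(field_raw.pop("boundary", Boundary.ZERO_FLUX)),
        )
        if field_raw:
            warnings.warn(
                f"{path}: ignoring unknown field keys {sorted(field_raw)}",
                stacklevel=2,
            )
        return ScenarioConfig(
            name=str(raw.get("name", path.stem)),
            sensor_metal=metal,
            regime=regime,
            metal_conc=float(raw["metal_conc"]),
            threshold=float(raw.get("threshold", ACTIVATION_THRESHOLD[metal])),
            initial_pop=int(raw.get("initial_pop", pop[keymap["initial_pop"]])),
            max_pop=int(raw.get("max_pop", pop[keymap["max_pop"]])),
            error_rate=float(raw.get("error_rate", pop["error_rate"])),
            growth_rate=float(raw.get("growth_rate", pop[keymap["growth_rate"]])),
            t_end=float(raw.get("t_end", pop[keymap["t_end"]])),
            dt=float(raw.get("dt", pop["dt"])),
            seed=int(raw.get("seed", 0)),
            maturation_delay=float(
                raw.get("maturation_delay", pop["maturation_delay"])
            ),
            colony_radius=float(
                raw.get("colony_radius", pop["colony_radius_growing"])
            ),
            field_params=field_params,
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def write_scenario_toml(config: ScenarioConfig, destination: str | Path) -> None:
    """Serialise a scenario to the TOML format :func:`parse_config` reads."""
    fp = config.field_params
    lines = [
        f'name = "{config.name}"',
        f'sensor = "{config.sensor_metal.value}"',
        f'regime = "{config.regime.value}"',
        f"metal_conc = {config.metal_conc}",
        f"threshold = {config.threshold}",
        f"initial_pop = {config.initial_pop}",
        f"max_pop = {config.max_pop}",
        f"error_rate = {config.error_rate}",
        f"growth_rate = {config.growth_rate}",
        f"t_end = {config.t_end}",
        f"dt = {config.dt}",
        f"seed = {config.seed}",
        f"maturation_delay = {config.maturation_delay}",
        f"colony_radius = {config.colony_radius}",
        "",
        "[field]",
        f'mode = "{fp.mode.value}"',
        f"domain_size = {fp.domain_size}",
        f"dx = {fp.dx}",
        f"D_coeff = {fp.D_coeff}",
        f"source_radius = {fp.source_radius}",
        f'boundary = "{fp.boundary.value}"',
    ]
    Path(destination).write_text("\n".join(lines) + "\n")
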