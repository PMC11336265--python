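"""Agent-based 2D simulation of biosensor populations.

Cells are 1-um disks on a continuous plane.  Each step every live cell
(in id order) may divide (probability ``growth_rate * dt``, suppressed at
the population cap), samples its local metal concentration, compares it to
the activation threshold, suffers the induced error (probability
``error_rate`` of reporting the inverted state for this step), and runs a
maturation clock: the visible ``expressing`` flag follows the sensed state
only after it has persisted for ``maturation_delay`` minutes, modelling
chromoprotein accumulation and decay.

State is stored as flat numpy arrays for speed; :class:`Cell` views are
materialised on demand.  All randomness flows through one generator seeded
from the scenario config, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import PlacementError
from .metal_field import MetalField, advance_field, concentration_at, init_field
from .scenarios import FieldMode, Regime, ScenarioConfig

_CELL_RADIUS = 1.0  # um


@dataclass(frozen=True)
class Cell:
    """Read-only view of one agent."""

    id: int
    position: tuple[float, float]  # um
    age: float                     # min
    alive: bool
    expressing: bool
    maturation_clock: float        # min until a pending state change shows
    errored_this_step: bool


@dataclass
class TimeSeriesRecord:
    """One output row: population and expressing counts at a time point."""

    time: float
    live_count: int
    expressing_count: int
    scenario_name: str

    def __post_init__(self) -> None:
        if not 0 <= self.expressing_count <= self.live_count:
            raise ValueError(
                f"need 0 <= expressing_count <= live_count, got "
                f"{self.expressing_count} / {self.live_count}"
            )


class Colony:
    """The population container: positions, ages and sensor state arrays."""

    def __init__(self, config: ScenarioConfig, positions: np.ndarray):
        n = len(positions)
        self.config = config
        self.t = 0.0
        self.positions = np.asarray(positions, dtype=float)
        self.alive = np.ones(n, dtype=bool)
        self.expressing = np.zeros(n, dtype=bool)
        self.age = np.zeros(n)
        self.maturation_clock = np.full(n, config.maturation_delay)
        self.errored_this_step = np.zeros(n, dtype=bool)
        self.rng = np.random.default_rng(config.seed)
        # running tallies for error-rate recovery
        self.error_on_events = 0   # cells reporting ON purely due to error
        self.error_events = 0      # any inverted report
        self.cell_steps = 0

    @property
    def n_live(self) -> int:
        return int(self.alive.sum())

    @property
    def n_expressing(self) -> int:
        return int((self.expressing & self.alive).sum())

    @property
    def cells(self) -> list[Cell]:
        return [
            Cell(
                id=i,
                position=(float(self.positions[i, 0]), float(self.positions[i, 1])),
                age=float(self.age[i]),
                alive=bool(self.alive[i]),
                expressing=bool(self.expressing[i]),
                maturation_clock=float(self.maturation_clock[i]),
                errored_this_step=bool(self.errored_this_step[i]),
            )
            for i in range(len(self.positions))
        ]


def _disk_points(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def init_colony(config: ScenarioConfig) -> Colony:
    """Place the initial population.

    Growing regime: ``initial_pop`` cells uniform in a central disk of
    radius ``colony_radius``.  Stationary regime: uniform over the whole
    (square) domain — the population is immersed in the bath."""
    half = 0.5 * config.field_params.domain_size
    rng = np.random.default_rng(config.seed)
    if config.regime is Regime.GROWING:
        area = np.pi * config.colony_radius**2
        if config.initial_pop * np.pi * _CELL_RADIUS**2 > area:
            raise PlacementError(
                f"{config.initial_pop} cells cannot seed a "
                f"{config.colony_radius} um disk"
            )
        positions = _disk_points(rng, config.initial_pop, config.colony_radius)
    else:
        side = 2.0 * half
        if config.initial_pop * np.pi * _CELL_RADIUS**2 > side**2:
            raise PlacementError(
                f"{config.initial_pop} cells cannot fit a {side} um square"
            )
        positions = rng.uniform(-half, half, size=(config.initial_pop, 2))
    colony = Colony(config, positions)
    colony.rng = rng  # keep the stream that placed the cells
    return colony


def step_colony(colony: Colony, field: MetalField, config: ScenarioConfig) -> Colony:
    """Advance the colony by one step of ``config.dt`` minutes (in place).

    Order per step: division (capped at ``max_pop``), local concentration
    sampling, threshold comparison, induced error inversion, maturation
    clock update, time advance.  Returns the same colony for chaining."""
    rng = colony.rng
    dt = config.dt
    half_extent = field.half_extent

    # --- division ----------------------------------------------------------
    n0 = len(colony.positions)
    headroom = config.max_pop - colony.n_live
    p_div = min(config.growth_rate * dt, 1.0)
    if headroom > 0 and p_div > 0:
        dividing = colony.alive & (rng.random(n0) < p_div)
        idx = np.nonzero(dividing)[0]
        if len(idx) > headroom:   # cap as carrying capacity: first come (by id)
            idx = idx[:headroom]
        if len(idx):
            theta = rng.uniform(0.0, 2.0 * np.pi, len(idx))
            offset = 2.0 * _CELL_RADIUS * np.column_stack(
                [np.cos(theta), np.sin(theta)]
            )
            daughters = np.clip(
                colony.positions[idx] + offset, -half_extent, half_extent
            )
            k = len(idx)
            colony.positions = np.vstack([colony.positions, daughters])
            colony.alive = np.append(colony.alive, np.ones(k, dtype=bool))
            colony.expressing = np.append(colony.expressing, np.zeros(k, dtype=bool))
            colony.age = np.append(colony.age, np.zeros(k))
            colony.maturation_clock = np.append(
                colony.maturation_clock, np.full(k, config.maturation_delay)
            )
            colony.errored_this_step = np.append(
                colony.errored_this_step, np.zeros(k, dtype=bool)
            )

    n = len(colony.positions)

    # --- sensing with induced error ----------------------------------------
    conc = concentration_at(field, colony.positions[:, 0], colony.positions[:, 1])
    conc = np.atleast_1d(np.asarray(conc))
    nominal = conc >= config.threshold
    errored = rng.random(n) < config.error_rate
    state = nominal ^ errored
    live = colony.alive
    colony.errored_this_step = errored & live
    colony.error_on_events += int((errored & ~nominal & live).sum())
    colony.error_events += int((errored & live).sum())
    colony.cell_steps += int(live.sum())

    # --- maturation debounce ------------------------------------------------
    # the visible flag follows the sensed state only after it has persisted
    # for maturation_delay minutes; agreement resets the clock
    mismatch = (state != colony.expressing) & live
    colony.maturation_clock[~mismatch] = config.maturation_delay
    colony.maturation_clock[mismatch] -= dt
    flip = mismatch & (colony.maturation_clock <= 0.0)
    colony.expressing[flip] = state[flip]
    colony.maturation_clock[flip] = config.maturation_delay

    colony.age[live] += dt
    colony.t += dt
    return colony


def run_scenario(
    config: ScenarioConfig,
) -> tuple[list[TimeSeriesRecord], Colony, MetalField]:
    """Run a scenario end to end.

    Alternates field diffusion (stable substeps) and colony steps from t=0
    to ``t_end`` and records time, live count and expressing count at every
    step.  Fully reproducible for a fixed config (including seed)."""
    field = init_field(config)
    colony = init_colony(config)
    records = [
        TimeSeriesRecord(0.0, colony.n_live, colony.n_expressing, config.name)
    ]
    n_steps = int(round(config.t_end / config.dt))
    for _ in range(n_steps):
        if field.mode is FieldMode.CENTRAL_SOURCE:
            field = advance_field(field, config.dt)
        step_colony(colony, field, config)
        records.append(
            TimeSeriesRecord(colony.t, colony.n_live, colony.n_expressing, config.name)
        )
    return records, colony, field


def estimated_error_rate(colony: Colony) -> float:
    """Per-cell per-step erroneous-ON frequency observed so far.

    In a zero-metal run the nominal state is always OFF, so every inverted
    report is an erroneous ON and this recovers the induced error rate."""
    if colony.cell_steps == 0:
        return float("nan")
    return colony.error_on_events / colony.cell_steps


def mean_radius(colony: Colony, expressing: bool) -> float:
    """Mean distance-to-centre (um) of live cells with the given flag."""
    mask = colony.alive & (colony.expressing == expressing)
    if not mask.any():
        return float("nan")
    return float(np.hypot(*colony.positions[mask].T).mean())
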