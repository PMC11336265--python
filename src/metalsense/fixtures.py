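"""Synthetic inputs: placeholder part sequences, part registries and the
twelve built-in simulation scenarios.

The real nucleotide sequences of the registry parts are not bundled;
placeholder sequences of realistic length are generated deterministically
from a single integer seed, and a user-supplied FASTA whose record IDs
match the part IDs can replace them record by record.

Generation rule (the contract tests rely on): the per-part stream seed is
``SeedSequence([global_seed, crc32(part_id)])`` and each base is drawn as
``rng.integers(0, 4)`` mapped through ``"ACGT"`` with numpy's PCG64
generator.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._defaults import load_defaults
from .errors import FixtureSpecError
from .parts import Part, PartRole
from .scenarios import (
    ACTIVATION_THRESHOLD,
    TESTED_CONCENTRATIONS,
    Boundary,
    FieldMode,
    FieldParams,
    Metal,
    Regime,
    ScenarioConfig,
)

_ALPHABET = "ACGT"

#: every distinct registry part used by the three sensors:
#: id -> (role, description)
PART_CATALOG: dict[str, tuple[PartRole, str]] = {
    "BBa_J23101": (PartRole.CONSTITUTIVE_PROMOTER, "constitutive promoter"),
    "BBa_B0030": (PartRole.RBS, "ribosome binding site"),
    "BBa_J15101": (PartRole.CDS, "arsR repressor coding region"),
    "BBa_B0010": (PartRole.TERMINATOR, "transcription terminator"),
    "BBa_J33100": (PartRole.REPRESSIBLE_PROMOTER, "arsenic sensitive promoter"),
    "BBa_E1010": (PartRole.CDS, "mRFP1 red chromoprotein coding region"),
    "BBa_B0015": (PartRole.DOUBLE_TERMINATOR, "bidirectional double terminator"),
    "BBa_K1420004": (PartRole.CDS, "merR repressor coding region"),
    "BBa_K356002": (PartRole.REPRESSIBLE_PROMOTER, "mercury sensitive promoter"),
    "BBa_K592009": (PartRole.CDS, "amilCP blue chromoprotein coding region"),
    "BBa_K592010": (PartRole.CDS, "amilGFP yellow chromoprotein coding region"),
    "BBa_I721002": (PartRole.CDS, "pbrR repressor coding region"),
    "BBa_I721001": (PartRole.REPRESSIBLE_PROMOTER, "lead sensitive promoter"),
}


@dataclass(frozen=True)
class PartFixtureSpec:
    """Specification of one placeholder part sequence."""

    part_id: str
    role: PartRole
    length_bp: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.part_id:
            raise FixtureSpecError("part_id must be non-empty")
        if self.length_bp < 1:
            raise FixtureSpecError(
                f"length_bp must be >= 1, got {self.length_bp}"
            )


def default_length(role: PartRole) -> int:
    """Placeholder sequence length (bp) for a part role."""
    return int(load_defaults()["part_lengths"][role.value])


def generate_part_sequence(spec: PartFixtureSpec) -> str:
    """Deterministic placeholder DNA sequence for ``spec``.

    Identical ``(part_id, length_bp, seed)`` always yields the identical
    uppercase ACGT string; distinct part IDs get independent streams even
    under one global seed.
    """
    if spec.length_bp < 1:  # dataclass may be bypassed via replace tricks
        raise FixtureSpecError(f"length_bp must be >= 1, got {spec.length_bp}")
    stream = np.random.SeedSequence(
        [spec.seed, zlib.crc32(spec.part_id.encode("ascii"))]
    )
    rng = np.random.Generator(np.random.PCG64(stream))
    idx = rng.integers(0, 4, size=spec.length_bp)
    return "".join(_ALPHABET[i] for i in idx)


def build_registry(
    seed: int = 0, parts_fasta: str | Path | None = None
) -> dict[str, Part]:
    """Full part registry for all three sensors.

    Sequences are placeholder fixtures generated from ``seed``; if
    ``parts_fasta`` is given, any FASTA record whose ID equals a part ID
    replaces the placeholder for that part (unknown record IDs are ignored,
    the remaining parts keep their fixtures).
    """
    registry: dict[str, Part] = {}
    for part_id, (role, description) in PART_CATALOG.items():
        spec = PartFixtureSpec(part_id, role, default_length(role), seed)
        registry[part_id] = Part(
            part_id=part_id,
            role=role,
            sequence=generate_part_sequence(spec),
            description=description,
        )
    if parts_fasta is not None:
        for record in SeqIO.parse(str(parts_fasta), "fasta"):
            if record.id in registry:
                old = registry[record.id]
                registry[record.id] = Part(
                    part_id=old.part_id,
                    role=old.role,
                    sequence=str(record.seq).upper(),
                    description=old.description,
                )
    return registry


def write_registry_fasta(registry: dict[str, Part], destination: str | Path) -> None:
    """Dump a registry to FASTA, one record per part, ID = part ID."""
    with open(destination, "w") as fh:
        for part in registry.values():
            fh.write(f">{part.part_id} {part.description}\n{part.sequence}\n")


def _scenario(
    metal: Metal, regime: Regime, conc: float, label: str, seed: int
) -> ScenarioConfig:
    pop = load_defaults()["population"]
    if regime is Regime.GROWING:
        field = FieldParams(mode=FieldMode.CENTRAL_SOURCE, boundary=Boundary.ZERO_FLUX)
        initial, cap = pop["growing_initial"], pop["growing_max"]
        growth, t_end = pop["growth_rate_growing"], pop["t_end_growing"]
    else:
        field = FieldParams(mode=FieldMode.HOMOGENEOUS)
        initial, cap = pop["stationary_initial"], pop["stationary_max"]
        growth, t_end = pop["growth_rate_stationary"], pop["t_end_stationary"]
    return ScenarioConfig(
        name=f"{metal.value}_{regime.value}_{label}",
        sensor_metal=metal,
        regime=regime,
        metal_conc=conc,
        threshold=ACTIVATION_THRESHOLD[metal],
        initial_pop=initial,
        max_pop=cap,
        error_rate=pop["error_rate"],
        growth_rate=growth,
        t_end=t_end,
        dt=pop["dt"],
        seed=seed,
        field_params=field,
    )


def builtin_scenarios(seed: int = 0) -> list[ScenarioConfig]:
    """The twelve study scenarios: per sensor, a growing colony with the
    metal poured centrally at threshold concentration, plus stationary
    populations immersed at threshold, at half threshold, and in metal-free
    water."""
    configs: list[ScenarioConfig] = []
    for metal in Metal:
        threshold_conc, half_conc, zero_conc = TESTED_CONCENTRATIONS[metal]
        configs.append(_scenario(metal, Regime.GROWING, threshold_conc, "threshold", seed))
        configs.append(_scenario(metal, Regime.STATIONARY, threshold_conc, "threshold", seed))
        configs.append(_scenario(metal, Regime.STATIONARY, half_conc, "below", seed))
        configs.append(_scenario(metal, Regime.STATIONARY, zero_conc, "zero", seed))
    return configs


def get_scenario(name: str, seed: int | None = None) -> ScenarioConfig:
    """Look up a built-in scenario by name, optionally re-seeded."""
    for config in builtin_scenarios():
        if config.name == name:
            return config if seed is None else config.with_seed(seed)
    known = ", ".join(c.name for c in builtin_scenarios())
    raise KeyError(f"unknown scenario {name!r}; built-ins: {known}")
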