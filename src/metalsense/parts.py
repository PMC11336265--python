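"""Standard biological parts and tandem circuit assembly.

Each biosensor is an eight-part tandem construct with a fixed grammar:

    constitutive promoter - RBS - repressor CDS - terminator -
    metal-sensitive promoter - RBS - chromoprotein CDS - double terminator

The first four parts form the regulator operon (constitutive production of
the metal-binding repressor), the last four the reporter operon (the
repressible promoter driving a visible chromoprotein).  Assembled circuits
export to FASTA (concatenated sequence) and GenBank (one feature per part).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import StrEnum
from pathlib import Path
from typing import IO, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import AssemblyGrammarError, MissingPartError
from .scenarios import Metal, REPORTER_COLOR


class PartRole(StrEnum):
    CONSTITUTIVE_PROMOTER = "constitutive_promoter"
    REPRESSIBLE_PROMOTER = "repressible_promoter"
    RBS = "rbs"
    CDS = "cds"
    TERMINATOR = "terminator"
    DOUBLE_TERMINATOR = "double_terminator"


class OperonKind(StrEnum):
    REGULATOR = "regulator"
    REPORTER = "reporter"


#: role grammar of the eight-part circuit, in order
CIRCUIT_GRAMMAR: tuple[PartRole, ...] = (
    PartRole.CONSTITUTIVE_PROMOTER,
    PartRole.RBS,
    PartRole.CDS,
    PartRole.TERMINATOR,
    PartRole.REPRESSIBLE_PROMOTER,
    PartRole.RBS,
    PartRole.CDS,
    PartRole.DOUBLE_TERMINATOR,
)

#: part IDs of each sensor circuit, in assembly order
CIRCUIT_LAYOUT: dict[Metal, tuple[str, ...]] = {
    Metal.ARSENIC: (
        "BBa_J23101", "BBa_B0030", "BBa_J15101", "BBa_B0010",
        "BBa_J33100", "BBa_B0030", "BBa_E1010", "BBa_B0015",
    ),
    Metal.MERCURY: (
        "BBa_J23101", "BBa_B0030", "BBa_K1420004", "BBa_B0010",
        "BBa_K356002", "BBa_B0030", "BBa_K592009", "BBa_B0015",
    ),
    Metal.LEAD: (
        "BBa_J23101", "BBa_B0030", "BBa_I721002", "BBa_B0010",
        "BBa_I721001", "BBa_B0030", "BBa_K592010", "BBa_B0015",
    ),
}

#: (regulator, reporter) operon names, after the dominant gene of each
OPERON_NAMES: dict[Metal, tuple[str, str]] = {
    Metal.ARSENIC: ("arsR", "mRFP1"),
    Metal.MERCURY: ("merR", "amilCP"),
    Metal.LEAD: ("pbrR", "amilGFP"),
}

#: GenBank feature key per part role
_FEATURE_KEY: dict[PartRole, str] = {
    PartRole.CONSTITUTIVE_PROMOTER: "promoter",
    PartRole.REPRESSIBLE_PROMOTER: "promoter",
    PartRole.RBS: "RBS",
    PartRole.CDS: "CDS",
    PartRole.TERMINATOR: "terminator",
    PartRole.DOUBLE_TERMINATOR: "terminator",
}

_DNA = set("ACGT")


@dataclass(frozen=True)
class Part:
    """A registry part: identifier, functional role and DNA sequence."""

    part_id: str
    role: PartRole
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.part_id:
            raise AssemblyGrammarError("part_id must be non-empty")
        if not self.sequence or set(self.sequence) - _DNA:
            raise AssemblyGrammarError(
                f"part {self.part_id}: sequence must be non-empty over ACGT"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneCircuit:
    """An assembled eight-part biosensor circuit."""

    name: str
    sensor_metal: Metal
    parts: tuple[Part, ...]
    reporter_color: str

    def __post_init__(self) -> None:
        roles = tuple(p.role for p in self.parts)
        if roles != CIRCUIT_GRAMMAR:
            raise AssemblyGrammarError(
                f"circuit {self.name}: part roles {[r.value for r in roles]} "
                f"violate the required order {[r.value for r in CIRCUIT_GRAMMAR]}"
            )
        if self.reporter_color != REPORTER_COLOR[self.sensor_metal]:
            raise AssemblyGrammarError(
                f"{self.sensor_metal.value} sensor must report "
                f"{REPORTER_COLOR[self.sensor_metal]}, got {self.reporter_color}"
            )

    @property
    def sequence(self) -> str:
        """In-order concatenation of the part sequences (no scars)."""
        return "".join(p.sequence for p in self.parts)


@dataclass(frozen=True)
class Operon:
    """A contiguous half of a circuit transcribed as one unit."""

    name: str
    parts: tuple[Part, ...]
    kind: OperonKind

    def __post_init__(self) -> None:
        if len(self.parts) != 4:
            raise AssemblyGrammarError(
                f"operon {self.name} must contain 4 parts, got {len(self.parts)}"
            )


def assemble_circuit(sensor_metal: Metal | str, registry: Mapping[str, Part]) -> GeneCircuit:
    """Assemble the tandem sensor circuit for ``sensor_metal`` from ``registry``.

    Raises :class:`MissingPartError` if a required part ID is absent and
    :class:`AssemblyGrammarError` if a registry part carries the wrong role
    for its position.
    """
    metal = Metal(sensor_metal)
    parts: list[Part] = []
    for position, part_id in enumerate(CIRCUIT_LAYOUT[metal]):
        if part_id not in registry:
            raise MissingPartError(part_id)
        part = registry[part_id]
        expected = CIRCUIT_GRAMMAR[position]
        if part.role is not expected:
            raise AssemblyGrammarError(
                f"position {position + 1} needs role {expected.value}, "
                f"but {part_id} has role {part.role.value}"
            )
        parts.append(part)
    return GeneCircuit(
        name=f"{metal.value}_biosensor",
        sensor_metal=metal,
        parts=tuple(parts),
        reporter_color=REPORTER_COLOR[metal],
    )


def split_operons(circuit: GeneCircuit) -> tuple[Operon, Operon]:
    """Split a circuit into its (regulator, reporter) operons.

    The regulator operon is parts 1-4, the reporter operon parts 5-8;
    concatenating them reproduces the circuit exactly.
    """
    regulator_name, reporter_name = OPERON_NAMES[circuit.sensor_metal]
    return (
        Operon(regulator_name, circuit.parts[:4], OperonKind.REGULATOR),
        Operon(reporter_name, circuit.parts[4:], OperonKind.REPORTER),
    )


def _to_seqrecord(circuit: GeneCircuit) -> SeqRecord:
    record = SeqRecord(
        Seq(circuit.sequence),
        id=circuit.name,
        name=circuit.name[:16],
        description=(
            f"{circuit.sensor_metal.value} whole-cell biosensor, "
            f"{circuit.reporter_color} chromoprotein reporter"
        ),
        annotations={"molecule_type": "DNA", "topology": "linear"},
    )
    offset = 0
    for part in circuit.parts:
        qualifiers: dict[str, list[str]] = {
            "label": [part.part_id],
            "part_id": [part.part_id],
            "role": [part.role.value],
        }
        if part.role is PartRole.DOUBLE_TERMINATOR:
            qualifiers["note"] = ["bidirectional double terminator"]
        record.features.append(
            SeqFeature(
                SimpleLocation(offset, offset + len(part), strand=1),
                type=_FEATURE_KEY[part.role],
                qualifiers=qualifiers,
            )
        )
        offset += len(part)
    return record


def write_fasta(circuit: GeneCircuit, destination: str | Path | IO[str]) -> None:
    """Write the circuit as a single FASTA record (concatenated sequence)."""
    SeqIO.write([_to_seqrecord(circuit)], destination, "fasta")


def write_genbank(circuit: GeneCircuit, destination: str | Path | IO[str]) -> None:
    """Write the circuit as a GenBank flat file with one feature per part.

    Features are contiguous, non-overlapping, on the plus strand, and
    together cover the full concatenated sequence; coordinates in the file
    are 1-based inclusive per the GenBank convention.
    """
    SeqIO.write([_to_seqrecord(circuit)], destination, "genbank")
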