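"""Circuit assembly grammar, operon splitting and FASTA/GenBank export."""

import pytest
from Bio import SeqIO
from hypothesis import given, settings
from hypothesis import strategies as st

import metalsense as ms
from metalsense.errors import AssemblyGrammarError, MissingPartError
from metalsense.parts import CIRCUIT_GRAMMAR, CIRCUIT_LAYOUT


class TestAssembly:
    def test_arsenic_part_order(self, arsenic_circuit):
        ids = [p.part_id for p in arsenic_circuit.parts]
        assert ids == [
            "BBa_J23101", "BBa_B0030", "BBa_J15101", "BBa_B0010",
            "BBa_J33100", "BBa_B0030", "BBa_E1010", "BBa_B0015",
        ]
        assert arsenic_circuit.reporter_color == "red"

    @pytest.mark.parametrize(
        "metal, subs, color",
        [
            (ms.Metal.MERCURY, ("BBa_K1420004", "BBa_K356002", "BBa_K592009"), "blue"),
            (ms.Metal.LEAD, ("BBa_I721002", "BBa_I721001", "BBa_K592010"), "yellow"),
        ],
    )
    def test_substitutions_at_positions_3_5_7(self, registry, metal, subs, color):
        circuit = ms.assemble_circuit(metal, registry)
        assert (
            circuit.parts[2].part_id,
            circuit.parts[4].part_id,
            circuit.parts[6].part_id,
        ) == subs
        assert circuit.reporter_color == color
        # the shared backbone parts are unchanged
        assert circuit.parts[0].part_id == "BBa_J23101"
        assert circuit.parts[7].part_id == "BBa_B0015"

    def test_missing_part_error_names_the_part(self, registry):
        partial = {k: v for k, v in registry.items() if k != "BBa_I721001"}
        with pytest.raises(MissingPartError, match="BBa_I721001"):
            ms.assemble_circuit(ms.Metal.LEAD, partial)

    def test_wrong_role_at_position_rejected(self, registry):
        bad = dict(registry)
        rbs = registry["BBa_B0030"]
        bad["BBa_J23101"] = ms.Part("BBa_J23101", ms.PartRole.RBS, rbs.sequence)
        with pytest.raises(AssemblyGrammarError, match="constitutive_promoter"):
            ms.assemble_circuit(ms.Metal.ARSENIC, bad)

    @given(perm=st.permutations(range(8)))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_any_role_disorder_rejected(self, arsenic_circuit, perm):
        parts = tuple(arsenic_circuit.parts[i] for i in perm)
        roles = tuple(p.role for p in parts)
        if roles == CIRCUIT_GRAMMAR:
            ms.GeneCircuit("ok", ms.Metal.ARSENIC, parts, "red")
        else:
            with pytest.raises(AssemblyGrammarError):
                ms.GeneCircuit("bad", ms.Metal.ARSENIC, parts, "red")

    def test_reporter_color_must_match_sensor(self, arsenic_circuit):
        with pytest.raises(AssemblyGrammarError):
            ms.GeneCircuit("x", ms.Metal.ARSENIC, arsenic_circuit.parts, "blue")


class TestOperons:
    @pytest.mark.parametrize(
        "metal, names",
        [
            (ms.Metal.ARSENIC, ("arsR", "mRFP1")),
            (ms.Metal.MERCURY, ("merR", "amilCP")),
            (ms.Metal.LEAD, ("pbrR", "amilGFP")),
        ],
    )
    def test_names_and_lossless_partition(self, registry, metal, names):
        circuit = ms.assemble_circuit(metal, registry)
        regulator, reporter = ms.split_operons(circuit)
        assert (regulator.name, reporter.name) == names
        assert regulator.kind.value == "regulator"
        assert reporter.kind.value == "reporter"
        assert len(regulator.parts) == len(reporter.parts) == 4
        assert regulator.parts + reporter.parts == circuit.parts


class TestExport:
    def test_fasta_is_concatenation_of_part_sequences(
        self, arsenic_circuit, tmp_path
    ):
        path = tmp_path / "circuit.fasta"
        ms.write_fasta(arsenic_circuit, path)
        record = SeqIO.read(path, "fasta")
        manual = "".join(p.sequence for p in arsenic_circuit.parts)
        assert str(record.seq) == manual
        assert len(record.seq) == sum(len(p) for p in arsenic_circuit.parts)
        assert "arsenic" in record.description

    def test_fasta_round_trip_identity(self, arsenic_circuit, tmp_path):
        path = tmp_path / "rt.fasta"
        ms.write_fasta(arsenic_circuit, path)
        assert str(SeqIO.read(path, "fasta").seq) == arsenic_circuit.sequence

    def test_genbank_features_cover_sequence_contiguously(
        self, arsenic_circuit, tmp_path
    ):
        path = tmp_path / "circuit.gb"
        ms.write_genbank(arsenic_circuit, path)
        record = SeqIO.read(path, "genbank")
        assert len(record.features) == 8
        expected_keys = [
            "promoter", "RBS", "CDS", "terminator",
            "promoter", "RBS", "CDS", "terminator",
        ]
        assert [f.type for f in record.features] == expected_keys
        cursor = 0
        for feature, part in zip(record.features, arsenic_circuit.parts):
            assert int(feature.location.start) == cursor
            cursor = int(feature.location.end)
            assert feature.qualifiers["part_id"] == [part.part_id]
            # feature span re-slices the original part sequence
            assert str(feature.extract(record.seq)) == part.sequence
        assert cursor == len(record.seq)

    def test_genbank_round_trip_recovers_part_ids_in_order(
        self, registry, tmp_path
    ):
        for metal in ms.Metal:
            circuit = ms.assemble_circuit(metal, registry)
            path = tmp_path / f"{metal.value}.gb"
            ms.write_genbank(circuit, path)
            record = SeqIO.read(path, "genbank")
            assert [f.qualifiers["part_id"][0] for f in record.features] == list(
                CIRCUIT_LAYOUT[metal]
            )
            assert str(record.seq) == circuit.sequence
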