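"""Structure model: PDB parsing, sequences, residue labels, cluster tables."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import quatmap.quaternary as quat
from quatmap.errors import (
    ChainNotFoundError,
    EmptyStructureError,
    LabelFormatError,
    PDBParseError,
)
from quatmap.structure import (
    THREE_TO_ONE,
    ResidueKey,
    chain_sequence,
    format_residue_label,
    load_published_clusters,
    parse_cluster_rows,
    parse_pdb,
    parse_residue_label,
    write_cluster_table,
    write_fasta,
)
from quatmap.synthetic import ComplexSpec, make_toy_complex, structure_to_pdb


def pdb_atom(serial, name, resname, chain, resnum, x, y, z,
             occ=1.0, altloc=" ", element=None, record="ATOM  "):
    element = element or name[0]
    return (f"{record}{serial:>5} {name:^4}{altloc}{resname:>3}"
            f" {chain}{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2}")


MINIMAL = "\n".join([
    pdb_atom(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
    pdb_atom(2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0),
    "END",
])


class TestParsePdb:
    def test_minimal_two_residues(self):
        s = parse_pdb(MINIMAL)
        assert list(s.chains) == ["A"]
        assert [r.name for r in s.chains["A"]] == ["ALA", "GLY"]
        assert s.chains["A"][0].ca is not None

    def test_two_chains(self):
        lines = []
        serial = 1
        for chain in "AB":
            for num in (1, 2, 3):
                lines.append(pdb_atom(serial, "CA", "ALA", chain, num,
                                      serial * 3.8, 0, 0))
                serial += 1
        s = parse_pdb("\n".join(lines))
        assert sorted(s.chains) == ["A", "B"]
        assert [r.key for r in s.chains["B"]] == [
            ResidueKey("B", 1), ResidueKey("B", 2), ResidueKey("B", 3)]

    def test_altloc_keeps_highest_occupancy(self):
        lines = [
            pdb_atom(1, "CA", "ALA", "A", 1, 1.0, 0, 0, occ=0.6, altloc="A"),
            pdb_atom(2, "CA", "ALA", "A", 1, 9.0, 0, 0, occ=0.4, altloc="B"),
        ]
        s = parse_pdb("\n".join(lines))
        (res,) = s.chains["A"]
        assert res.ca.position[0] == pytest.approx(1.0)

    def test_waters_and_ligands_excluded(self):
        lines = [
            pdb_atom(1, "CA", "ALA", "A", 1, 0, 0, 0),
            pdb_atom(2, "O", "HOH", "A", 101, 5, 5, 5, record="HETATM"),
            pdb_atom(3, "C1", "NAG", "A", 201, 9, 9, 9, record="HETATM"),
        ]
        s = parse_pdb("\n".join(lines))
        assert s.n_residues() == 1

    def test_malformed_record_names_line(self):
        bad = MINIMAL.replace("   3.800", "   3.8xx")
        with pytest.raises(PDBParseError, match="line 2"):
            parse_pdb(bad)

    def test_no_polymer_residues(self):
        water_only = pdb_atom(1, "O", "HOH", "A", 1, 0, 0, 0, record="HETATM")
        with pytest.raises(EmptyStructureError):
            parse_pdb(water_only)
        with pytest.raises(EmptyStructureError):
            parse_pdb("REMARK nothing here\nEND\n")

    def test_no_duplicate_keys_on_synthetic_files(self):
        for seed in range(5):
            s, _ = make_toy_complex(ComplexSpec(n_chains=3, residues_per_chain=8,
                                                seed=seed))
            reparsed = parse_pdb(structure_to_pdb(s))
            keys = [r.key for r in reparsed.residues()]
            assert len(keys) == len(set(keys)) == s.n_residues()


class TestChainSequence:
    def test_standard_codes(self):
        s = parse_pdb(MINIMAL)
        seq, keys = chain_sequence(s, "A")
        assert seq == "AG"
        assert keys == [ResidueKey("A", 1), ResidueKey("A", 2)]

    def test_nonstandard_residue_becomes_x(self):
        lines = [
            pdb_atom(1, "CA", "ALA", "A", 1, 0, 0, 0),
            pdb_atom(2, "CA", "MSE", "A", 2, 3.8, 0, 0, record="HETATM"),
        ]
        seq, keys = chain_sequence(parse_pdb("\n".join(lines)), "A")
        assert seq == "AX"
        assert keys[1] == ResidueKey("A", 2)

    def test_length_matches_residue_count(self):
        s, _ = make_toy_complex(ComplexSpec(n_chains=2, residues_per_chain=7, seed=1))
        for chain in s.chains:
            seq, keys = chain_sequence(s, chain)
            assert len(seq) == len(keys) == len(s.chains[chain])

    def test_missing_chain(self):
        with pytest.raises(ChainNotFoundError):
            chain_sequence(parse_pdb(MINIMAL), "Z")


class TestResidueLabels:
    @pytest.mark.parametrize("label, expected", [
        ("TYR.69.D", (ResidueKey("D", 69), "TYR")),
        ("GLU..280.A", (ResidueKey("A", 280), "GLU")),
        ("THRR.57.A", (ResidueKey("A", 57), "THRR")),
        ("VSL.55.C", (ResidueKey("C", 55), "VSL")),
    ])
    def test_published_notation(self, label, expected):
        assert parse_residue_label(label) == expected

    def test_no_number_is_error(self):
        with pytest.raises(LabelFormatError):
            parse_residue_label("FOO")
        with pytest.raises(LabelFormatError):
            parse_residue_label("")

    def test_missing_chain_uses_default(self):
        key, name = parse_residue_label("ALA.225", default_chain="C")
        assert key == ResidueKey("C", 225)
        with pytest.raises(LabelFormatError):
            parse_residue_label("ALA.225")

    @given(
        name=st.sampled_from(sorted(THREE_TO_ONE)),
        number=st.integers(min_value=1, max_value=9999),
        chain=st.sampled_from("ABCDEFGHIJKLMNOPQRSTUVWXYZ"),
    )
    def test_round_trip(self, name, number, chain):
        key = ResidueKey(chain, number)
        assert parse_residue_label(format_residue_label(key, name)) == (key, name)


class TestClusterTables:
    def test_parse_rows_resolves_missing_chain_from_row(self):
        table = parse_cluster_rows("ALA.225, GLN.228, TYR.232.C, TYR.46.A\n", "X")
        keys = [k for k, _ in table.rows[0]]
        assert keys[0] == ResidueKey("C", 225)
        assert keys[1] == ResidueKey("C", 228)
        assert keys[3] == ResidueKey("A", 46)

    @pytest.mark.parametrize("pdb_id, n_rows", [
        ("4D12", 5), ("2YZE", 7), ("4MB8", 7), ("5M98", 12),
    ])
    def test_published_listings_load(self, pdb_id, n_rows):
        table = load_published_clusters(pdb_id)
        assert len(table.rows) == n_rows
        for row in table.rows:
            assert len(row) >= 2
            assert len({k.chain_id for k, _ in row}) >= 2

    def test_write_cluster_table(self, toy_linear_structure):
        cl = quat.QuaternaryCluster(
            seeds={ResidueKey("A", 2)}, neighbors={ResidueKey("B", 1)})
        text, frame = write_cluster_table(toy_linear_structure, [cl])
        assert text == "ALA.2.A, GLY.1.B\n"
        assert list(frame.columns) == [
            "structure_id", "cluster_index", "chain", "number", "name", "role"]
        assert frame.role.tolist() == ["seed", "neighbor"]

    def test_write_cluster_table_empty_and_deterministic(self, toy_linear_structure):
        text, frame = write_cluster_table(toy_linear_structure, [])
        assert text == ""
        assert frame.empty and list(frame.columns)
        cl = quat.QuaternaryCluster(
            seeds={ResidueKey("A", 2)}, neighbors={ResidueKey("B", 1)})
        out1 = write_cluster_table(toy_linear_structure, [cl])
        out2 = write_cluster_table(toy_linear_structure, [cl])
        assert out1[0] == out2[0]
        assert out1[1].equals(out2[1])


def test_write_fasta_round_trips_sequences():
    s, _ = make_toy_complex(ComplexSpec(n_chains=2, residues_per_chain=12, seed=0))
    fasta = write_fasta(s)
    records = [b for b in fasta.strip().split(">") if b]
    assert len(records) == 2
    header, *seq_lines = records[0].splitlines()
    assert "".join(seq_lines) == chain_sequence(s, "A")[0]
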