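"""Parsing, hydrogen stripping, renumbering and ensemble reading."""

import numpy as np
import pytest

from nrcontacts import (
    NumberingError,
    ParseError,
    read_snapshot_ensemble,
    read_structure,
    renumber,
    strip_hydrogens,
    write_structure,
)

from conftest import make_pdb, pdb_line


class TestReadStructure:
    def test_water_always_excluded(self, two_residue_with_water):
        s = read_structure(two_residue_with_water)
        assert list(s.residues) == [10, 11]
        assert s.ligands == ()

    def test_hetero_group_becomes_ligand_with_heavy_count(self, residue_and_ligand):
        s = read_structure(residue_and_ligand)
        assert list(s.residues) == [10]
        assert len(s.ligands) == 1
        assert s.ligands[0].component_ids == ("XYZ",)
        assert s.ligands[0].n_atoms_heavy == 5

    def test_fragment_cocktail_pooled_into_one_entity(self):
        """Several hetero fragments in one pocket count as a single ligand."""
        atoms = [("ATOM", 1, "CA", "ALA", "A", 10, 0.0, 0.0, 0.0, "C")]
        for k, comp in enumerate(["AAA", "BBB", "CCC"]):
            atoms.append(("HETATM", 2 + k, "C1", comp, "A", 201 + k, 5.0 + k, 0.0, 0.0, "C"))
        s = read_structure(make_pdb(atoms))
        assert len(s.ligands) == 1
        assert s.ligands[0].component_ids == ("AAA", "BBB", "CCC")
        assert s.ligands[0].n_atoms_total == 3

    def test_altloc_keeps_highest_occupancy_then_alphabetical(self):
        text = make_pdb(
            [
                ("ATOM", 1, "CA", "ALA", "A", 10, 1.0, 0.0, 0.0, "C", "A", "", 0.4),
                ("ATOM", 2, "CA", "ALA", "A", 10, 2.0, 0.0, 0.0, "C", "B", "", 0.6),
                ("ATOM", 3, "CB", "ALA", "A", 10, 3.0, 0.0, 0.0, "C", "A", "", 0.5),
                ("ATOM", 4, "CB", "ALA", "A", 10, 4.0, 0.0, 0.0, "C", "B", "", 0.5),
            ]
        )
        s = read_structure(text)
        coords = {a.name: a.coords[0] for a in s.residues[10]}
        assert coords["CA"] == 2.0  # higher occupancy wins
        assert coords["CB"] == 3.0  # tie broken alphabetically

    def test_insertion_codes_rejected(self):
        text = make_pdb(
            [
                ("ATOM", 1, "CA", "ALA", "A", 10, 0.0, 0.0, 0.0, "C", "", "A"),
            ]
        )
        with pytest.raises(NumberingError, match="insertion code"):
            read_structure(text)

    def test_malformed_record_names_line(self):
        good = pdb_line("ATOM", 1, "CA", "ALA", "A", 10, 0.0, 0.0, 0.0, "C")
        bad = "ATOM      2  CA  ALA A  11      not_a_number"
        with pytest.raises(ParseError, match="line 2"):
            read_structure(good + "\n" + bad + "\nEND\n")

    def test_chain_selection_defaults_to_first_polymer(self):
        text = make_pdb(
            [
                ("ATOM", 1, "CA", "ALA", "B", 10, 0.0, 0.0, 0.0, "C"),
                ("ATOM", 2, "CA", "GLY", "C", 20, 5.0, 0.0, 0.0, "C"),
                ("HETATM", 3, "C1", "XYZ", "B", 201, 1.0, 0.0, 0.0, "C"),
                ("HETATM", 4, "C1", "ZZZ", "C", 202, 6.0, 0.0, 0.0, "C"),
            ]
        )
        s = read_structure(text)
        assert list(s.residues) == [10]
        assert s.ligands[0].component_ids == ("XYZ",)
        s2 = read_structure(text, chain="C")
        assert list(s2.residues) == [20]
        assert s2.ligands[0].component_ids == ("ZZZ",)


class TestStripHydrogens:
    def test_counts(self, hydrogen_rich):
        s = read_structure(hydrogen_rich)
        assert s.has_hydrogens
        stripped = strip_hydrogens(s)
        n_protein = sum(len(atoms) for atoms in stripped.residues.values())
        assert n_protein == 7
        assert stripped.ligands[0].n_atoms_total == 3
        assert not stripped.has_hydrogens

    def test_idempotent_and_identity_without_hydrogens(self, hydrogen_rich, two_residue_with_water):
        s = strip_hydrogens(read_structure(hydrogen_rich))
        assert strip_hydrogens(s) == s
        t = read_structure(two_residue_with_water)
        assert strip_hydrogens(t) == t


class TestRenumber:
    def test_offset_zero_is_identity(self, two_residue_with_water):
        s = read_structure(two_residue_with_water)
        assert renumber(s, 0) == s

    @pytest.mark.parametrize(
        "start,offset,expected",
        [(1, 264, 265), (286, 21, 307)],  # internal→canonical; t-isoform→canonical
    )
    def test_numbering_conventions(self, start, offset, expected):
        s = read_structure(
            make_pdb([("ATOM", 1, "CA", "ALA", "A", start, 0.0, 0.0, 0.0, "C")])
        )
        assert list(renumber(s, offset).residues) == [expected]

    def test_round_trip(self, hydrogen_rich):
        s = read_structure(hydrogen_rich)
        assert renumber(renumber(s, 17), -17) == s


def test_write_read_round_trip(hydrogen_rich):
    s = read_structure(hydrogen_rich, structure_id="rt")
    back = read_structure(write_structure(s), structure_id="rt")
    assert list(back.residues) == list(s.residues)
    for i in s.residues:
        for a, b in zip(s.residues[i], back.residues[i]):
            assert a.name == b.name and a.element == b.element
            assert np.allclose(a.coords, b.coords, atol=1e-3)
    assert back.ligands[0].component_ids == s.ligands[0].component_ids
    assert back.ligands[0].n_atoms_total == s.ligands[0].n_atoms_total


class TestSnapshotEnsemble:
    def _multi_model(self, n_models: int, shift_last: bool = False) -> str:
        lines = []
        serial = 1
        for m in range(1, n_models + 1):
            lines.append(f"MODEL     {m:>4}")
            resis = [5, 6] if not (shift_last and m == n_models) else [5, 7]
            for r in resis:
                lines.append(pdb_line("ATOM", serial, "CA", "GLY", "A", r, float(m), float(r), 0.0, "C"))
                serial += 1
            lines.append("ENDMDL")
        lines.append("END")
        return "\n".join(lines) + "\n"

    def test_one_structure_per_frame_with_shared_indices(self):
        frames = list(read_snapshot_ensemble(self._multi_model(3)))
        assert len(frames) == 3
        assert all(f.residue_indices == [5, 6] for f in frames)
        # coordinates actually differ between frames
        assert frames[0].residues[5][0].coords[0] != frames[2].residues[5][0].coords[0]

    def test_mismatched_frames_rejected(self):
        from nrcontacts import EnsembleError

        with pytest.raises(EnsembleError, match="differs"):
            list(read_snapshot_ensemble(self._multi_model(3, shift_last=True)))

    def test_hydrogens_retained_in_frames(self):
        text = "\n".join(
            [
                "MODEL        1",
                pdb_line("ATOM", 1, "CA", "GLY", "A", 5, 0.0, 0.0, 0.0, "C"),
                pdb_line("ATOM", 2, "HA", "GLY", "A", 5, 0.5, 0.0, 0.0, "H"),
                "ENDMDL",
                "END",
            ]
        ) + "\n"
        (frame,) = list(read_snapshot_ensemble(text))
        assert any(a.is_hydrogen for a in frame.residues[5])
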