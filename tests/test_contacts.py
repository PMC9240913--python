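"""Contact definition: geometric boundary, neighbour exclusion, windows,
ligand vectors and frequency matrices."""

import numpy as np
import pytest

from nrcontacts import (
    EnsembleError,
    WindowError,
    frequency_from_maps,
    ligand_contact_vector,
    mean_contact_map,
    residue_contact_map,
    restrict_window,
)
from nrcontacts.contacts import from_sparse_text, to_sparse_text
from nrcontacts.synthetic_data import add_ligand, make_coordinate_fixture


def brute_force_contact_pairs(structure, cutoff, min_seq_sep, heavy_only=True):
    """Independent oracle: double loop over all atom pairs."""
    pairs = set()
    items = list(structure.residues.items())
    for a in range(len(items)):
        for b in range(a + 1, len(items)):
            i, atoms_i = items[a]
            j, atoms_j = items[b]
            if abs(i - j) < min_seq_sep:
                continue
            dmin = min(
                float(np.linalg.norm(p.coords - q.coords))
                for p in atoms_i
                for q in atoms_j
                if not (heavy_only and (p.is_hydrogen or q.is_hydrogen))
            )
            if dmin <= cutoff:
                pairs.add((i, j))
    return pairs


class TestResidueContactMap:
    @pytest.mark.parametrize(
        "distance,expected",
        [(4.5, 1), (4.51, 0), (4.499, 1)],
        ids=["at-cutoff", "just-outside", "just-inside"],
    )
    def test_cutoff_is_a_closed_bound(self, distance, expected):
        s = make_coordinate_fixture([(10, 20, distance)])
        m = residue_contact_map(s)
        assert m.entries[10 - m.lo, 20 - m.lo] == expected

    @pytest.mark.parametrize("gap", [1, 2])
    def test_sequential_neighbours_never_count(self, gap):
        s = make_coordinate_fixture([(10, 10 + gap, 3.0)])
        m = residue_contact_map(s)
        assert m.total_contacts() == 0

    def test_neighbour_separation_uses_author_numbering(self):
        # indices 10 and 13 are |Δ| = 3 apart: admissible even though they
        # are adjacent in the resolved-residue ranking
        s = make_coordinate_fixture([(10, 13, 3.0)])
        assert residue_contact_map(s).total_contacts() == 1

    def test_matches_brute_force_on_multi_pair_fixture(self):
        pairs = [(10, 20, 4.5), (30, 40, 4.0), (50, 60, 4.6), (70, 80, 3.2), (90, 95, 5.5)]
        s = make_coordinate_fixture(pairs)
        m = residue_contact_map(s)
        assert set(m.contact_pairs()) == brute_force_contact_pairs(s, 4.5, 3)

    def test_invariant_under_rigid_motion(self, rng):
        from dataclasses import replace

        s = make_coordinate_fixture([(10, 20, 4.4), (30, 44, 4.1), (21, 44, 18.0)], min_far=15.0)
        # random rotation (QR of a Gaussian matrix) + translation
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        t = rng.normal(scale=50.0, size=3)
        moved = replace(
            s,
            residues={
                i: tuple(replace(a, coords=Q @ a.coords + t) for a in atoms)
                for i, atoms in s.residues.items()
            },
        )
        assert residue_contact_map(moved).contact_pairs() == residue_contact_map(s).contact_pairs()

    def test_empty_structure_rejected(self):
        from nrcontacts.structure_io import Structure

        with pytest.raises(EnsembleError):
            residue_contact_map(Structure(id="empty", residues={}, ligands=()))


class TestLigandContactVector:
    def test_contact_and_miss(self):
        s = make_coordinate_fixture([(310, 320, 25.0)], min_far=20.0)
        pos = s.residues[320][0].coords + np.array([4.4, 0.0, 0.0])
        s = add_ligand(s, pos)
        v = ligand_contact_vector(s)
        assert v.contacted_residues() == [320]

    def test_distant_ligand_gives_zero_vector(self):
        s = make_coordinate_fixture([(310, 320, 25.0)], min_far=20.0)
        s = add_ligand(s, s.residues[320][0].coords + np.array([10.0, 0.0, 0.0]))
        assert ligand_contact_vector(s).L.sum() == 0

    def test_no_sequence_separation_rule(self):
        # the ligand may contact adjacent residues freely
        s = make_coordinate_fixture([(10, 13, 4.0)])
        s = add_ligand(s, s.residues[10][0].coords + np.array([0.0, 3.0, 0.0]))
        v = ligand_contact_vector(s)
        assert v.L[10 - v.lo] == 1

    def test_apo_structure_rejected(self):
        s = make_coordinate_fixture([(10, 20, 4.0)])
        with pytest.raises(EnsembleError, match="no ligand"):
            ligand_contact_vector(s)

    def test_restrict_vector_window(self):
        s = make_coordinate_fixture([(310, 320, 25.0)], min_far=20.0)
        s = add_ligand(s, s.residues[320][0].coords + np.array([4.0, 0.0, 0.0]))
        v = ligand_contact_vector(s).restrict(276, 475)
        assert (v.lo, v.hi) == (276, 475)
        assert v.contacted_residues() == [320]


class TestRestrictWindow:
    def test_common_region_is_200_square(self):
        s = make_coordinate_fixture([(280, 300, 4.0)])
        m = restrict_window(residue_contact_map(s), 276, 475)
        assert m.entries.shape == (200, 200)
        assert m.contact_pairs() == [(280, 300)]

    def test_restriction_to_own_window_is_identity(self):
        s = make_coordinate_fixture([(280, 300, 4.0)])
        m = residue_contact_map(s)
        r = restrict_window(m, m.lo, m.hi)
        assert np.array_equal(r.entries, m.entries)

    def test_contact_outside_window_dropped(self):
        s = make_coordinate_fixture([(280, 480, 4.0)])
        m = restrict_window(residue_contact_map(s), 276, 475)
        assert m.total_contacts() == 0

    def test_invalid_window(self):
        s = make_coordinate_fixture([(280, 300, 4.0)])
        with pytest.raises(WindowError):
            restrict_window(residue_contact_map(s), 400, 300)


class TestFrequencies:
    def test_single_frame_equals_binary_map(self):
        s = make_coordinate_fixture([(10, 20, 4.0)])
        f = mean_contact_map([s], cutoff=4.2)
        m = residue_contact_map(s, cutoff=4.2, hydrogen_policy="all_atom")
        assert f.n_frames == 1
        assert np.array_equal(f.values, m.entries.astype(float))

    def test_identical_frames_give_zero_one_frequencies(self):
        s = make_coordinate_fixture([(10, 20, 4.0)])
        f = mean_contact_map([s, s, s])
        assert set(np.unique(f.values)) <= {0.0, 1.0}

    def test_frame_count_consistency(self):
        """value * n_frames is integral: each cell counts whole frames."""
        s1 = make_coordinate_fixture([(10, 20, 4.0)])
        s2 = make_coordinate_fixture([(10, 20, 5.0)])
        f = mean_contact_map([s1, s1, s2])
        assert np.allclose(f.values * f.n_frames, np.round(f.values * f.n_frames))
        assert f.frequency(10, 20) == pytest.approx(2 / 3)

    def test_mismatched_frames_rejected(self):
        s1 = make_coordinate_fixture([(10, 20, 4.0)])
        s2 = make_coordinate_fixture([(10, 30, 4.0)])
        with pytest.raises(EnsembleError):
            mean_contact_map([s1, s2])

    def test_no_frames_rejected(self):
        with pytest.raises(EnsembleError):
            frequency_from_maps([])


def test_sparse_text_round_trip():
    s = make_coordinate_fixture([(10, 20, 4.0), (30, 44, 4.2)])
    m = residue_contact_map(s)
    back = from_sparse_text(to_sparse_text(m))
    assert back.contact_pairs() == m.contact_pairs()
    assert (back.lo, back.hi, back.cutoff, back.min_seq_sep) == (m.lo, m.hi, m.cutoff, m.min_seq_sep)
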