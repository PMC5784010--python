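"""Structure I/O, histone typing, base pairing and crystal expansion."""

import gemmi
import numpy as np
import pandas as pd
import pytest

import ncpgeom as ng
from ncpgeom import refdata
from ncpgeom.structure import (AmbiguousTypingError, DomainTableError,
                               IncompleteNCPError, RegisterError,
                               _orthogonalization_matrix, _ungapped_identity)

ALTLOC_PDB = """\
CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1
ATOM      1  CA AALA A   1      10.000  10.000  10.000  0.60 10.00           C
ATOM      2  CA BALA A   1      11.000  11.000  11.000  0.40 10.00           C
END
"""


def test_pdb_round_trip_preserves_coordinates_and_identity(toy, tmp_path):
    model, _ = toy
    am = ng.AtomicModel(atoms=model.atoms)
    path = tmp_path / "toy.pdb"
    ng.write_pdb(am, path)
    back = ng.load_structure(path, format="pdb")
    assert back.chains() == am.chains()
    assert len(back.atoms) == len(am.atoms)
    a = am.atoms.sort_values(["chain", "resseq", "name"])
    b = back.atoms.sort_values(["chain", "resseq", "name"])
    assert list(a["resname"]) == list(b["resname"])
    d = np.abs(a[["x", "y", "z"]].to_numpy() - b[["x", "y", "z"]].to_numpy())
    assert d.max() <= 1e-3 + 1e-12      # fixed-width PDB precision


def test_altloc_resolved_to_highest_occupancy(tmp_path):
    path = tmp_path / "altloc.pdb"
    path.write_text(ALTLOC_PDB)
    model = ng.load_structure(path)
    assert len(model.atoms) == 1
    row = model.atoms.iloc[0]
    assert row["altloc"] == "A" and row["occ"] == pytest.approx(0.6)
    assert row["x"] == pytest.approx(10.0)


def test_unreadable_and_missing_files_raise(tmp_path):
    bad = tmp_path / "bad.cif"
    bad.write_text("this is not a structure file\n")
    with pytest.raises(Exception):
        ng.load_structure(bad, format="mmcif")
    with pytest.raises(FileNotFoundError):
        ng.load_structure(tmp_path / "absent.pdb")


def test_toy_crystal_file_reports_its_symmetry_operators(toy, tmp_path):
    model, _ = toy
    path = ng.make_toy_crystal(model, tmp_path / "toy.pdb",
                               spacegroup="P 21 21 21", cell=(80.0, 200.0, 90.0))
    back = ng.load_structure(path)
    assert back.cell[:3] == pytest.approx((80.0, 200.0, 90.0))
    assert len(back.operations) == 4
    R0, t0 = back.operations[0]
    assert np.allclose(R0, np.eye(3)) and np.allclose(t0, 0.0)


class TestHistoneTyping:
    def test_reference_sequences_self_match(self):
        for seq in refdata.HISTONE_SEQUENCES.values():
            assert _ungapped_identity(seq, seq) == 1.0

    def test_toy_octamer_fully_typed(self, toy):
        model, _ = toy
        types = sorted(t for t, _ in model.chain_types.values())
        assert types == ["H2A", "H2A", "H2B", "H2B", "H3", "H3", "H4", "H4"]

    def test_typing_is_permutation_invariant(self, toy, tmp_path):
        model, _ = toy
        shuffled = model.atoms.sample(frac=1.0, random_state=3).reset_index(drop=True)
        am = ng.AtomicModel(atoms=shuffled)
        ncps = ng.identify_components(am)
        assert ncps[0].chain_types == model.chain_types

    def test_missing_histone_chain_is_incomplete(self, toy):
        model, _ = toy
        am = ng.AtomicModel(atoms=model.atoms[model.atoms["chain"] != "A"])
        with pytest.raises(IncompleteNCPError):
            ng.identify_components(am)

    def test_ambiguous_typing_raises(self, toy):
        model, _ = toy
        am = ng.AtomicModel(atoms=model.atoms)
        same = refdata.HISTONE_SEQUENCES["H3"]
        refs = {"H3": same, "H4": same, "H2A": refdata.HISTONE_SEQUENCES["H2A"],
                "H2B": refdata.HISTONE_SEQUENCES["H2B"]}
        with pytest.raises(AmbiguousTypingError):
            ng.identify_components(am, references=refs)


class TestDomains:
    def test_empty_tail_table_makes_all_residues_globular(self, toy):
        model, _ = toy
        m2 = ng.identify_components(ng.AtomicModel(atoms=model.atoms))[0]
        ng.assign_domains(m2, ng.TailTable.empty())
        assert all(v == "globular" for v in m2.domains.values())

    def test_range_beyond_chain_length_raises(self, toy):
        model, _ = toy
        m2 = ng.identify_components(ng.AtomicModel(atoms=model.atoms))[0]
        table = ng.TailTable({"H4": [(1, 24), (150, 160)]})
        with pytest.raises(DomainTableError):
            ng.assign_domains(m2, table)

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(DomainTableError):
            ng.TailTable({"H3": [(1, 36), (30, 40)]})

    def test_charged_residue_counts_split_by_domain(self, toy):
        model, _ = toy
        full = model.charged_residue_counts()
        tails = model.charged_residue_counts("tail")
        glob = model.charged_residue_counts("globular")
        for k in full:
            assert full[k] == tails[k] + glob[k]


class TestBasePairing:
    def test_odd_count_has_central_zero_index(self, toy):
        model, _ = toy
        idx = [bp.index for bp in model.base_pairs]
        assert idx == sorted(idx)
        assert idx[0] == -73 and idx[-1] == 73 and 0 in idx

    def test_even_count_has_half_integer_indices(self):
        model, _ = ng.make_ideal_sh_dna(ng.SyntheticSpec(bp=146))
        ng.pair_bases(model)
        idx = [bp.index for bp in model.base_pairs]
        assert idx[0] == -72.5 and idx[-1] == 72.5
        assert 0 not in idx and 0.5 in idx and -0.5 in idx

    def test_c1_distances_within_tolerance_on_ideal_duplex(self, toy):
        # pair_bases would raise RegisterError otherwise; also check directly
        model, _ = toy
        ng.pair_bases(model)   # idempotent, no register error

    def test_misregistered_strands_raise(self):
        model, _ = ng.make_ideal_sh_dna(ng.SyntheticSpec())
        s1, s2 = model.dna_strands
        model.dna_strands = (s1, list(reversed(s2)))   # parallel pairing
        with pytest.raises(RegisterError):
            ng.pair_bases(model)

    def test_centroid_is_mean_of_base_atoms(self, toy):
        model, _ = toy
        bp0 = next(bp for bp in model.base_pairs if bp.index == 0)
        sub = model.atoms
        n1 = []
        for chain, resseq, _ in (bp0.res1, bp0.res2):
            a = sub[(sub["chain"] == chain) & (sub["resseq"] == resseq)
                    & (sub["name"] == "N1")]
            n1.append(a[["x", "y", "z"]].to_numpy(float)[0])
        assert np.allclose(bp0.centroid, np.mean(n1, axis=0))


class TestCrystalExpansion:
    def test_expansion_matches_brute_force_enumeration(self, toy, tmp_path):
        model, _ = toy
        path = ng.make_toy_crystal(model, tmp_path / "c.pdb",
                                   spacegroup="P 21 21 21",
                                   cell=(80.0, 200.0, 90.0))
        ncp = ng.identify_components(ng.load_structure(path))[0]
        ng.assign_domains(ncp)
        ng.pair_bases(ncp)
        com = ncp.globular_com()
        placements = ng.expand_crystal(ncp, max_com_distance=120.0)

        # independent enumeration straight from gemmi's operator list
        sg = gemmi.find_spacegroup_by_name("P 21 21 21")
        M = _orthogonalization_matrix((80.0, 200.0, 90.0, 90.0, 90.0, 90.0))
        Minv = np.linalg.inv(M)
        frac = Minv @ com
        expected = []
        for op in sg.operations():
            R = np.array(op.rot, float) / op.DEN
            t = np.array(op.tran, float) / op.DEN
            for na in (-1, 0, 1):
                for nb in (-1, 0, 1):
                    for nc in (-1, 0, 1):
                        new = M @ (R @ frac + t + np.array([na, nb, nc]))
                        d = np.linalg.norm(new - com)
                        if 1e-6 < d <= 120.0:
                            expected.append(tuple(np.round(new, 6)))
        got = [tuple(np.round(p.com, 6)) for p in placements if not p.is_identity]
        assert sorted(got) == sorted(expected)

    def test_placements_are_isometries(self, toy, tmp_path):
        model, _ = toy
        path = ng.make_toy_crystal(model, tmp_path / "c.pdb",
                                   spacegroup="P 21 21 21",
                                   cell=(80.0, 200.0, 90.0))
        ncp = ng.identify_components(ng.load_structure(path))[0]
        ng.assign_domains(ncp)
        xyz = ncp.atoms[["x", "y", "z"]].to_numpy(float)[:50]
        d0 = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
        for p in ng.expand_crystal(ncp, 120.0)[1:3]:
            moved = p.transform_points(xyz)
            d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
            assert np.abs(d1 - d0).max() < 1e-6

    def test_zero_reach_gives_empty_neighbour_list(self, toy, tmp_path):
        model, _ = toy
        path = ng.make_toy_crystal(model, tmp_path / "c.pdb", spacegroup="P 1",
                                   cell=(150.0, 150.0, 60.0))
        ncp = ng.identify_components(ng.load_structure(path))[0]
        ng.assign_domains(ncp)
        placements = ng.expand_crystal(ncp, max_com_distance=0.0)
        assert len(placements) == 1 and placements[0].is_identity

    def test_p1_neighbours_are_pure_lattice_translations(self, toy, tmp_path):
        model, _ = toy
        path = ng.make_toy_crystal(model, tmp_path / "c.pdb", spacegroup="P 1",
                                   cell=(150.0, 150.0, 60.0))
        ncp = ng.identify_components(ng.load_structure(path))[0]
        ng.assign_domains(ncp)
        for p in ng.expand_crystal(ncp, 100.0)[1:]:
            assert np.allclose(p.rotation, np.eye(3))
            assert p.op_id == 0 and p.lattice != (0, 0, 0)

    def test_missing_cell_raises_helpful_error(self, toy):
        model, _ = toy
        with pytest.raises(ValueError, match="cell"):
            ng.expand_crystal(model)
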