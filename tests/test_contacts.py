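"""Ionic contacts, charge budgets and the acidic patch."""

import numpy as np
import pandas as pd
import pytest

import ncpgeom as ng
from ncpgeom.structure import ATOM_COLUMNS


def _mini_model(residues, dna=()):
    """Hand-built model: residues = [(chain, resseq, resname, atom, xyz)]."""
    rows = []
    for i, (chain, resseq, resname, atom, xyz) in enumerate(list(residues) + list(dna)):
        elem = "P" if atom == "P" else ("N" if atom.startswith("N") else "C")
        rows.append((i + 1, atom, "", resname, resseq, chain, elem, 1.0, *xyz))
    atoms = pd.DataFrame(rows, columns=ATOM_COLUMNS)
    hist_chains = sorted({r[0] for r in residues})
    model = ng.NCPModel(atoms=atoms,
                        chain_types={c: ("H3", i) for i, c in enumerate(hist_chains)},
                        dna_strands=([], []))
    model.domains = {(r[0], r[1]): "globular" for r in residues}
    return model


def test_cutoff_boundary():
    for d, expected in [(7.4, 1), (7.6, 0)]:
        model = _mini_model([("A", 1, "LYS", "NZ", (0, 0, 0))],
                            dna=[("I", 1, "DA", "P", (d, 0, 0))])
        cs = ng.ion_contacts(model)
        assert cs.count("LYS", "P") == expected


def test_unique_residue_pairs_take_minimum_distance():
    # one Arg with two phosphates of the same residue within reach would be
    # impossible; instead check Lys vs Glu counted once per residue pair
    model = _mini_model([("A", 1, "LYS", "NZ", (0, 0, 0)),
                         ("A", 2, "GLU", "CD", (4.0, 0, 0)),
                         ("A", 3, "GLU", "CD", (0, 5.0, 0))])
    cs = ng.ion_contacts(model)
    assert cs.count("LYS", "carboxylate") == 2
    assert len(cs.contacts) == 2
    assert min(c.distance for c in cs.contacts) == pytest.approx(4.0)


def test_matches_brute_force_all_pairs_scan(rng):
    """The kd-tree implementation equals an O(n^2) scan on random markers."""
    n_bas, n_acid, n_p = 120, 100, 150
    pos = rng.uniform(0, 60, (n_bas + n_acid + n_p, 3))
    residues, dna = [], []
    for i in range(n_bas):
        rn, at = ("LYS", "NZ") if i % 2 else ("ARG", "CZ")
        residues.append(("A", i + 1, rn, at, pos[i]))
    for j in range(n_acid):
        rn, at = ("GLU", "CD") if j % 2 else ("ASP", "CG")
        residues.append(("B", j + 1, rn, at, pos[n_bas + j]))
    for k in range(n_p):
        dna.append(("I", k + 1, "DA", "P", pos[n_bas + n_acid + k]))
    model = _mini_model(residues, dna)
    cs = ng.ion_contacts(model)

    got = {(c.basic, c.partner): c.distance for c in cs.contacts}
    expected = {}
    cutoff = 7.5
    basics = [r for r in residues if r[2] in ("LYS", "ARG")]
    acceptors = ([r for r in residues if r[2] in ("GLU", "ASP")]
                 + [(c, s, "P", a, x) for c, s, _, a, x in dna])
    for cb, sb, rb, _, xb in basics:
        for ca, sa, ra, _, xa in acceptors:
            d = float(np.linalg.norm(np.asarray(xb) - np.asarray(xa)))
            if d < cutoff:
                expected[((cb, sb, rb), (ca, sa, ra))] = d
    assert got.keys() == expected.keys()
    for k in got:
        assert got[k] == pytest.approx(expected[k])


def test_contacts_invariant_under_rigid_motion_and_reordering(rng):
    from ncpgeom.geometry import random_rotation
    pos = rng.uniform(0, 40, (60, 3))
    residues = [("A", i + 1, ["LYS", "ARG", "GLU", "ASP"][i % 4],
                 {"LYS": "NZ", "ARG": "CZ", "GLU": "CD", "ASP": "CG"}[
                     ["LYS", "ARG", "GLU", "ASP"][i % 4]], pos[i])
                for i in range(40)]
    dna = [("I", k + 1, "DA", "P", pos[40 + k]) for k in range(20)]
    model = _mini_model(residues, dna)
    base = ng.ion_contacts(model).summary()
    assert sum(base.values()) > 0
    moved = _mini_model(residues, dna)
    moved.atoms = moved.atoms.sample(frac=1.0, random_state=1)
    R = random_rotation(rng)
    xyz = moved.atoms[["x", "y", "z"]].to_numpy(float) @ R.T + rng.uniform(-9, 9, 3)
    moved.atoms = moved.atoms.copy()
    moved.atoms[["x", "y", "z"]] = xyz
    assert ng.ion_contacts(moved).summary() == base


def test_missing_marker_atoms_warn_and_skip():
    model = _mini_model([("A", 1, "LYS", "CA", (0, 0, 0)),
                         ("A", 2, "GLU", "CD", (4, 0, 0))])
    with pytest.warns(UserWarning, match="marker"):
        cs = ng.ion_contacts(model)
    assert cs.skipped_residues == 1 and len(cs.contacts) == 0


def test_inter_ncp_flag_for_placed_pair():
    model = _mini_model([("A", 1, "LYS", "NZ", (0.0, 0.0, 0.0))],
                        dna=[("I", 1, "DA", "P", (20.0, 0.0, 0.0))])
    placement = ng.NCPPlacement(ncp=model, rotation=np.eye(3),
                                translation=np.array([-14.0, 0.0, 0.0]),
                                op_id=1, lattice=(0, 0, 0), com=np.zeros(3))
    # the placed copy's phosphate lands 6 A from the reference lysine
    cs = ng.ion_contacts(model, other=model, other_placement=placement)
    assert cs.count(inter_ncp=True) == 1
    assert cs.count(inter_ncp=False) == 0    # intra P is 20 A away


class TestChargeBudget:
    def test_krde_peptide_is_neutral(self):
        model = _mini_model([("A", i + 1, rn, "CA", (3.8 * i, 0, 0))
                             for i, rn in enumerate(["LYS", "ARG", "ASP", "GLU"])])
        assert ng.charge_budget(model).total == 0

    def test_toy_ncp_budget_components(self, toy):
        model, _ = toy
        b = ng.charge_budget(model)
        # 147 bp duplex with every phosphate present
        assert b.dna == -294
        assert b.total == b.dna + b.gho + b.tails
        counts_t = model.charged_residue_counts("tail")
        counts_g = model.charged_residue_counts("globular")
        assert b.tails == (counts_t["LYS"] + counts_t["ARG"]
                           - counts_t["GLU"] - counts_t["ASP"])
        assert b.gho == (counts_g["LYS"] + counts_g["ARG"]
                         - counts_g["GLU"] - counts_g["ASP"])

    def test_terminal_phosphate_convention(self, toy):
        model, _ = toy
        with_term = ng.charge_budget(model, count_terminal_phosphates=True)
        without = ng.charge_budget(model, count_terminal_phosphates=False)
        assert with_term.dna == -294 and without.dna == -292

    def test_budget_additivity(self, toy):
        model, _ = toy
        b = ng.charge_budget(model)
        assert b.total == b.dna + b.gho + b.tails


class TestAcidicPatch:
    def test_reference_octamer_has_patch_on_both_faces(self, toy):
        model, _ = toy
        present, missing = ng.acidic_patch_residues(model)
        # six canonical H2A residues per copy resolve; the H2B glutamate is
        # listed at its alternative numbering and reported missing, not fatal
        by_type = {}
        for chain, resseq, resname in present:
            htype = model.chain_types[chain][0]
            by_type.setdefault(htype, []).append(resseq)
        assert sorted(set(by_type["H2A"])) == [56, 61, 64, 90, 91, 92]
        assert len(present) + len(missing) == 14

    def test_missing_h2a_warns_and_reports_empty(self, toy):
        model, _ = toy
        keep = {c: t for c, t in model.chain_types.items() if t[0] != "H2A"}
        sub = ng.NCPModel(atoms=model.atoms[model.atoms["chain"].isin(keep)],
                          chain_types=keep, dna_strands=model.dna_strands)
        with pytest.warns(UserWarning, match="H2A"):
            present, missing = ng.acidic_patch_residues(sub)
        assert not any(m[2] in ("GLU", "ASP") and m[0] == "H2A" for m in present)

    def test_renamed_residues_go_to_missing_list(self, toy):
        model, _ = toy
        renamed = ng.NCPModel(atoms=model.atoms.copy(),
                              chain_types=model.chain_types,
                              dna_strands=model.dna_strands)
        h2a = [c for c, (t, _) in model.chain_types.items() if t == "H2A"]
        mask = renamed.atoms["chain"].isin(h2a) & (renamed.atoms["resseq"] == 56)
        renamed.atoms.loc[mask, "resname"] = "GLN"
        present, missing = ng.acidic_patch_residues(renamed)
        assert sum(1 for m in missing if m[1] == 56) == 2
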