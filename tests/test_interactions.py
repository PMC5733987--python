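import math
import random

import pytest

from protchar import (
    FixtureSpec,
    build_toy_structure,
    find_pose_hbonds,
    interface_residues,
    summarize_pose,
)
from protchar.structure_io import Atom, Residue, Structure


def _random_dimer(rng, n_per_chain=5):
    chains = {}
    serial = 0
    for chain_id, x0 in (("A", 0.0), ("B", rng.uniform(2.0, 12.0))):
        residues = []
        for i in range(n_per_chain):
            atoms = []
            for an in ("N", "CA", "C", "O"):
                serial += 1
                xyz = (x0 + rng.uniform(0, 8), rng.uniform(0, 8), rng.uniform(0, 8))
                atoms.append(Atom(an, an[0], xyz, serial=serial))
            residues.append(Residue("GLY", i + 1, chain_id, "", atoms))
        chains[chain_id] = residues
    return Structure(chains=chains)


def _brute_force_contacts(structure, a, b, cutoff):
    out = set()
    for ra in structure.chains[a]:
        for rb in structure.chains[b]:
            best = min(
                math.dist(x.coords, y.coords)
                for x in ra.atoms for y in rb.atoms
                if x.element != "H" and y.element != "H"
            )
            if best <= cutoff:
                out.add((ra.id, rb.id, round(best, 9)))
    return out


class TestInterface:
    def test_constructed_single_contact(self):
        s = build_toy_structure(FixtureSpec("two_chain_contact", {"d": 3.5}))
        contacts, per_chain = interface_residues(s, "A", "B", cutoff=4.0)
        assert len(contacts) == 1
        assert contacts[0].min_distance == pytest.approx(3.5)
        assert per_chain == {"A": ["GLY1"], "B": ["GLY1"]}

    def test_cutoff_below_min_distance(self):
        s = build_toy_structure(FixtureSpec("two_chain_contact", {"d": 3.5}))
        contacts, _ = interface_residues(s, "A", "B", cutoff=3.0)
        assert contacts == []

    def test_missing_chain(self):
        s = build_toy_structure(FixtureSpec("two_chain_contact", {"d": 3.5}))
        with pytest.raises(KeyError):
            interface_residues(s, "A", "C")

    def test_brute_force_oracle_random_dimers(self):
        rng = random.Random(77)
        for _ in range(100):
            s = _random_dimer(rng)
            cutoff = rng.uniform(2.0, 8.0)
            contacts, _ = interface_residues(s, "A", "B", cutoff=cutoff)
            got = {(c.residue_a, c.residue_b, round(c.min_distance, 9)) for c in contacts}
            assert got == _brute_force_contacts(s, "A", "B", cutoff)

    def test_symmetry(self):
        rng = random.Random(5)
        s = _random_dimer(rng)
        ab, _ = interface_residues(s, "A", "B", cutoff=5.0)
        ba, _ = interface_residues(s, "B", "A", cutoff=5.0)
        assert {(c.residue_a, c.residue_b) for c in ab} == \
            {(c.residue_b, c.residue_a) for c in ba}


class TestPoseHbonds:
    def test_constructed_bond(self):
        s = build_toy_structure(FixtureSpec("hbond_complex", {"d": 3.0}))
        bonds = find_pose_hbonds(s, s.het_groups)
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(3.0)
        assert bonds[0].receptor_atom == "NH1"

    def test_beyond_cutoff(self):
        s = build_toy_structure(FixtureSpec("hbond_complex", {"d": 4.0}))
        assert find_pose_hbonds(s, s.het_groups, dist_cutoff=3.5) == []

    def test_angle_gate_with_explicit_h(self):
        linear = build_toy_structure(
            FixtureSpec("hbond_complex", {"d": 3.0, "angle": 180.0, "explicit_h": True}))
        bent = build_toy_structure(
            FixtureSpec("hbond_complex", {"d": 3.0, "angle": 90.0, "explicit_h": True}))
        good = find_pose_hbonds(linear, linear.het_groups)
        assert any(b.receptor_atom == "NH1" and b.angle == pytest.approx(180.0, abs=0.5)
                   for b in good)
        assert all(b.receptor_atom != "NH1" for b in find_pose_hbonds(bent, bent.het_groups))

    def test_ligand_without_polar_atoms(self):
        s = build_toy_structure(FixtureSpec("hbond_complex", {"d": 3.0}))
        carbon_only = Residue("LIG", 1, "L", "", [Atom("C1", "C", (3.0, 0.0, 0.0))])
        assert find_pose_hbonds(s, [carbon_only]) == []

    def test_monotone_in_distance_cutoff(self):
        rng = random.Random(99)
        s, lig = _random_complex(rng)
        sets = []
        for cutoff in (2.5, 3.0, 3.5, 4.0):
            bonds = find_pose_hbonds(s, lig, dist_cutoff=cutoff)
            sets.append({(b.receptor_residue, b.receptor_atom, b.ligand_atom)
                         for b in bonds})
        for smaller, larger in zip(sets, sets[1:]):
            assert smaller <= larger

    def test_enumeration_oracle_random_complexes(self):
        rng = random.Random(41)
        for _ in range(100):
            s, lig = _random_complex(rng)
            cutoff = rng.uniform(2.5, 4.5)
            bonds = find_pose_hbonds(s, lig, dist_cutoff=cutoff)
            got = {(b.receptor_residue, b.receptor_atom, b.ligand_atom) for b in bonds}
            assert got == _brute_force_hbonds(s, lig, cutoff)


def _random_complex(rng):
    """Receptor of Ser/Lys/Gly residues (no hydrogens) plus a phosphate-like ligand."""
    residues = []
    serial = 0
    for i in range(4):
        name = rng.choice(["SER", "LYS", "GLY"])
        atom_names = {"SER": ("N", "CA", "C", "O", "OG"),
                      "LYS": ("N", "CA", "C", "O", "NZ"),
                      "GLY": ("N", "CA", "C", "O")}[name]
        atoms = []
        for an in atom_names:
            serial += 1
            xyz = (rng.uniform(0, 6), rng.uniform(0, 6), rng.uniform(0, 6))
            atoms.append(Atom(an, an[0], xyz, serial=serial))
        residues.append(Residue(name, i + 1, "A", "", atoms))
    lig_atoms = [Atom("P1", "P", (rng.uniform(0, 6),) * 3, serial=90)]
    for k in range(3):
        lig_atoms.append(Atom(f"O{k+1}", "O",
                              (rng.uniform(0, 6), rng.uniform(0, 6), rng.uniform(0, 6)),
                              serial=91 + k))
    lig = [Residue("IHP", 1, "L", "", lig_atoms)]
    return Structure(chains={"A": residues}), lig


def _brute_force_hbonds(structure, lig, cutoff):
    """Independent donor x acceptor enumeration (no hydrogens anywhere)."""
    donors = {"SER": {"N", "OG"}, "LYS": {"N", "NZ"}, "GLY": {"N"}}
    out = set()
    lig_polar = [(r, a) for r in lig for a in r.atoms if a.element in "NO"]
    for res in structure.chains["A"]:
        for atom in res.atoms:
            is_donor = atom.name in donors[res.name]
            is_acceptor = atom.element == "O"
            if not (is_donor or is_acceptor):
                continue
            for lres, latom in lig_polar:
                if math.dist(atom.coords, latom.coords) <= cutoff:
                    out.add((res.id, atom.name, latom.name))
    return out


class TestSummarize:
    def test_count_and_multiset(self):
        s = build_toy_structure(FixtureSpec("hbond_complex", {"d": 3.0}))
        bonds = find_pose_hbonds(s, s.het_groups)
        summary = summarize_pose(bonds)
        assert summary["n_hbonds"] == len(bonds) == len(summary["residues"])

    def test_empty(self):
        assert summarize_pose([]) == {"n_hbonds": 0, "residues": []}

    def test_repeated_residues_kept(self):
        s = build_toy_structure(FixtureSpec("hbond_complex", {"d": 3.0}))
        bonds = find_pose_hbonds(s, s.het_groups) * 2
        assert summarize_pose(bonds)["residues"].count("ARG1") == 2
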