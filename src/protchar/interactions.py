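"""Inter-chain interface detection and receptor-ligand hydrogen-bond
enumeration on given poses (no docking)."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .structure_io import Atom, Residue, Structure

log = logging.getLogger(__name__)

# heavy donor atoms carrying at least one polar hydrogen in standard residues
PROTEIN_DONORS = {
    ("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("ASN", "ND2"), ("GLN", "NE2"),
    ("TRP", "NE1"), ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
}
PROTEIN_N_ACCEPTORS = {("HIS", "ND1"), ("HIS", "NE2")}

DEFAULT_DIST_CUTOFF = 3.5
DEFAULT_ANGLE_MIN = 120.0


@dataclass(frozen=True)
class ContactRecord:
    residue_a: str
    residue_b: str
    chain_a: str
    chain_b: str
    min_distance: float


@dataclass(frozen=True)
class PoseHBond:
    receptor_residue: str
    receptor_atom: str
    ligand_atom: str
    distance: float
    angle: float | None
    donor_side: str  # "receptor" | "ligand"


def interface_residues(structure: Structure, chain_a: str, chain_b: str,
                       cutoff: float = 4.0
                       ) -> tuple[list[ContactRecord], dict[str, list[str]]]:
    """Residue pairs of two chains with heavy-atom minimum distance <= cutoff.

    Returns the pair list plus a per-chain deduplicated residue list.
    """
    res_a = structure.chain(chain_a)
    res_b = structure.chain(chain_b)
    contacts = []
    for ra in res_a:
        heavy_a = [a for a in ra.atoms if a.is_heavy]
        for rb in res_b:
            best = math.inf
            for aa in heavy_a:
                for ab in rb.atoms:
                    if not ab.is_heavy:
                        continue
                    d = aa.distance(ab)
                    if d < best:
                        best = d
            if best <= cutoff:
                contacts.append(ContactRecord(ra.id, rb.id, chain_a, chain_b, best))
    per_chain = {
        chain_a: sorted({c.residue_a for c in contacts}),
        chain_b: sorted({c.residue_b for c in contacts}),
    }
    return contacts, per_chain


def _protein_donor_atoms(res: Residue):
    for a in res.atoms:
        if a.name == "N" and a.element == "N" and res.name != "PRO":
            yield a  # backbone amide
        elif (res.name, a.name) in PROTEIN_DONORS:
            yield a


def _protein_acceptor_atoms(res: Residue):
    for a in res.atoms:
        if a.element == "O":
            yield a
        elif (res.name, a.name) in PROTEIN_N_ACCEPTORS:
            yield a


def _explicit_hydrogens(res: Residue, heavy: Atom, max_bond: float = 1.25):
    return [a for a in res.atoms if a.element == "H" and heavy.distance(a) <= max_bond]


def _angle(donor: Atom, h: Atom, acceptor: Atom) -> float:
    dv = tuple(donor.coords[i] - h.coords[i] for i in range(3))
    av = tuple(acceptor.coords[i] - h.coords[i] for i in range(3))
    dot = sum(dv[i] * av[i] for i in range(3))
    nd = math.sqrt(sum(x * x for x in dv))
    na = math.sqrt(sum(x * x for x in av))
    cosang = max(-1.0, min(1.0, dot / (nd * na)))
    return math.degrees(math.acos(cosang))


def _pair_geometry_ok(donor_res: Residue, donor: Atom, acceptor: Atom,
                      dist_cutoff: float, angle_min: float
                      ) -> tuple[bool, float, float | None]:
    d = donor.distance(acceptor)
    if d > dist_cutoff:
        return False, d, None
    hs = _explicit_hydrogens(donor_res, donor)
    if not hs:
        return True, d, None  # no H available: distance-only criterion
    best = max(_angle(donor, h, acceptor) for h in hs)
    return best >= angle_min, d, best


def find_pose_hbonds(receptor: Structure, ligand: Residue | list[Residue],
                     dist_cutoff: float = DEFAULT_DIST_CUTOFF,
                     angle_min: float = DEFAULT_ANGLE_MIN) -> list[PoseHBond]:
    """Hydrogen bonds between receptor polymer chains and a ligand pose.

    Donor-acceptor pairs of N/O heavy atoms within ``dist_cutoff``; the
    D-H...A angle test applies only when an explicit hydrogen rides the
    donor. Results are sorted by distance.
    """
    lig_residues = [ligand] if isinstance(ligand, Residue) else list(ligand)
    lig_polar = [
        (res, a) for res in lig_residues for a in res.atoms if a.element in ("N", "O")
    ]
    if not lig_polar:
        log.warning("ligand has no N/O atoms; no hydrogen bonds possible")
        return []

    bonds = []
    for chain_res in receptor.chains.values():
        for res in chain_res:
            # receptor donates to ligand N/O acceptors
            for donor in _protein_donor_atoms(res):
                for lres, lat in lig_polar:
                    ok, d, ang = _pair_geometry_ok(res, donor, lat, dist_cutoff, angle_min)
                    if ok:
                        bonds.append(PoseHBond(res.id, donor.name, lat.name, d, ang,
                                               "receptor"))
            # ligand N/O (with H if present) donates to receptor acceptors
            for acceptor in _protein_acceptor_atoms(res):
                for lres, lat in lig_polar:
                    ok, d, ang = _pair_geometry_ok(lres, lat, acceptor, dist_cutoff,
                                                   angle_min)
                    if ok:
                        bonds.append(PoseHBond(res.id, acceptor.name, lat.name, d, ang,
                                               "ligand"))
    # one bond per donor/acceptor atom pair (a pair may qualify in both directions)
    unique: dict[tuple[str, str, str], PoseHBond] = {}
    for b in sorted(bonds, key=lambda b: b.distance):
        unique.setdefault((b.receptor_residue, b.receptor_atom, b.ligand_atom), b)
    return sorted(unique.values(), key=lambda b: b.distance)


def summarize_pose(hbonds: list[PoseHBond]) -> dict:
    """Table-style pose summary: bond count plus the residue multiset."""
    return {
        "n_hbonds": len(hbonds),
        "residues": [b.receptor_residue for b in hbonds],
    }
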