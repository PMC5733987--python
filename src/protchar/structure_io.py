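"""Minimal PDB-format reader/writer and atom selection.

Dialect: coordinates are parsed strictly from columns 31-54; trailing
fields (occupancy, B-factor, element) are read when present, tolerated
when absent. Only the first MODEL block is kept. Alternate locations are
resolved to the highest occupancy (ties: altloc 'A', then blank). PDBQT
files are accepted read-only (AutoDock atom types mapped to elements,
charges ignored).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Iterator

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_NAMES = {"HOH", "WAT", "DOD"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

# AutoDock (PDBQT) atom types that do not start with their element letter
_PDBQT_TYPES = {"A": "C", "OA": "O", "NA": "N", "SA": "S", "HD": "H", "HS": "H"}


class PDBFormatError(ValueError):
    pass


@dataclass
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]
    occupancy: float = 1.0
    altloc: str = ""
    serial: int = 0

    def distance(self, other: "Atom") -> float:
        ax, ay, az = self.coords
        bx, by, bz = other.coords
        return math.sqrt((ax - bx) ** 2 + (ay - by) ** 2 + (az - bz) ** 2)

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


@dataclass
class Residue:
    name: str
    number: int
    chain_id: str
    icode: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def is_water(self) -> bool:
        return self.name in WATER_NAMES

    @property
    def id(self) -> str:
        return f"{self.name}{self.number}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Structure:
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    het_groups: list[Residue] = field(default_factory=list)

    def chain(self, chain_id: str) -> list[Residue]:
        try:
            return self.chains[chain_id]
        except KeyError:
            raise KeyError(
                f"chain {chain_id!r} not present; have {sorted(self.chains)}"
            ) from None

    def residues(self) -> Iterator[Residue]:
        for residues in self.chains.values():
            yield from residues
        yield from self.het_groups

    def atoms(self) -> Iterator[Atom]:
        for res in self.residues():
            yield from res.atoms


def _element_from_fields(name: str, element_field: str, pdbqt: bool) -> str:
    ef = element_field.strip()
    if ef:
        if pdbqt:
            return _PDBQT_TYPES.get(ef, ef[0].upper())
        return ef[0].upper() + ef[1:].lower() if len(ef) > 1 else ef.upper()
    stripped = name.strip().lstrip("0123456789")
    return stripped[:1].upper() if stripped else "X"


def _parse_atom_line(line: str, pdbqt: bool) -> tuple[str, str, int, str, Atom]:
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBFormatError(f"malformed coordinate field: {line.rstrip()!r}") from exc
    if not all(math.isfinite(v) for v in (x, y, z)):
        raise PDBFormatError(f"non-finite coordinates: {line.rstrip()!r}")
    name = line[12:16].strip()
    altloc = line[16].strip()
    resname = line[17:20].strip()
    chain_id = line[21].strip() or " "
    try:
        resnum = int(line[22:26])
    except ValueError as exc:
        raise PDBFormatError(f"malformed residue number: {line.rstrip()!r}") from exc
    icode = line[26].strip()
    try:
        occ = float(line[54:60])
    except (ValueError, IndexError):
        occ = 1.0
    try:
        serial = int(line[6:11])
    except ValueError:
        serial = 0
    element = _element_from_fields(name, line[76:78] if len(line) > 76 else "", pdbqt)
    atom = Atom(name, element, (x, y, z), occ, altloc, serial)
    return resname, chain_id, resnum, icode, atom


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    by_name: dict[str, list[Atom]] = {}
    for a in atoms:
        by_name.setdefault(a.name, []).append(a)
    resolved = []
    for group in by_name.values():
        if len(group) == 1:
            resolved.append(group[0])
        else:
            # highest occupancy wins; ties prefer altloc 'A', then blank
            rank = {"A": 0, "": 1}
            group.sort(key=lambda a: (-a.occupancy, rank.get(a.altloc, 2), a.altloc))
            resolved.append(group[0])
    resolved.sort(key=lambda a: a.serial)
    return resolved


def parse_pdb(path: str | Path, dialect: str | None = None) -> Structure:
    """Parse a PDB (or PDBQT) file into a :class:`Structure`.

    The first MODEL only. HETATM records and non-standard residue names go
    to ``het_groups``; standard residues to per-chain polymer lists.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pdbqt = (dialect == "pdbqt") or path.suffix.lower() == ".pdbqt"

    raw: dict[tuple[str, int, str, str, bool], list[Atom]] = {}
    order: list[tuple[str, int, str, str, bool]] = []
    for line in path.read_text().splitlines():
        rec = line[:6].strip()
        if rec == "ENDMDL":
            break  # first model only
        if rec not in ("ATOM", "HETATM"):
            continue
        resname, chain_id, resnum, icode, atom = _parse_atom_line(line, pdbqt)
        key = (chain_id, resnum, icode, resname, rec == "HETATM")
        if key not in raw:
            raw[key] = []
            order.append(key)
        raw[key].append(atom)
    if not raw:
        raise PDBFormatError(f"no ATOM/HETATM records in {path}")

    structure = Structure()
    for key in order:
        chain_id, resnum, icode, resname, is_het = key
        res = Residue(resname, resnum, chain_id, icode, _resolve_altlocs(raw[key]))
        if is_het or resname not in STANDARD_RESIDUES:
            structure.het_groups.append(res)
        else:
            structure.chains.setdefault(chain_id, []).append(res)
    return structure


def write_pdb(path: str | Path, structure: Structure) -> None:
    """Write ATOM/HETATM records; coordinates at 3 decimals."""
    serial = 0
    lines = []
    for res in structure.residues():
        record = "HETATM" if res.name not in STANDARD_RESIDUES else "ATOM  "
        for a in res.atoms:
            serial += 1
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            x, y, z = a.coords
            lines.append(
                f"{record}{serial:5d} {name}{a.altloc or ' '}{res.name:>3s} "
                f"{res.chain_id:1s}{res.number:4d}{res.icode or ' '}   "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}"
            )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def select_atoms(
    structure: Structure,
    chain: str | None = None,
    residue_name: str | None = None,
    atom_name: str | None = None,
    predicate: Callable[[Residue, Atom], bool] | None = None,
) -> list[Atom]:
    """All atoms matching every given criterion, in file order."""
    out = []
    for res in structure.residues():
        if chain is not None and res.chain_id != chain:
            continue
        if residue_name is not None and res.name != residue_name:
            continue
        for a in res.atoms:
            if atom_name is not None and a.name != atom_name:
                continue
            if predicate is not None and not predicate(res, a):
                continue
            out.append(a)
    return out
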