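"""Deterministic fixture generation: sequences with prescribed composition,
ideal-geometry toy structures, and the bundled printed-table fixtures.

Everything here is a pure function of (spec, seed) so tests never need a
download.
"""

from __future__ import annotations

import hashlib
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_seq import CompositionTable, ProteinSequence, read_composition_tsv
from .glycation import DistanceRow
from .structure_io import Atom, Residue, Structure

FIXTURE_DIR = Path(__file__).parent / "data" / "fixtures"

# ideal backbone geometry (bond lengths A, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

HELIX_PHI, HELIX_PSI = -57.0, -47.0
STRAND_PHI, STRAND_PSI = -139.0, 135.0


@dataclass(frozen=True)
class FixtureSpec:
    kind: str  # sequence_from_composition | ideal_helix | lone_strand |
               # lys_acid_pair | two_chain_contact | hbond_complex
    params: dict = field(default_factory=dict)
    seed: int = 0


def random_sequence(comp: CompositionTable, seed: int, seq_id: str = "synthetic"
                    ) -> ProteinSequence:
    """Uniformly random permutation of the residue multiset, seeded."""
    pool = [aa for aa, n in sorted(comp.counts.items()) for _ in range(n)]
    rng = random.Random(seed)
    rng.shuffle(pool)
    return ProteinSequence(seq_id, "".join(pool))


def _place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float):
    """NeRF: position of atom d given three predecessors and internal coords."""
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    angle = math.radians(angle_deg)
    dihedral = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(angle),
        bond * math.sin(angle) * math.cos(dihedral),
        bond * math.sin(angle) * math.sin(dihedral),
    ])
    return tuple(c + d_local[0] * bc + d_local[1] * m + d_local[2] * n)


def _backbone_chain(n_res: int, phi: float, psi: float, chain_id: str = "A",
                    resname: str = "ALA") -> list[Residue]:
    """Ideal poly-residue backbone (N, CA, C, O) at fixed phi/psi, omega=180."""
    coords = []  # flat list of (name, xyz) per residue
    n0 = (0.0, 0.0, 0.0)
    ca0 = (_B_N_CA, 0.0, 0.0)
    ang = math.radians(_A_N_CA_C)
    c0 = (ca0[0] - _B_CA_C * math.cos(ang), _B_CA_C * math.sin(ang), 0.0)
    residues_xyz = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, n_res):
        prev = residues_xyz[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi)
        ca = _place(prev["CA"], prev["C"], n, _B_N_CA, _A_C_N_CA, 180.0)
        c = _place(prev["C"], n, ca, _B_CA_C, _A_N_CA_C, phi)
        residues_xyz.append({"N": n, "CA": ca, "C": c})
    # carbonyl O: dihedral N-CA-C-O = psi + 180
    for xyz in residues_xyz:
        xyz["O"] = _place(xyz["N"], xyz["CA"], xyz["C"], _B_C_O, _A_CA_C_O, psi + 180.0)
    out = []
    serial = 0
    for i, xyz in enumerate(residues_xyz):
        atoms = []
        for name in ("N", "CA", "C", "O"):
            serial += 1
            atoms.append(Atom(name, name[0], xyz[name], serial=serial))
        out.append(Residue(resname, i + 1, chain_id, "", atoms))
    return out


def _single_residue(name: str, number: int, chain_id: str,
                    atoms: list[tuple[str, str, tuple]]) -> Residue:
    return Residue(name, number, chain_id, "",
                   [Atom(n, el, xyz, serial=i + 1) for i, (n, el, xyz) in enumerate(atoms)])


def _lys_acid_pair(params: dict) -> Structure:
    d = float(params.get("d", 5.0))
    if d <= 0:
        raise ValueError("distance must be positive")
    lys = _single_residue("LYS", 1, "A", [
        ("N", "N", (-8.0, 0.0, 0.0)), ("CA", "C", (-6.5, 0.0, 0.0)),
        ("C", "C", (-5.0, 0.0, 0.0)), ("O", "O", (-5.0, 1.2, 0.0)),
        ("NZ", "N", (0.0, 0.0, 0.0)),
    ])
    asp = _single_residue("ASP", 2, "A", [
        ("N", "N", (d + 6.0, 0.0, 0.0)), ("CA", "C", (d + 4.5, 0.0, 0.0)),
        ("C", "C", (d + 3.0, 0.0, 0.0)), ("O", "O", (d + 3.0, 1.2, 0.0)),
        ("OD1", "O", (d, 0.0, 0.0)),
    ])
    residues = [lys, asp]
    if "d_base" in params:
        db = float(params["d_base"])
        if db <= 0:
            raise ValueError("distance must be positive")
        residues.append(_single_residue("HIS", 3, "A", [
            ("N", "N", (0.0, db + 6.0, 0.0)), ("CA", "C", (0.0, db + 4.5, 0.0)),
            ("C", "C", (0.0, db + 3.0, 0.0)), ("O", "O", (1.2, db + 3.0, 0.0)),
            ("NE2", "N", (0.0, db, 0.0)),
        ]))
    return Structure(chains={"A": residues})


def _two_chain_contact(params: dict) -> Structure:
    d = float(params.get("d", 3.5))
    if d <= 0:
        raise ValueError("distance must be positive")

    def gly(chain_id, number, x0):
        return _single_residue("GLY", number, chain_id, [
            ("N", "N", (x0, 0.0, 0.0)), ("CA", "C", (x0 + 1.5, 0.0, 0.0)),
            ("C", "C", (x0 + 3.0, 0.0, 0.0)), ("O", "O", (x0 + 4.2, 0.0, 0.0)),
        ])

    # closest inter-chain pair: O of chain A at x=4.2 vs N of chain B at 4.2+d
    return Structure(chains={"A": [gly("A", 1, 0.0)], "B": [gly("B", 1, 4.2 + d)]})


def _hbond_complex(params: dict) -> Structure:
    d = float(params.get("d", 3.0))
    angle = float(params.get("angle", 180.0))
    explicit_h = bool(params.get("explicit_h", False))
    if d <= 0:
        raise ValueError("distance must be positive")
    atoms = [
        ("N", "N", (-6.0, 0.0, 0.0)), ("CA", "C", (-4.5, 0.0, 0.0)),
        ("C", "C", (-3.0, 0.0, 0.0)), ("O", "O", (-3.0, 1.2, 0.0)),
        ("NH1", "N", (0.0, 0.0, 0.0)),
    ]
    if explicit_h:
        atoms.append(("HH11", "H", _h_for_angle(d, angle)))
    arg = _single_residue("ARG", 1, "A", atoms)
    lig = _single_residue("IHP", 1, "L", [
        ("P1", "P", (d + 1.6, 0.0, 0.0)),
        ("O1", "O", (d, 0.0, 0.0)),
        ("O2", "O", (d + 2.4, 1.2, 0.0)),
    ])
    return Structure(chains={"A": [arg]}, het_groups=[lig])


def _h_for_angle(d: float, theta_deg: float, bond: float = 1.0):
    """H position giving a D-H...A angle of ``theta_deg`` for D at the origin
    and A at (d, 0, 0); solved by bisection on the DH direction."""

    def angle_at_h(alpha):
        h = np.array([bond * math.cos(alpha), bond * math.sin(alpha), 0.0])
        v1 = -h
        v2 = np.array([d, 0.0, 0.0]) - h
        c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    lo, hi = 0.0, math.pi * 0.999  # angle_at_h decreases from 180 deg
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if angle_at_h(mid) > theta_deg:
            lo = mid
        else:
            hi = mid
    alpha = 0.5 * (lo + hi)
    return (bond * math.cos(alpha), bond * math.sin(alpha), 0.0)


def build_toy_structure(spec: FixtureSpec) -> Structure:
    """Construct a toy structure with exact geometric ground truth."""
    p = spec.params
    if spec.kind == "ideal_helix":
        n = int(p.get("n", 20))
        return Structure(chains={"A": _backbone_chain(n, HELIX_PHI, HELIX_PSI)})
    if spec.kind == "lone_strand":
        n = int(p.get("n", 10))
        return Structure(chains={"A": _backbone_chain(n, STRAND_PHI, STRAND_PSI)})
    if spec.kind == "lys_acid_pair":
        return _lys_acid_pair(p)
    if spec.kind == "two_chain_contact":
        return _two_chain_contact(p)
    if spec.kind == "hbond_complex":
        return _hbond_complex(p)
    raise ValueError(f"unknown fixture kind {spec.kind!r}")


@dataclass(frozen=True)
class TableFixtures:
    """Machine-readable transcription of the published tables."""

    compositions: dict[str, CompositionTable]
    glycation_distances: tuple[DistanceRow, ...]
    glycation_external: dict[tuple[str, int], bool]
    determinants: tuple[dict, ...]
    sequons: tuple[dict, ...]
    summary: dict[tuple[str, str], tuple[str, str]]  # (protein, metric) -> (printed, corrected)


def _verify_manifest(data_dir: Path) -> None:
    manifest = data_dir / "MANIFEST.sha256"
    for line in manifest.read_text().splitlines():
        if not line.strip():
            continue
        digest, name = line.split()
        actual = hashlib.sha256((data_dir / name).read_bytes()).hexdigest()
        if actual != digest:
            raise RuntimeError(f"fixture checksum mismatch for {name}")


def _rows(path: Path) -> list[list[str]]:
    out = []
    header = None
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        if header is None:
            header = line.split("\t")
            continue
        out.append(line.split("\t"))
    return out


def table_fixtures(data_dir: str | Path | None = None) -> TableFixtures:
    """Load (and checksum-verify) the bundled printed-table fixtures."""
    data_dir = Path(data_dir) if data_dir is not None else FIXTURE_DIR
    _verify_manifest(data_dir)
    comps = {
        "3K4Q": read_composition_tsv(data_dir / "composition_3k4q.tsv"),
        "1QFX": read_composition_tsv(data_dir / "composition_1qfx.tsv"),
    }
    dist = tuple(
        DistanceRow(r[0], int(r[1]), r[2], r[3] if r[3] != "-" else None,
                    float(r[4]), r[5] == "gt")
        for r in _rows(data_dir / "glycation_distances.tsv")
    )
    external = {
        (r[0], int(r[1])): r[2] == "1"
        for r in _rows(data_dir / "glycation_predictions.tsv")
    }
    determinants = tuple(
        {"protein": r[0], "fragment": int(r[1]), "start": int(r[2]),
         "sequence": r[3], "end": int(r[4]), "length": int(r[5])}
        for r in _rows(data_dir / "antigenic_determinants.tsv")
    )
    sequons = tuple(
        {"protein": r[0], "position": int(r[1]), "context": r[2]}
        for r in _rows(data_dir / "sequons.tsv")
    )
    summary = {(r[0], r[1]): (r[2], r[3]) for r in _rows(data_dir / "summary_values.tsv")}
    return TableFixtures(comps, dist, external, determinants, sequons, summary)
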