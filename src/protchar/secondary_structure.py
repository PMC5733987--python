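"""Simplified Kabsch-Sander secondary-structure assignment (3 states).

Backbone hydrogen bonds are scored with the classic electrostatic model
E = 27.888 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) kcal/mol and accepted at
E < -0.5. Amide hydrogens absent from crystal structures are synthesized
1.01 A from N along the preceding C=O direction. Helices (alpha, with
3-10 and pi folded in by default) come from runs of i->i+k turns; strands
from parallel/antiparallel bridge patterns; everything else is coil.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .structure_io import Structure

log = logging.getLogger(__name__)

COUPLING = 27.888  # q1*q2*332 in kcal*A/mol
HBOND_ENERGY_CUTOFF = -0.5
MIN_SEPARATION = 0.1


@dataclass(frozen=True)
class SSAssignment:
    labels: tuple[str, ...]       # per-residue H/E/C
    residue_numbers: tuple[int, ...]
    pct_helix: float
    pct_sheet: float
    pct_other: float


def _dist(a, b) -> float:
    return math.sqrt(sum((a[i] - b[i]) ** 2 for i in range(3)))


def backbone_hbond_energy(n, h, c, o) -> float:
    """Kabsch-Sander electrostatic H-bond energy in kcal/mol.

    ``n``/``h`` are the donor amide atoms, ``c``/``o`` the acceptor
    carbonyl atoms, each an (x, y, z) triple in Angstrom.
    """
    r_on = _dist(o, n)
    r_ch = _dist(c, h)
    r_oh = _dist(o, h)
    r_cn = _dist(c, n)
    if min(r_on, r_ch, r_oh, r_cn) < MIN_SEPARATION:
        raise ValueError("coincident atoms in hydrogen-bond energy")
    return COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _synth_hydrogen(n, prev_c, prev_o, bond: float = 1.01):
    """Amide H placed ``bond`` A from N along the previous C=O direction."""
    v = tuple(prev_c[i] - prev_o[i] for i in range(3))
    norm = math.sqrt(sum(x * x for x in v))
    return tuple(n[i] + bond * v[i] / norm for i in range(3))


def assign_ss(structure: Structure, chain: str,
              fold_310_pi_into_helix: bool = True) -> SSAssignment:
    """Three-state H/E/C assignment for one chain.

    Residues lacking complete backbone (N, CA, C, O) are labeled C with a
    warning. Percentages are over all polymer residues of the chain.
    """
    residues = structure.chain(chain)
    n_res = len(residues)
    backbone = []
    for res in residues:
        atoms = {name: res.atom(name) for name in ("N", "CA", "C", "O")}
        if any(a is None for a in atoms.values()):
            log.warning("residue %s lacks complete backbone; labeled C", res.id)
            backbone.append(None)
        else:
            backbone.append({k: a.coords for k, a in atoms.items()})

    # amide H per residue: explicit if present, else synthesized from i-1 C=O
    hydrogens: list[tuple | None] = [None] * n_res
    for i, res in enumerate(residues):
        if backbone[i] is None or res.name == "PRO":
            continue
        explicit = res.atom("H") or res.atom("HN")
        if explicit is not None:
            hydrogens[i] = explicit.coords
        elif i > 0 and backbone[i - 1] is not None:
            hydrogens[i] = _synth_hydrogen(
                backbone[i]["N"], backbone[i - 1]["C"], backbone[i - 1]["O"]
            )

    def hbond(donor: int, acceptor: int) -> bool:
        """True if N-H of residue ``donor`` bonds to C=O of ``acceptor``."""
        if donor < 0 or acceptor < 0 or donor >= n_res or acceptor >= n_res:
            return False
        if abs(donor - acceptor) < 2:
            return False
        if backbone[donor] is None or backbone[acceptor] is None:
            return False
        h = hydrogens[donor]
        if h is None:
            return False
        try:
            e = backbone_hbond_energy(
                backbone[donor]["N"], h,
                backbone[acceptor]["C"], backbone[acceptor]["O"],
            )
        except ValueError:
            return False
        return e < HBOND_ENERGY_CUTOFF

    labels = ["C"] * n_res

    # bridges -> E (checked first; helix overrides E per DSSP precedence)
    for i in range(1, n_res - 1):
        for j in range(i + 3, n_res - 1):
            parallel = (hbond(j, i - 1) and hbond(i + 1, j)) or (
                hbond(i, j - 1) and hbond(j + 1, i))
            anti = (hbond(i, j) and hbond(j, i)) or (
                hbond(j + 1, i - 1) and hbond(i + 1, j - 1))
            if parallel or anti:
                labels[i] = "E"
                labels[j] = "E"

    # k-turns -> helix runs; two consecutive turns at i-1, i mark i..i+k-1
    turn_ks = (4, 3, 5) if fold_310_pi_into_helix else (4,)
    for k in turn_ks:
        turns = [hbond(i + k, i) for i in range(n_res)]
        for i in range(1, n_res):
            if turns[i - 1] and turns[i]:
                for j in range(i, min(i + k, n_res)):
                    labels[j] = "H"

    for i in range(n_res):  # incomplete backbone is always coil
        if backbone[i] is None:
            labels[i] = "C"

    assigned = n_res if n_res else 1
    n_h = labels.count("H")
    n_e = labels.count("E")
    return SSAssignment(
        labels=tuple(labels),
        residue_numbers=tuple(r.number for r in residues),
        pct_helix=100.0 * n_h / assigned,
        pct_sheet=100.0 * n_e / assigned,
        pct_other=100.0 * (assigned - n_h - n_e) / assigned,
    )
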