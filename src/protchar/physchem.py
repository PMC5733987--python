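"""Whole-protein physicochemical properties computed from composition or sequence.

Composition-sufficient quantities (molecular weight, pI, charge tallies,
GRAVY, aliphatic index) take a :class:`~protchar.core_seq.CompositionTable`;
the instability index needs dipeptides and therefore a sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core_seq import AMINO_ACIDS, CompositionTable, ProteinSequence, composition
from .param_tables import ParameterTables

_ACIDIC = "DECY"   # side chains deprotonating in the Bjellqvist model
_BASIC = "HKR"

INSTABILITY_THRESHOLD = 40.0


@dataclass(frozen=True)
class PhysChemReport:
    mw_kda: float
    pi: float
    neg_count: int
    neg_pct: float
    pos_count: int
    pos_pct: float
    gravy: float
    aliphatic_index: float
    instability_index: float | None
    stability_label: str | None
    half_life: tuple[str, str, str]
    nterm_residue: str
    length: int


def molecular_weight(comp: CompositionTable, tables: ParameterTables) -> float:
    """Average molecular weight in kDa: sum of residue masses plus one water."""
    da = sum(n * tables.residue_mass[aa] for aa, n in comp.counts.items())
    return (da + tables.water_mass) / 1000.0


def net_charge(comp: CompositionTable, nterm_residue: str, pH: float,
               tables: ParameterTables) -> float:
    """Henderson-Hasselbalch net charge at ``pH`` (one N- and one C-terminus)."""
    if nterm_residue not in AMINO_ACIDS:
        raise ValueError(f"unknown N-terminal residue {nterm_residue!r}")
    q = 1.0 / (1.0 + 10.0 ** (pH - tables.nterm_pka(nterm_residue)))
    for aa in _BASIC:
        q += comp.count(aa) / (1.0 + 10.0 ** (pH - tables.pka[f"side_{aa}"]))
    q -= 1.0 / (1.0 + 10.0 ** (tables.pka["Cterm"] - pH))
    for aa in _ACIDIC:
        q -= comp.count(aa) / (1.0 + 10.0 ** (tables.pka[f"side_{aa}"] - pH))
    return q


def isoelectric_point(comp: CompositionTable, nterm_residue: str,
                      tables: ParameterTables, tol: float = 1e-4) -> float:
    """pH where the net charge vanishes, by bisection on [0, 14].

    ``net_charge`` is strictly decreasing in pH, so the zero is unique.
    """
    if comp.length == 0:
        raise ValueError("isoelectric point undefined for an empty composition")
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-10:
        mid = 0.5 * (lo + hi)
        if net_charge(comp, nterm_residue, mid, tables) > 0:
            lo = mid
        else:
            hi = mid
    pi = 0.5 * (lo + hi)
    if abs(net_charge(comp, nterm_residue, pi, tables)) > tol:
        raise RuntimeError("net charge does not vanish on [0, 14]")
    return pi


def charged_counts(comp: CompositionTable) -> tuple[int, float, int, float]:
    """(neg_count, neg_pct, pos_count, pos_pct); neg = D+E, pos = R+K.

    Histidine is deliberately excluded from the positive tally.
    """
    if comp.length == 0:
        raise ValueError("charged_counts undefined for an empty composition")
    neg = comp.count("D") + comp.count("E")
    pos = comp.count("R") + comp.count("K")
    L = comp.length
    return neg, 100.0 * neg / L, pos, 100.0 * pos / L


def gravy(comp: CompositionTable, tables: ParameterTables) -> float:
    """Grand average of hydropathy: composition-weighted Kyte-Doolittle mean."""
    if comp.length == 0:
        raise ValueError("GRAVY undefined for an empty composition")
    return sum(n * tables.kd_scale[aa] for aa, n in comp.counts.items()) / comp.length


def aliphatic_index(comp: CompositionTable, tables: ParameterTables) -> float:
    """X(Ala) + a*X(Val) + b*(X(Ile)+X(Leu)), X in mole percent."""
    if comp.length == 0:
        raise ValueError("aliphatic index undefined for an empty composition")
    a, b = tables.aliphatic_coeffs
    L = comp.length
    x = lambda aa: 100.0 * comp.count(aa) / L
    return x("A") + a * x("V") + b * (x("I") + x("L"))


def instability_index(seq: ProteinSequence, tables: ParameterTables) -> tuple[float, str]:
    """Guruprasad dipeptide statistic: (10/L) * sum of DIWV over L-1 dipeptides."""
    L = len(seq)
    if L < 2:
        raise ValueError("instability index needs at least 2 residues")
    s = seq.residues
    total = sum(tables.diwv[s[i]][s[i + 1]] for i in range(L - 1))
    ii = 10.0 / L * total
    return ii, ("unstable" if ii > INSTABILITY_THRESHOLD else "stable")


def estimated_half_life(nterm_residue: str, tables: ParameterTables) -> tuple[str, str, str]:
    """N-end-rule half-life lookup (mammalian in vitro, yeast, E. coli)."""
    try:
        return tables.nend_rule[nterm_residue]
    except KeyError:
        raise ValueError(f"unknown N-terminal residue {nterm_residue!r}") from None


def build_report(comp: CompositionTable, nterm_residue: str, tables: ParameterTables,
                 seq: ProteinSequence | None = None) -> PhysChemReport:
    """Assemble the full physicochemical report for one protein.

    ``seq`` is optional; without it the instability index is absent.
    """
    neg, neg_pct, pos, pos_pct = charged_counts(comp)
    ii = label = None
    if seq is not None:
        if composition(seq) != comp:
            raise ValueError("sequence does not match the supplied composition")
        ii, label = instability_index(seq, tables)
    pi = isoelectric_point(comp, nterm_residue, tables)
    report = PhysChemReport(
        mw_kda=molecular_weight(comp, tables),
        pi=pi,
        neg_count=neg, neg_pct=neg_pct, pos_count=pos, pos_pct=pos_pct,
        gravy=gravy(comp, tables),
        aliphatic_index=aliphatic_index(comp, tables),
        instability_index=ii, stability_label=label,
        half_life=estimated_half_life(nterm_residue, tables),
        nterm_residue=nterm_residue,
        length=comp.length,
    )
    if not 0.0 < report.pi < 14.0 or not math.isfinite(report.pi):
        raise RuntimeError("isoelectric point out of range")
    return report


def truncate(value: float, decimals: int) -> float:
    """Truncate toward zero at ``decimals`` places (printed-table convention)."""
    factor = 10 ** decimals
    return math.trunc(value * factor) / factor
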