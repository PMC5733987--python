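"""Structure-based lysine glycation analysis.

For every lysine NZ in a chain, the minimum Euclidean distance to the
acidic side-chain oxygens (Asp OD1/OD2, Glu OE1/OE2) and to the basic
side-chain nitrogens (His ND1/NE2, Arg NE/NH1/NH2, other Lys NZ) is
measured; a lysine is called glycable when the overall minimum is
strictly below the cutoff (default 10 A). Calls can be compared against
an external per-lysine prediction list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .structure_io import Residue, Structure

log = logging.getLogger(__name__)

ACID_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASE_ATOMS = {"HIS": ("ND1", "NE2"), "ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}

DEFAULT_CUTOFF = 10.0


@dataclass(frozen=True)
class LysineEnvironment:
    lysine: str                               # residue id, e.g. "LYS119"
    chain: str
    nearest_acid: tuple[str, float] | None    # (residue id, distance A)
    nearest_base: tuple[str, float] | None

    @property
    def min_distance(self) -> float | None:
        ds = [d for _, d in filter(None, (self.nearest_acid, self.nearest_base))]
        return min(ds) if ds else None


@dataclass(frozen=True)
class GlycationCall:
    lysine: str
    glycable: bool
    supporting_distance: float | None
    method: str  # "distance" | "external"


@dataclass(frozen=True)
class DistanceRow:
    """One printed lysine-partner distance; ``lower_bound`` marks rows that
    state only that no partner lies within the given distance."""

    protein: str
    lysine: int
    partner_kind: str            # "acid" | "base"
    partner: str | None
    distance: float
    lower_bound: bool = False


@dataclass(frozen=True)
class AgreementStats:
    n_a: int           # distance-method positives
    n_b: int           # external-method positives
    n_overlap: int
    fraction_b_of_a: float       # % of distance calls confirmed externally
    fraction_a_with_support: float  # % of external calls with distance support


def _candidate_atoms(residues: list[Residue], table: dict[str, tuple[str, ...]],
                     exclude: Residue | None = None):
    for res in residues:
        if res is exclude:
            continue
        names = table.get(res.name)
        if not names:
            continue
        for name in names:
            atom = res.atom(name)
            if atom is not None:
                yield res, atom


def lysine_environment(structure: Structure, chain: str,
                       include_interchain: bool = False) -> list[LysineEnvironment]:
    """Per-lysine nearest acidic and basic side-chain distances.

    The basic-residue search excludes the lysine's own atoms. By default
    only residues of ``chain`` are candidates; ``include_interchain``
    widens the search to all chains.
    """
    residues = structure.chain(chain)
    candidates = (
        [r for ch in structure.chains.values() for r in ch]
        if include_interchain else residues
    )
    envs = []
    for res in residues:
        if res.name != "LYS":
            continue
        nz = res.atom("NZ")
        if nz is None:
            log.warning("LYS %s%d lacks an NZ atom; skipped", res.chain_id, res.number)
            continue
        best = {}
        for kind, table in (("acid", ACID_ATOMS), ("base", BASE_ATOMS)):
            nearest = None
            for other, atom in _candidate_atoms(candidates, table, exclude=res):
                d = nz.distance(atom)
                if nearest is None or d < nearest[1]:
                    nearest = (other.id, d)
            best[kind] = nearest
        envs.append(LysineEnvironment(res.id, chain, best["acid"], best["base"]))
    return envs


def classify_glycation(envs: list[LysineEnvironment],
                       cutoff: float = DEFAULT_CUTOFF) -> list[GlycationCall]:
    """Glycable iff the strict minimum distance is < ``cutoff``."""
    calls = []
    for env in envs:
        d = env.min_distance
        calls.append(GlycationCall(env.lysine, d is not None and d < cutoff, d, "distance"))
    return calls


def environments_from_distance_table(rows: list[DistanceRow] | tuple[DistanceRow, ...],
                                     protein: str) -> list[LysineEnvironment]:
    """Build per-lysine environments from a transcribed distance table.

    For each lysine, the minimum printed distance per partner class is
    taken; lower-bound rows propagate as (bound, no partner) so that the
    strict cutoff rule still classifies them correctly.
    """
    by_lysine: dict[int, dict[str, tuple[str | None, float]]] = {}
    for row in rows:
        if row.protein != protein:
            continue
        slot = by_lysine.setdefault(row.lysine, {})
        current = slot.get(row.partner_kind)
        if current is None or row.distance < current[1]:
            slot[row.partner_kind] = (None if row.lower_bound else row.partner,
                                      row.distance)
    envs = []
    for lysine in sorted(by_lysine):
        slot = by_lysine[lysine]
        acid = slot.get("acid")
        base = slot.get("base")
        envs.append(LysineEnvironment(
            f"LYS{lysine}", "A",
            (acid[0] or "-", acid[1]) if acid else None,
            (base[0] or "-", base[1]) if base else None,
        ))
    return envs


def compare_predictions(calls_distance: list[GlycationCall],
                        calls_external: list[GlycationCall]) -> AgreementStats:
    """Overlap statistics between the two call sets (same lysine universe)."""
    uni_a = {c.lysine for c in calls_distance}
    uni_b = {c.lysine for c in calls_external}
    if uni_a != uni_b:
        raise ValueError(
            f"mismatched lysine universes: {sorted(uni_a ^ uni_b)} not shared"
        )
    pos_a = {c.lysine for c in calls_distance if c.glycable}
    pos_b = {c.lysine for c in calls_external if c.glycable}
    overlap = pos_a & pos_b
    return AgreementStats(
        n_a=len(pos_a),
        n_b=len(pos_b),
        n_overlap=len(overlap),
        fraction_b_of_a=100.0 * len(overlap) / len(pos_a) if pos_a else 0.0,
        fraction_a_with_support=100.0 * len(overlap) / len(pos_b) if pos_b else 0.0,
    )


def read_external_calls(path: str | Path) -> list[GlycationCall]:
    """Load a 2-column TSV (lysine id, predicted 0/1) of external calls."""
    calls = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.lower().startswith("lysine\t"):
            continue
        lysine, flag = line.split("\t")[:2]
        calls.append(GlycationCall(lysine, flag in ("1", "true", "X"), None, "external"))
    return calls
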