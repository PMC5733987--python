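"""Sequence motif scanners: N-glycosylation sequons and the histidine
acid phosphatase catalytic motif."""

from __future__ import annotations

from dataclasses import dataclass

from .core_seq import ProteinSequence


@dataclass(frozen=True)
class SequonHit:
    """One Asn-Xaa-Ser/Thr acceptor site (Xaa != Pro)."""

    position: int   # Asn position in reported numbering
    context: str    # 4-residue window starting at the Asn


@dataclass(frozen=True)
class MotifHit:
    """One RHGXRXP match, with the nearest downstream HD dyad if present."""

    start: int
    hd_position: int | None


def find_sequons(seq: ProteinSequence) -> list[SequonHit]:
    """All overlapping N-X-S/T sites with X != P, in ascending position."""
    s = seq.residues
    hits = []
    for i in range(len(s) - 2):
        if s[i] == "N" and s[i + 1] != "P" and s[i + 2] in "ST":
            hits.append(SequonHit(seq.position(i), s[i : i + 4]))
    return hits


def find_catalytic_motif(seq: ProteinSequence) -> list[MotifHit]:
    """All RHGXRXP matches; X is any standard residue."""
    s = seq.residues
    hits = []
    for i in range(len(s) - 6):
        if (s[i] == "R" and s[i + 1] == "H" and s[i + 2] == "G"
                and s[i + 4] == "R" and s[i + 6] == "P"):
            hd = None
            for j in range(i + 7, len(s) - 1):
                if s[j] == "H" and s[j + 1] == "D":
                    hd = seq.position(j)
                    break
            hits.append(MotifHit(seq.position(i), hd))
    return hits
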