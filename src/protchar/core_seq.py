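"""Protein sequence and composition data model, plus FASTA I/O.

Sequences are plain one-letter strings over the 20 standard amino acids.
A ``numbering_offset`` records the reported number of the first residue so
that positions printed by downstream analyses can follow mature-chain or
author numbering.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: optional mapping for the rare 21st/22nd residues when not rejecting them
NONSTANDARD_MAP = {"U": "C", "O": "K"}


class SequenceError(ValueError):
    """Raised for sequences containing non-standard residue letters."""


@dataclass(frozen=True)
class ProteinSequence:
    """A validated one-letter protein sequence.

    Parameters
    ----------
    id : str
        Free-text record identifier.
    residues : str
        Residue string over ``ACDEFGHIKLMNPQRSTVWY``.
    numbering_offset : int
        Reported number of the first residue (default 1).
    """

    id: str
    residues: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        for i, ch in enumerate(self.residues):
            if ch not in _AA_SET:
                raise SequenceError(
                    f"record {self.id!r}: illegal residue {ch!r} at "
                    f"position {i + self.numbering_offset}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def position(self, index: int) -> int:
        """Reported residue number for 0-based string index."""
        return index + self.numbering_offset

    def index(self, position: int) -> int:
        """0-based string index for a reported residue number."""
        return position - self.numbering_offset


@dataclass(frozen=True)
class CompositionTable:
    """Residue counts standing in for a sequence in composition-only math."""

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for aa, n in self.counts.items():
            if aa not in _AA_SET:
                raise SequenceError(f"illegal residue letter {aa!r} in composition")
            if n < 0 or int(n) != n:
                raise ValueError(f"negative or non-integer count for {aa!r}: {n}")
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def length(self) -> int:
        return sum(self.counts.values())

    def count(self, residue: str) -> int:
        return self.counts.get(residue, 0)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CompositionTable):
            return NotImplemented
        return {k: v for k, v in self.counts.items() if v} == {
            k: v for k, v in other.counts.items() if v
        }

    def __hash__(self):
        return hash(tuple(sorted((k, v) for k, v in self.counts.items() if v)))


def composition(seq: ProteinSequence) -> CompositionTable:
    """Tally every residue of ``seq`` exactly once."""
    return CompositionTable(Counter(seq.residues))


def mole_percent(comp: CompositionTable, residue: str) -> float:
    """Mole percent of ``residue``: 100 * count / length."""
    if comp.length == 0:
        raise ValueError("mole_percent undefined for an empty composition")
    return 100.0 * comp.count(residue) / comp.length


def read_fasta(
    path: str | Path,
    on_nonstandard: str = "reject",
    numbering_offset: int = 1,
) -> list[ProteinSequence]:
    """Read a FASTA file into :class:`ProteinSequence` records.

    ``on_nonstandard`` is ``"reject"`` (default: any letter outside the 20
    standard codes raises) or ``"map"`` (U->C, O->K; anything else still
    raises).
    """
    if on_nonstandard not in ("reject", "map"):
        raise ValueError(f"unknown on_nonstandard mode {on_nonstandard!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    from Bio import SeqIO

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if on_nonstandard == "map":
            residues = "".join(NONSTANDARD_MAP.get(c, c) for c in residues)
        records.append(ProteinSequence(rec.id, residues, numbering_offset))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(path: str | Path, seqs: Iterable[ProteinSequence], width: int = 60) -> None:
    """Write sequences as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for seq in seqs:
            fh.write(f">{seq.id}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


def read_composition_tsv(path: str | Path) -> CompositionTable:
    """Load a TSV with columns ``residue``, ``count`` (``#`` comments allowed)."""
    counts: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("residue\t"):
                continue
            aa, n = line.split("\t")[:2]
            counts[aa] = counts.get(aa, 0) + int(n)
    return CompositionTable(counts)
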