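"""Kolaskar-Tongaonkar antigenic propensity profile and determinant extraction.

The per-residue propensity is averaged over 7-residue windows and assigned
to window centers. When the whole-protein mean exceeds 1.0, centers with
values strictly above 1.0 are potentially antigenic; otherwise the protein
mean itself is the threshold. Maximal runs of antigenic centers of at least
``min_len`` residues are reported as determinants.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core_seq import ProteinSequence
from .param_tables import ParameterTables
from .profiles import sliding_profile

WINDOW = 7


@dataclass(frozen=True)
class PropensityProfile:
    window: int
    positions: tuple[int, ...]
    values: tuple[float, ...]
    protein_mean: float
    sequence: str = ""
    numbering_offset: int = 1


@dataclass(frozen=True)
class AntigenicDeterminant:
    start: int
    end: int
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def kolaskar_profile(seq: ProteinSequence, tables: ParameterTables) -> PropensityProfile:
    """Window-7 mean antigenic propensity per center, plus the protein mean."""
    if len(seq) < WINDOW:
        raise ValueError(f"sequence shorter than window {WINDOW}")
    p = sliding_profile(seq, "kt", tables, window=WINDOW)
    mean = sum(p.values) / len(p.values)
    return PropensityProfile(
        window=WINDOW, positions=p.positions, values=p.values,
        protein_mean=mean, sequence=seq.residues,
        numbering_offset=seq.numbering_offset,
    )


def antigenic_determinants(profile: PropensityProfile, min_len: int = 8
                           ) -> list[AntigenicDeterminant]:
    """Maximal runs of consecutive centers with propensity strictly above the
    threshold (1.0 if the protein mean is >= 1.0, else the protein mean),
    of length >= ``min_len``."""
    threshold = 1.0 if profile.protein_mean >= 1.0 else profile.protein_mean
    determinants = []
    run_start = None
    positions = profile.positions
    for i, v in enumerate(profile.values):
        above = v - threshold > 1e-9  # strict exceedance, guarded against float ties
        if above and run_start is None:
            run_start = i
        if (not above or i == len(profile.values) - 1) and run_start is not None:
            run_end = i if above else i - 1
            start, end = positions[run_start], positions[run_end]
            if end - start + 1 >= min_len:
                frag = ""
                if profile.sequence:
                    off = profile.numbering_offset
                    frag = profile.sequence[start - off : end - off + 1]
                determinants.append(AntigenicDeterminant(start, end, frag))
            run_start = None
    return determinants
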