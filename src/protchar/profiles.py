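"""Sliding-window per-residue profiles and extrema reporting.

Window means are assigned to the window's central residue; the first and
last (window-1)/2 residues carry no value (no edge padding).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core_seq import ProteinSequence
from .param_tables import ParameterTables


@dataclass(frozen=True)
class Profile:
    scale_name: str
    window: int
    positions: tuple[int, ...]   # reported numbering of window centers
    values: tuple[float, ...]
    residues: tuple[str, ...] = ()


@dataclass(frozen=True)
class Extremum:
    position: int
    residue: str
    value: float


def sliding_profile(seq: ProteinSequence, scale: str | Mapping[str, float],
                    tables: ParameterTables | None = None, window: int = 9) -> Profile:
    """Mean of a per-residue scale over every full ``window``-length stretch."""
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    L = len(seq)
    if window > L:
        raise ValueError(f"window {window} exceeds sequence length {L}")
    if isinstance(scale, str):
        if tables is None:
            raise ValueError("tables required when scale is given by name")
        name, values_map = scale, tables.scale(scale)
    else:
        name, values_map = "custom", scale
    x = np.array([values_map[aa] for aa in seq.residues], dtype=float)
    kernel = np.ones(window) / window
    means = np.convolve(x, kernel, mode="valid")
    half = (window - 1) // 2
    centers = range(half, L - half)
    return Profile(
        scale_name=name,
        window=window,
        positions=tuple(seq.position(i) for i in centers),
        values=tuple(float(v) for v in means),
        residues=tuple(seq.residues[i] for i in centers),
    )


def _ranked(profile: Profile, reverse: bool, k: int) -> list[Extremum]:
    order = sorted(
        range(len(profile.values)),
        key=lambda i: ((-profile.values[i]) if reverse else profile.values[i],
                       profile.positions[i]),
    )
    res = profile.residues or ("?",) * len(profile.values)
    return [Extremum(profile.positions[i], res[i], profile.values[i]) for i in order[:k]]


def profile_extrema(profile: Profile, k: int = 3
                    ) -> tuple[Extremum, Extremum, dict[str, list[Extremum]]]:
    """Global minimum and maximum plus the top/bottom ``k`` ranked values.

    Ties are broken by the lowest position; tied extrema all appear in the
    ranked lists.
    """
    if not profile.values:
        raise ValueError("empty profile")
    bottom = _ranked(profile, reverse=False, k=k)
    top = _ranked(profile, reverse=True, k=k)
    return bottom[0], top[0], {"min": bottom, "max": top}
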