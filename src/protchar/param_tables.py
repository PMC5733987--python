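"""Authoritative store for every numeric constant used by the calculators.

All tables ship as plain TSV files under ``data/params`` together with a
MANIFEST of SHA-256 checksums that is verified at load time. Downstream
code always receives the loaded :class:`ParameterTables` explicitly; there
are no hidden module-level tables.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

from .core_seq import AMINO_ACIDS

DEFAULT_DATA_DIR = Path(__file__).parent / "data" / "params"


class TableError(RuntimeError):
    """Missing, tampered, or incomplete parameter table."""


@dataclass(frozen=True)
class ParameterTables:
    """Immutable bundle of vendored constant tables."""

    residue_mass: Mapping[str, float]
    water_mass: float
    pka: Mapping[str, float]
    kd_scale: Mapping[str, float]
    accessibility_scale: Mapping[str, float]
    accessibility_scale_name: str
    diwv: Mapping[str, Mapping[str, float]]
    kt_propensity: Mapping[str, float]
    nend_rule: Mapping[str, tuple[str, str, str]]
    aliphatic_coeffs: tuple[float, float] = (2.9, 3.9)
    extra_scales: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def scale(self, name: str) -> Mapping[str, float]:
        """Look up a per-residue scale by name."""
        known = {
            "kd": self.kd_scale,
            "kyte_doolittle": self.kd_scale,
            "accessibility": self.accessibility_scale,
            "kt": self.kt_propensity,
            **dict(self.extra_scales),
        }
        try:
            return known[name]
        except KeyError:
            raise KeyError(f"unknown scale {name!r}; have {sorted(known)}") from None

    def nterm_pka(self, residue: str) -> float:
        return self.pka.get(f"Nterm_{residue}", self.pka["Nterm_default"])


def _read_tsv(path: Path) -> list[list[str]]:
    if not path.exists():
        raise TableError(f"missing parameter table {path.name}")
    rows = []
    for line in path.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows[1:]  # drop header


def _check_manifest(data_dir: Path) -> None:
    manifest = data_dir / "MANIFEST.sha256"
    if not manifest.exists():
        raise TableError(f"missing MANIFEST.sha256 in {data_dir}")
    for line in manifest.read_text().splitlines():
        if not line.strip():
            continue
        digest, name = line.split()
        p = data_dir / name
        if not p.exists():
            raise TableError(f"missing parameter table {name}")
        actual = hashlib.sha256(p.read_bytes()).hexdigest()
        if actual != digest:
            raise TableError(f"checksum mismatch for {name}")


def _require_full_alphabet(table: Mapping[str, float], name: str) -> None:
    missing = sorted(set(AMINO_ACIDS) - set(table))
    if missing:
        raise TableError(f"table {name} is missing residues {missing}")


def load_tables(data_dir: str | Path | None = None) -> ParameterTables:
    """Load and checksum-verify all constant tables.

    Raises :class:`TableError` on a missing file, checksum mismatch, or
    incomplete alphabet coverage.
    """
    data_dir = Path(data_dir) if data_dir is not None else DEFAULT_DATA_DIR
    _check_manifest(data_dir)

    mass_rows = _read_tsv(data_dir / "residue_mass.tsv")
    residue_mass = {r[0]: float(r[1]) for r in mass_rows if r[0] != "water"}
    water = {r[0]: float(r[1]) for r in mass_rows if r[0] == "water"}
    if "water" not in water:
        raise TableError("residue_mass.tsv lacks the water row")

    pka = {r[0]: float(r[1]) for r in _read_tsv(data_dir / "pka.tsv")}
    for key in ("Cterm", "Nterm_default", "side_D", "side_E", "side_C",
                "side_Y", "side_H", "side_K", "side_R"):
        if key not in pka:
            raise TableError(f"pka.tsv lacks group {key}")

    kd = {r[0]: float(r[1]) for r in _read_tsv(data_dir / "kd_scale.tsv")}
    acc = {r[0]: float(r[1]) for r in _read_tsv(data_dir / "accessibility_janin.tsv")}
    kt = {r[0]: float(r[1]) for r in _read_tsv(data_dir / "kt_propensity.tsv")}

    diwv: dict[str, dict[str, float]] = {a: {} for a in AMINO_ACIDS}
    for a, b, w in _read_tsv(data_dir / "diwv.tsv"):
        diwv[a][b] = float(w)
    n_pairs = sum(len(v) for v in diwv.values())
    if n_pairs != 400:
        raise TableError(f"diwv.tsv covers {n_pairs} of 400 ordered pairs")

    nend = {r[0]: (r[1], r[2], r[3]) for r in _read_tsv(data_dir / "nend_rule.tsv")}
    coeffs = {r[0]: float(r[1]) for r in _read_tsv(data_dir / "aliphatic_coeffs.tsv")}

    for table, name in ((residue_mass, "residue_mass"), (kd, "kd_scale"),
                        (acc, "accessibility"), (kt, "kt_propensity"),
                        (nend, "nend_rule")):
        _require_full_alphabet(table, name)
    if min(kd.values()) != -4.5 or max(kd.values()) != 4.5:
        raise TableError("kd_scale span is not [-4.5, 4.5]")

    freeze = MappingProxyType
    return ParameterTables(
        residue_mass=freeze(residue_mass),
        water_mass=water["water"],
        pka=freeze(pka),
        kd_scale=freeze(kd),
        accessibility_scale=freeze(acc),
        accessibility_scale_name="janin_pct_accessible",
        diwv=freeze({a: freeze(d) for a, d in diwv.items()}),
        kt_propensity=freeze(kt),
        nend_rule=freeze(nend),
        aliphatic_coeffs=(coeffs["val_coeff"], coeffs["ile_leu_coeff"]),
    )
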