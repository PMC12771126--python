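"""Core container types and on-disk formats.

A conformer ensemble lives on disk as three plain-text files tied together
by a small JSON manifest:

* a multi-frame XYZ file (count line, comment line, ``N`` atom lines per
  frame; the comment line carries ``analog_id conformer_id``),
* a comma-delimited electronic-energy table (one row per conformer, one
  column per basis-set level, energies in hartree; empty cells mean the
  level was not computed for that conformer),
* a long-format harmonic-frequency table (``conformer_id,frequency_cm1``,
  unscaled wavenumbers).

Readers never reorder conformers relative to file order, and a write/read
round trip reproduces the content exactly at the printed precision.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .constants import LEVEL_VOCABULARY, PERIODIC_TABLE


class ParseError(ValueError):
    """A file did not conform to the expected on-disk format."""


@dataclass
class Conformer:
    """One molecular structure: element symbols plus Cartesian coordinates (Å)."""

    conformer_id: str
    analog_id: str
    elements: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), Å
    charge: int = 0
    comment: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.elements) != len(self.coords):
            raise ValueError(
                f"{len(self.elements)} element symbols but {len(self.coords)} coordinates"
            )
        if len(self.elements) == 0:
            raise ValueError("a conformer needs at least one atom")
        for sym in self.elements:
            if sym not in PERIODIC_TABLE:
                raise ValueError(f"invalid element symbol {sym!r}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class EnergyRecord:
    """Electronic energies of one conformer keyed by basis-set level (hartree)."""

    conformer_id: str
    energies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for level, value in self.energies.items():
            if level not in LEVEL_VOCABULARY:
                raise ValueError(f"unknown energy level label {level!r}")
            if not math.isfinite(value):
                raise ValueError(
                    f"non-finite energy at level {level!r} for {self.conformer_id!r}"
                )

    def __getitem__(self, level: str) -> float:
        try:
            return self.energies[level]
        except KeyError:
            raise KeyError(
                f"conformer {self.conformer_id!r} has no energy at level {level!r}"
            ) from None

    def __contains__(self, level: str) -> bool:
        return level in self.energies


@dataclass
class FrequencySet:
    """Unscaled harmonic wavenumbers (cm⁻¹) of one conformer, sorted ascending.

    Negative entries mark imaginary modes; they are preserved on input
    (``has_imaginary``) and rejected by thermochemistry, never dropped
    silently.
    """

    conformer_id: str
    frequencies: np.ndarray
    linear_flag: bool = False

    def __post_init__(self) -> None:
        freqs = np.sort(np.asarray(self.frequencies, dtype=float))
        if freqs.size == 0:
            raise ValueError(f"empty frequency list for conformer {self.conformer_id!r}")
        if not np.all(np.isfinite(freqs)):
            raise ValueError(f"non-finite frequency for conformer {self.conformer_id!r}")
        self.frequencies = freqs

    @property
    def has_imaginary(self) -> bool:
        return bool(self.frequencies[0] <= 0.0)

    def expected_count(self, n_atoms: int) -> int:
        return 3 * n_atoms - 5 if self.linear_flag else 3 * n_atoms - 6


# ---------------------------------------------------------------------------
# multi-frame XYZ
# ---------------------------------------------------------------------------


def read_xyz_ensemble(path: str | Path, analog_id: str | None = None,
                      charge: int = 0) -> list[Conformer]:
    """Read a standard multi-frame XYZ file into a list of conformers.

    The comment line is retained verbatim; when it has the form
    ``"<analog_id> <conformer_id>"`` those identifiers are used, otherwise
    ids default to the frame index. File order is preserved.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    conformers: list[Conformer] = []
    pos = 0
    frame = 0
    while pos < len(lines):
        if not lines[pos].strip():  # tolerate trailing blank lines
            pos += 1
            continue
        try:
            n_atoms = int(lines[pos].strip())
        except ValueError:
            raise ParseError(
                f"{path}: frame {frame}: malformed atom-count line {lines[pos]!r}"
            ) from None
        if n_atoms <= 0:
            raise ParseError(f"{path}: frame {frame}: non-positive atom count {n_atoms}")
        if pos + 1 + n_atoms >= len(lines) + 1 and pos + 1 + n_atoms > len(lines):
            raise ParseError(
                f"{path}: frame {frame}: count line says {n_atoms} atoms but file ends early"
            )
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        elements: list[str] = []
        coords: list[list[float]] = []
        for i in range(n_atoms):
            idx = pos + 2 + i
            if idx >= len(lines):
                raise ParseError(
                    f"{path}: frame {frame}: expected {n_atoms} atom lines, got {i}"
                )
            parts = lines[idx].split()
            if len(parts) < 4:
                raise ParseError(
                    f"{path}: frame {frame}: atom line {i} has "
                    f"{len(parts)} fields, expected 4"
                )
            sym = parts[0]
            if sym not in PERIODIC_TABLE:
                raise ParseError(
                    f"{path}: frame {frame}: invalid element symbol {sym!r} on atom line {i}"
                )
            try:
                xyz = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise ParseError(
                    f"{path}: frame {frame}: unparseable coordinate on atom line {i}: "
                    f"{lines[idx]!r}"
                ) from None
            elements.append(sym)
            coords.append(xyz)
        fields = comment.split()
        if len(fields) >= 2:
            aid, cid = fields[0], fields[1]
        else:
            aid = analog_id or "unknown"
            cid = str(frame)
        conformers.append(
            Conformer(
                conformer_id=cid,
                analog_id=analog_id or aid,
                elements=tuple(elements),
                coords=np.array(coords),
                charge=charge,
                comment=comment,
            )
        )
        pos += 2 + n_atoms
        frame += 1
    return conformers


def write_xyz_ensemble(conformers: Iterable[Conformer], path: str | Path) -> None:
    """Write conformers as multi-frame XYZ; comment line is ``analog_id conformer_id``."""
    path = Path(path)
    chunks = []
    for c in conformers:
        body = "\n".join(
            f"{sym:<3s} {x: .8f} {y: .8f} {z: .8f}"
            for sym, (x, y, z) in zip(c.elements, c.coords)
        )
        chunks.append(f"{c.n_atoms}\n{c.analog_id} {c.conformer_id}\n{body}")
    path.write_text("\n".join(chunks) + "\n")


# ---------------------------------------------------------------------------
# energy tables
# ---------------------------------------------------------------------------


def read_energy_table(path: str | Path) -> list[EnergyRecord]:
    """Read a CSV with a ``conformer_id`` column and one column per level.

    Missing cells become absent levels, never zeros. Duplicate conformer
    ids and non-numeric energies are errors.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"conformer_id": str})
    if "conformer_id" not in df.columns:
        raise ParseError(f"{path}: missing required column 'conformer_id'")
    dupes = df["conformer_id"][df["conformer_id"].duplicated()].tolist()
    if dupes:
        raise ParseError(f"{path}: duplicate conformer_id values: {sorted(set(dupes))}")
    level_cols = [col for col in df.columns if col != "conformer_id"]
    for col in level_cols:
        if col not in LEVEL_VOCABULARY:
            raise ParseError(f"{path}: unknown energy level column {col!r}")
    records = []
    for row_idx, row in df.iterrows():
        energies = {}
        for col in level_cols:
            cell = row[col]
            if pd.isna(cell) or (isinstance(cell, str) and not cell.strip()):
                continue
            try:
                energies[col] = float(cell)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path}: non-numeric energy {cell!r} in row {row_idx}, column {col!r}"
                ) from None
        records.append(EnergyRecord(conformer_id=str(row["conformer_id"]), energies=energies))
    return records


def write_energy_table(records: Iterable[EnergyRecord], path: str | Path) -> None:
    records = list(records)
    levels: list[str] = []
    for rec in records:
        for level in rec.energies:
            if level not in levels:
                levels.append(level)
    rows = [
        {"conformer_id": rec.conformer_id, **{lv: rec.energies.get(lv) for lv in levels}}
        for rec in records
    ]
    pd.DataFrame(rows, columns=["conformer_id", *levels]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# frequency tables
# ---------------------------------------------------------------------------


def read_frequency_table(path: str | Path) -> list[FrequencySet]:
    """Read a long-format CSV (``conformer_id,frequency_cm1[,linear]``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"conformer_id": str})
    for col in ("conformer_id", "frequency_cm1"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    out = []
    for cid, group in df.groupby("conformer_id", sort=False):
        freqs = group["frequency_cm1"].to_numpy(dtype=float)
        linear = bool(group["linear"].iloc[0]) if "linear" in df.columns else False
        out.append(FrequencySet(conformer_id=str(cid), frequencies=freqs, linear_flag=linear))
    return out


def write_frequency_table(freq_sets: Iterable[FrequencySet], path: str | Path) -> None:
    rows = [
        {"conformer_id": fs.conformer_id, "frequency_cm1": f, "linear": fs.linear_flag}
        for fs in freq_sets
        for f in fs.frequencies
    ]
    pd.DataFrame(rows, columns=["conformer_id", "frequency_cm1", "linear"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------


@dataclass
class Manifest:
    """Paths and conditions tying one analog's ensemble files together."""

    analog_id: str
    xyz: Path
    energies: Path
    frequencies: Path
    charge: int = 1  # ligands are N-protonated in aqueous solution
    temperature: float = 310.15

    def load(self) -> tuple[list[Conformer], list[EnergyRecord], list[FrequencySet]]:
        return (
            read_xyz_ensemble(self.xyz, analog_id=self.analog_id, charge=self.charge),
            read_energy_table(self.energies),
            read_frequency_table(self.frequencies),
        )


def read_manifest(path: str | Path) -> Manifest:
    path = Path(path)
    data: Mapping = json.loads(path.read_text())
    base = path.parent
    return Manifest(
        analog_id=str(data["analog_id"]),
        xyz=base / data["xyz"],
        energies=base / data["energies"],
        frequencies=base / data["frequencies"],
        charge=int(data.get("charge", 1)),
        temperature=float(data.get("temperature", 310.15)),
    )


def write_manifest(manifest: Manifest, path: str | Path) -> None:
    path = Path(path)
    payload = {
        "analog_id": manifest.analog_id,
        "xyz": Path(manifest.xyz).name,
        "energies": Path(manifest.energies).name,
        "frequencies": Path(manifest.frequencies).name,
        "charge": manifest.charge,
        "temperature": manifest.temperature,
    }
    path.write_text(json.dumps(payload, indent=2) + "\n")
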