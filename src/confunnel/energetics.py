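"""Complete-basis-set extrapolation, composite Gibbs energies, relative
energies, and the electronic-energy funnel window.

The CBS limit is estimated from the cc-pVDZ/TZ/QZ (or haug- counterparts)
triple by the three-point 4–5 inverse-polynomial scheme

    E_CBS = (243 E_DZ − 2048 E_TZ + 3125 E_QZ) / 1320

whose coefficients (3⁵, −2·4⁵, 5⁵)/1320 exactly annihilate both the N⁻⁴
and N⁻⁵ convergence terms at cardinal numbers N = 3, 4, 5. The scheme is
linear, so it applies equally to absolute electronic energies and to
relative (free) energies whose thermal part is level-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .constants import HARTREE_TO_KCAL, KCAL_TO_HARTREE
from .io_formats import EnergyRecord
from .thermochem import ThermoCorrections

CBS_COEFFS = (243.0, -2048.0, 3125.0)
CBS_DENOM = 1320.0


@dataclass(frozen=True)
class CompositeGibbs:
    """Electronic energy + RRHO correction for one conformer (hartree)."""

    conformer_id: str
    e_elec: float  # hartree, at level_label
    g_corr: float  # kcal/mol
    g_total: float  # hartree
    level_label: str
    temperature: float
    scale_factor: float


@dataclass(frozen=True)
class RelativeEnergyTable:
    """Per-conformer ΔG° (kcal/mol) relative to the ensemble minimum."""

    conformer_ids: tuple[str, ...]
    delta_g: tuple[float, ...]  # kcal/mol, min exactly 0
    reference_id: str
    level_label: str

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.conformer_ids, self.delta_g))


def cbs_extrapolate(e_dz: float, e_tz: float, e_qz: float) -> float:
    """Three-point CBS estimate from consecutive double/triple/quadruple-ζ
    energies (any single unit system; the output shares it)."""
    values = (e_dz, e_tz, e_qz)
    if not all(math.isfinite(v) for v in values):
        raise ValueError(f"non-finite input energies {values}")
    return (CBS_COEFFS[0] * e_dz + CBS_COEFFS[1] * e_tz + CBS_COEFFS[2] * e_qz) / CBS_DENOM


def cbs_extrapolate_record(
    record: EnergyRecord, augmented: bool = False
) -> EnergyRecord:
    """Return *record* with the extrapolated level added.

    ``augmented=False`` consumes DZ/TZ/QZ and adds ``CBS(DTQ)``;
    ``augmented=True`` consumes haDZ/haTZ/haQZ and adds ``CBS(haDTQ)``.
    """
    levels = ("haDZ", "haTZ", "haQZ") if augmented else ("DZ", "TZ", "QZ")
    target = "CBS(haDTQ)" if augmented else "CBS(DTQ)"
    missing = [lv for lv in levels if lv not in record]
    if missing:
        raise KeyError(
            f"conformer {record.conformer_id!r} lacks level(s) {missing} for {target}"
        )
    value = cbs_extrapolate(*(record[lv] for lv in levels))
    return EnergyRecord(
        conformer_id=record.conformer_id,
        energies={**record.energies, target: value},
    )


def composite_gibbs(
    record: EnergyRecord, corr: ThermoCorrections, level: str
) -> CompositeGibbs:
    """G_total = E_elec(level) + G°corr, in hartree, provenance stamped."""
    if level not in record:
        raise KeyError(
            f"conformer {record.conformer_id!r} has no energy at level {level!r}"
        )
    e_elec = record[level]
    g_total = e_elec + corr.g_corr * KCAL_TO_HARTREE
    return CompositeGibbs(
        conformer_id=record.conformer_id,
        e_elec=e_elec,
        g_corr=corr.g_corr,
        g_total=g_total,
        level_label=level,
        temperature=corr.temperature,
        scale_factor=corr.scale_factor,
    )


def relative_gibbs(ensemble: Sequence[CompositeGibbs]) -> RelativeEnergyTable:
    """ΔG° in kcal/mol relative to the ensemble minimum.

    All entries must share one level label (mixing a partially computed
    augmented level with the full set would corrupt downstream Boltzmann
    denominators). Ties at the minimum resolve to the lexicographically
    smallest conformer id.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    labels = {e.level_label for e in ensemble}
    if len(labels) > 1:
        raise ValueError(f"mixed energy levels in one ensemble: {sorted(labels)}")
    g = np.array([e.g_total for e in ensemble])
    g_min = g.min()
    ref = min(e.conformer_id for e, gi in zip(ensemble, g) if gi == g_min)
    delta = (g - g_min) * HARTREE_TO_KCAL
    return RelativeEnergyTable(
        conformer_ids=tuple(e.conformer_id for e in ensemble),
        delta_g=tuple(float(d) for d in delta),
        reference_id=ref,
        level_label=labels.pop(),
    )


def relative_from_values(
    ids: Sequence[str], values_kcal: Sequence[float], level: str = "CBS(DTQ)"
) -> RelativeEnergyTable:
    """Build a relative table directly from kcal/mol values (re-referenced
    to their minimum)."""
    if len(ids) == 0:
        raise ValueError("empty ensemble")
    v = np.asarray(values_kcal, dtype=float)
    vmin = v.min()
    ref = min(i for i, vi in zip(ids, v) if vi == vmin)
    return RelativeEnergyTable(
        conformer_ids=tuple(ids),
        delta_g=tuple(float(x) for x in v - vmin),
        reference_id=ref,
        level_label=level,
    )


def energy_window_filter(
    ids: Sequence[str], rel_kcal: Sequence[float], window: float
) -> list[str]:
    """Ids whose relative energy is within *window* kcal/mol of the minimum
    (inclusive boundary). Typically applied to DFT electronic energies
    before the expensive coupled-cluster stage (default window 8)."""
    if window < 0:
        raise ValueError("window must be non-negative")
    return [i for i, e in zip(ids, rel_kcal) if e <= window]


def relative_electronic_kcal(
    records: Iterable[EnergyRecord], level: str
) -> tuple[list[str], list[float]]:
    """Relative electronic energies (kcal/mol) at *level* across records."""
    records = list(records)
    missing = [r.conformer_id for r in records if level not in r]
    if missing:
        raise KeyError(f"level {level!r} missing for conformer(s) {missing}")
    e = np.array([r[level] for r in records])
    rel = (e - e.min()) * HARTREE_TO_KCAL
    return [r.conformer_id for r in records], [float(x) for x in rel]
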