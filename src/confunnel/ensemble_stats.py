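"""Boltzmann populations, ensemble stabilization free energy, population
subsets, conformer-type censuses, and pharmacology correlation reports.

For an ensemble with relative free energies ΔG°_i (kcal/mol, minimum 0)
at temperature T:

* Boltzmann percentage:  BP_i = 100 · exp(−ΔG°_i/RT) / Σ_j exp(−ΔG°_j/RT)
* stabilization free energy:  ΔG°{A} = −RT ln Σ_i exp(−ΔG°_i/RT)

ΔG°{A} ≤ 0 always, with equality only for a single conformer at 0: it is
the entropic lowering of the ensemble free energy relative to the global
minimum alone. Populations are only meaningful when every surviving
conformer has an energy at the chosen level; a partial high-level subset
would leave the denominator incomplete, so that case is refused.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .constants import DEFAULT_TEMPERATURE_K, R_KCAL_MOL_K
from .energetics import RelativeEnergyTable
from .geometry import ConformationLabel

CLASS_NAMES = ("cis", "trans", "gauche")


@dataclass(frozen=True)
class PopulationTable:
    conformer_ids: tuple[str, ...]
    bp: tuple[float, ...]  # percent, sums to 100
    temperature: float
    level_label: str
    complete_flag: bool = True

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.conformer_ids, self.bp))


@dataclass(frozen=True)
class StabilizationResult:
    dg_stab: float  # kcal/mol, <= 0
    n_conformers: int
    temperature: float


@dataclass(frozen=True)
class Census:
    counts: dict[str, int]  # keys cis/trans/gauche
    bp_cutoff: float

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def boltzmann_percentages(
    rel: RelativeEnergyTable,
    temperature: float = DEFAULT_TEMPERATURE_K,
    complete: bool = True,
) -> PopulationTable:
    """Equilibrium population share (percent) of each conformer.

    ``complete`` asserts that *rel* covers the entire surviving ensemble at
    its level; pass ``complete=False`` only to acknowledge explicitly that
    a partial table would produce unreliable percentages — it still raises.
    """
    if not complete:
        raise ValueError(
            "refusing to compute Boltzmann percentages from an incomplete "
            "ensemble: the partition-sum denominator would be unrepresentative"
        )
    dg = np.asarray(rel.delta_g, dtype=float)
    w = np.exp(-dg / (R_KCAL_MOL_K * temperature))
    bp = 100.0 * w / w.sum()
    return PopulationTable(
        conformer_ids=rel.conformer_ids,
        bp=tuple(float(x) for x in bp),
        temperature=temperature,
        level_label=rel.level_label,
        complete_flag=True,
    )


def stabilization_correction(
    rel: RelativeEnergyTable, temperature: float = DEFAULT_TEMPERATURE_K
) -> StabilizationResult:
    """Ensemble stabilization ΔG°{A} = −RT ln Σ exp(−ΔG°_i/RT), kcal/mol."""
    dg = np.asarray(rel.delta_g, dtype=float)
    if dg.size == 0:
        raise ValueError("empty ensemble")
    if not math.isclose(dg.min(), 0.0, abs_tol=1e-9):
        raise ValueError("relative table must contain its reference at Δ G° = 0")
    rt = R_KCAL_MOL_K * temperature
    dg_stab = -rt * float(np.log(np.sum(np.exp(-dg / rt))))
    return StabilizationResult(
        dg_stab=dg_stab, n_conformers=int(dg.size), temperature=temperature
    )


def population_subset(pop: PopulationTable, cutoff: float) -> list[str]:
    """Conformer ids with BP strictly above *cutoff* percent, descending BP."""
    if not 0 <= cutoff < 100:
        raise ValueError("cutoff must lie in [0, 100)")
    pairs = [(cid, bp) for cid, bp in zip(pop.conformer_ids, pop.bp) if bp > cutoff]
    pairs.sort(key=lambda p: (-p[1], p[0]))
    return [cid for cid, _ in pairs]


def conformer_type_census(
    labels: Mapping[str, ConformationLabel | str],
    pop: PopulationTable,
    cutoff: float = 0.5,
) -> Census:
    """Count cis/trans/gauche conformers among those with BP above *cutoff*."""
    selected = population_subset(pop, cutoff)
    missing = [cid for cid in selected if cid not in labels]
    if missing:
        raise KeyError(f"no conformation label for conformer(s) {missing}")
    counts = {name: 0 for name in CLASS_NAMES}
    for cid in selected:
        lab = labels[cid]
        name = lab.label if isinstance(lab, ConformationLabel) else str(lab)
        if name not in counts:
            raise ValueError(f"unknown conformation class {name!r} for {cid!r}")
        counts[name] += 1
    return Census(counts=counts, bp_cutoff=cutoff)


# ---------------------------------------------------------------------------
# pharmacology correlation report
# ---------------------------------------------------------------------------

_CENSORED_RE = re.compile(r"^\s*>\s*([0-9.]+)\s*$")


def parse_potency(value: float | int | str) -> tuple[float, bool]:
    """Parse a potency/affinity cell; ``'>1000'`` → (1000.0, censored=True)."""
    if isinstance(value, (int, float)):
        return float(value), False
    m = _CENSORED_RE.match(value)
    if m:
        return float(m.group(1)), True
    return float(value), False


@dataclass(frozen=True)
class CorrelationReport:
    """Descriptive association between a per-analog summary and one
    pharmacology measure. No significance claim is made."""

    measure: str
    analogs_spearman: tuple[str, ...]
    analogs_pearson: tuple[str, ...]
    spearman_rho: float  # censored entries included as tied maxima
    pearson_r: float  # on log10(nM), censored entries excluded
    n_censored: int


def pharmacology_correlation(
    summary: Mapping[str, float],
    pharm: Mapping[str, float | str],
    measure: str = "potency",
) -> CorrelationReport:
    """Rank and linear association between a per-analog summary statistic
    (e.g. the stabilization ΔG°{A}) and experimental potency/affinity (nM).

    Censored entries like ``'>1000'`` enter the Spearman rank as ties at
    their bound and are excluded from the Pearson coefficient, which is
    computed on log10(nM).
    """
    shared = sorted(set(summary) & set(pharm))
    if len(shared) < 3:
        raise ValueError(f"need at least 3 shared analogs, have {len(shared)}")
    x = np.array([summary[a] for a in shared], dtype=float)
    parsed = [parse_potency(pharm[a]) for a in shared]
    y = np.array([v for v, _ in parsed])
    censored = np.array([c for _, c in parsed])

    rho = float(stats.spearmanr(x, y).statistic)

    keep = ~censored
    if keep.sum() >= 3:
        r = float(stats.pearsonr(x[keep], np.log10(y[keep])).statistic)
        pearson_analogs = tuple(a for a, k in zip(shared, keep) if k)
    else:
        r = float("nan")
        pearson_analogs = ()
    return CorrelationReport(
        measure=measure,
        analogs_spearman=tuple(shared),
        analogs_pearson=pearson_analogs,
        spearman_rho=rho,
        pearson_r=r,
        n_censored=int(censored.sum()),
    )
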