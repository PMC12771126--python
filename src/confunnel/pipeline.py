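"""End-to-end funnel orchestration: manifests in, per-analog reports out.

Stage order per analog: duplicate removal → electronic-energy window →
RRHO thermochemistry → CBS extrapolation and composite ΔG° → Boltzmann
populations and stabilization → conformation classification → census.
Each analog is processed in isolation; a failure aborts that analog with
a logged cause and the others proceed. Identical inputs and configuration
produce byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .dedup import deduplicate
from .energetics import (
    cbs_extrapolate,
    cbs_extrapolate_record,
    composite_gibbs,
    energy_window_filter,
    relative_electronic_kcal,
    relative_gibbs,
)
from .ensemble_stats import (
    Census,
    PopulationTable,
    StabilizationResult,
    boltzmann_percentages,
    conformer_type_census,
    stabilization_correction,
)
from .geometry import ClassificationError, classify_conformation
from .io_formats import Manifest
from .thermochem import thermo_corrections

logger = logging.getLogger("confunnel")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable funnel parameters; serialized into every report."""

    temperature: float = 310.15  # K
    pressure: float = 1.0  # bar
    scale_factor: float = 0.971
    rot_tol: float = 0.01
    e_tol: float = 0.1  # kcal/mol
    window: float = 8.0  # kcal/mol, on relative DFT electronic energies
    bp_cutoffs: tuple[float, ...] = (0.5, 5.0)  # percent
    cis_max_deg: float = 60.0
    trans_min_deg: float = 135.0
    bp_level: str = "CBS(DTQ)"
    dedup_level: str = "DFT"
    window_level: str = "DFT"
    sigma: int = 1

    def __post_init__(self) -> None:
        for name in ("temperature", "pressure", "scale_factor", "rot_tol", "e_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.window < 0:
            raise ValueError("window must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalogReport:
    """Per-analog funnel outcome, mirroring a one-row funnel summary."""

    analog_id: str
    stage_counts: dict[str, int]
    dg_stab: float | None
    population: pd.DataFrame | None  # conformer_id, dg_kcal, bp_percent, class, angle
    censuses: dict[float, Census]
    reference_id: str | None
    config: PipelineConfig
    error: str | None = None
    version: str = __version__

    @property
    def failed(self) -> bool:
        return self.error is not None

    def summary_row(self) -> dict:
        row: dict = {"analog": self.analog_id, **self.stage_counts}
        row["dg_stab_kcal"] = self.dg_stab
        for cutoff, census in self.censuses.items():
            for name, count in census.counts.items():
                row[f"{name}_above_{cutoff:g}pct"] = count
        row["error"] = self.error or ""
        return row


def run_analog(manifest: Manifest, config: PipelineConfig) -> AnalogReport:
    """Run the funnel for one analog's manifest."""
    t0 = time.perf_counter()
    conformers, energy_records, frequency_sets = manifest.load()
    by_id = {c.conformer_id: c for c in conformers}
    energies = {r.conformer_id: r for r in energy_records}
    freqs = {f.conformer_id: f for f in frequency_sets}
    stage_counts = {"input": len(conformers)}

    def log_stage(stage: str, n_out: int) -> None:
        logger.info(
            "analog=%s stage=%s in=%d out=%d elapsed=%.2fs",
            manifest.analog_id, stage, stage_counts.get("input", 0), n_out,
            time.perf_counter() - t0,
        )

    # 1. duplicate removal at the sampling-comparison level
    dedup_energy = {
        cid: energies[cid][config.dedup_level] for cid in by_id if cid in energies
    }
    missing = sorted(set(by_id) - set(dedup_energy))
    if missing:
        raise KeyError(
            f"analog {manifest.analog_id!r}: no {config.dedup_level} energy for {missing}"
        )
    decision = deduplicate(
        conformers, dedup_energy, rot_tol=config.rot_tol, e_tol=config.e_tol
    )
    survivors = list(decision.kept_ids)
    stage_counts["after_dedup"] = len(survivors)
    log_stage("dedup", len(survivors))

    # 2. electronic-energy window on relative DFT energies
    ids, rel = relative_electronic_kcal(
        [energies[cid] for cid in survivors], config.window_level
    )
    survivors = energy_window_filter(ids, rel, config.window)
    stage_counts["after_window"] = len(survivors)
    log_stage("window", len(survivors))

    # 3-4. thermochemistry + CBS + composite relative ΔG°
    composites = []
    for cid in survivors:
        corr = thermo_corrections(
            by_id[cid],
            freqs.get(cid),
            temperature=config.temperature,
            pressure=config.pressure,
            sigma=config.sigma,
            scale=config.scale_factor,
        )
        record = energies[cid]
        if config.bp_level == "CBS(DTQ)" and "CBS(DTQ)" not in record:
            record = cbs_extrapolate_record(record)
        elif config.bp_level == "CBS(haDTQ)" and "CBS(haDTQ)" not in record:
            record = cbs_extrapolate_record(record, augmented=True)
        composites.append(composite_gibbs(record, corr, config.bp_level))
    rel_table = relative_gibbs(composites)
    stage_counts["with_composite_dg"] = len(composites)

    # 5. populations + stabilization
    pop = boltzmann_percentages(rel_table, temperature=config.temperature)
    stab = stabilization_correction(rel_table, temperature=config.temperature)
    log_stage("populations", len(survivors))

    # 6. classification
    labels = {}
    for cid in survivors:
        labels[cid] = classify_conformation(
            by_id[cid], cis_max=config.cis_max_deg, trans_min=config.trans_min_deg
        )

    # 7. censuses at each cutoff
    censuses = {
        cutoff: conformer_type_census(labels, pop, cutoff)
        for cutoff in config.bp_cutoffs
    }
    log_stage("census", len(survivors))

    dg_map = rel_table.as_dict()
    bp_map = pop.as_dict()
    population = pd.DataFrame(
        {
            "conformer_id": survivors,
            "dg_kcal": [dg_map[c] for c in survivors],
            "bp_percent": [bp_map[c] for c in survivors],
            "conformation": [labels[c].label for c in survivors],
            "separation_angle_deg": [labels[c].separation_angle for c in survivors],
        }
    ).sort_values("dg_kcal", kind="stable", ignore_index=True)

    return AnalogReport(
        analog_id=manifest.analog_id,
        stage_counts=stage_counts,
        dg_stab=stab.dg_stab,
        population=population,
        censuses=censuses,
        reference_id=rel_table.reference_id,
        config=config,
    )


def run_pipeline(
    manifests: Sequence[Manifest], config: PipelineConfig | None = None
) -> list[AnalogReport]:
    """Run the funnel for every manifest; one analog's failure never
    corrupts the others."""
    config = config or PipelineConfig()
    reports = []
    for manifest in manifests:
        try:
            reports.append(run_analog(manifest, config))
        except (ValueError, KeyError, OSError, ClassificationError) as exc:
            logger.error("analog=%s failed: %s", manifest.analog_id, exc)
            reports.append(
                AnalogReport(
                    analog_id=manifest.analog_id,
                    stage_counts={},
                    dg_stab=None,
                    population=None,
                    censuses={},
                    reference_id=None,
                    config=config,
                    error=str(exc),
                )
            )
    return reports


def write_reports(reports: Sequence[AnalogReport], out_dir: str | Path) -> None:
    """CSV per analog plus a funnel-summary CSV and a JSON config echo."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for report in reports:
        rows.append(report.summary_row())
        if report.population is not None:
            report.population.to_csv(
                out_dir / f"{report.analog_id}_population.csv", index=False
            )
    pd.DataFrame(rows).to_csv(out_dir / "funnel_summary.csv", index=False)
    if reports:
        header = {"version": reports[0].version, "config": reports[0].config.to_dict()}
        (out_dir / "run_config.json").write_text(json.dumps(header, indent=2) + "\n")


# ---------------------------------------------------------------------------
# ζ-level convergence report
# ---------------------------------------------------------------------------


def basis_ladder_report(ladder: pd.DataFrame) -> pd.DataFrame:
    """Augment a per-conformer ζ-level table with the CBS extrapolation and
    consecutive-ζ convergence differences.

    *ladder* needs a ``structure`` column plus relative (free) energies in
    kcal/mol at ``haDZ``/``haTZ``/``haQZ`` (optionally ``ha5Z``). Adds
    ``CBS(haDTQ)``, ``ddg_haQZ-haTZ`` and, when ha5Z is present,
    ``ddg_ha5Z-haQZ``. Missing optional columns are skipped with a
    warning, never fabricated.
    """
    required = ("haDZ", "haTZ", "haQZ")
    missing = [col for col in required if col not in ladder.columns]
    if missing:
        raise KeyError(f"ladder table lacks required column(s) {missing}")
    out = ladder.copy()
    out["CBS(haDTQ)"] = [
        cbs_extrapolate(dz, tz, qz)
        for dz, tz, qz in zip(out["haDZ"], out["haTZ"], out["haQZ"])
    ]
    out["ddg_haQZ-haTZ"] = out["haQZ"] - out["haTZ"]
    if "ha5Z" in out.columns:
        out["ddg_ha5Z-haQZ"] = out["ha5Z"] - out["haQZ"]
    else:
        logger.warning("no ha5Z column; ddg_ha5Z-haQZ omitted")
    return out
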