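"""Synthetic conformer ensembles with planted ground truth.

Real inputs to this pipeline are quantum-chemistry outputs (optimized
geometries, basis-set-resolved electronic energies, harmonic frequencies).
This module fabricates statistically analogous ensembles so every
downstream stage can be exercised and checked against known answers:

* geometries are fentanyl-like probes — a protonated-nitrogen surrogate
  in a saturated six-ring plus two planar aryl six-rings whose
  centroid-separation angle (seen from the nitrogen) is set exactly,
  planting the cis/trans/gauche class;
* electronic energies at the DZ/TZ/QZ levels follow
  ``E_N = E_CBS + a N⁻⁴ + b N⁻⁵`` at cardinal numbers N = 3, 4, 5 around a
  planted CBS limit, plus optional declared Gaussian noise;
* harmonic frequencies are 3N−6 positive modes with a deliberately
  low-frequency-rich profile;
* the planted total ΔG° ordering and class labels are recorded in a
  ground-truth table that the pipeline never reads.

Everything is deterministic for a fixed seed (one integer, propagated
to every draw; no global random state).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import KCAL_TO_HARTREE
from .io_formats import (
    Conformer,
    EnergyRecord,
    FrequencySet,
    Manifest,
    write_energy_table,
    write_frequency_table,
    write_manifest,
    write_xyz_ensemble,
)
from .thermochem import thermo_corrections

#: Angle windows (degrees) the generator draws from for each planted class.
CLASS_ANGLE_WINDOWS = {"cis": (5.0, 50.0), "gauche": (65.0, 130.0), "trans": (140.0, 178.0)}

_AROMATIC_CC = 1.39  # Å
_RING1_DIST = 5.0  # Å, anchor to first ring centroid
_RING2_DIST = 7.0  # Å, anchor to second ring centroid (offset avoids overlap)
_SATURATED_CC = 1.54  # Å


@dataclass
class EnsembleSpec:
    """Recipe for one synthetic analog ensemble."""

    analog_id: str
    n_conformers: int
    class_mix: tuple[float, float, float] = (0.6, 0.15, 0.25)  # cis, trans, gauche
    dg_spread_kcal: float = 8.0
    e_base_hartree: float = -1000.0
    convergence_coeffs: tuple[float, float] = (0.05, -0.02)  # (a, b), hartree
    noise_sigma_hartree: float = 0.0
    n_low_modes: int = 10
    low_mode_range: tuple[float, float] = (20.0, 300.0)
    high_mode_range: tuple[float, float] = (400.0, 3300.0)
    freq_jitter_cm1: float = 3.0  # per-conformer mode scatter about the shared set
    dft_offset_hartree: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_conformers < 1:
            raise ValueError("n_conformers must be >= 1")
        if self.dg_spread_kcal < 0:
            raise ValueError("dg_spread_kcal must be >= 0")
        if not math.isclose(sum(self.class_mix), 1.0, abs_tol=1e-9):
            raise ValueError("class_mix fractions must sum to 1")
        if any(f < 0 for f in self.class_mix):
            raise ValueError("class_mix fractions must be non-negative")
        n_nonzero = sum(1 for f in self.class_mix if f > 0)
        if n_nonzero > self.n_conformers:
            raise ValueError(
                f"cannot realize {n_nonzero} classes with {self.n_conformers} conformer(s)"
            )


@dataclass
class SyntheticEnsemble:
    conformers: list[Conformer]
    energy_records: list[EnergyRecord]
    frequency_sets: list[FrequencySet]
    ground_truth: pd.DataFrame = field(repr=False)


def _hexagon(radius: float) -> np.ndarray:
    ang = np.arange(6) * math.pi / 3.0
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)])


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Proper rotation taking +z to *direction* (unit)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, direction)
    c = float(np.dot(z, direction))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def generate_two_ring_probe(
    angle_deg: float,
    seed: int = 0,
    analog_id: str = "probe",
    conformer_id: str = "0",
    jitter: float = 0.01,
) -> Conformer:
    """A fentanyl-like toy: protonated-N surrogate in a chair six-ring and
    two face-on planar aryl rings at a set centroid-separation angle.

    The angle between the anchor→centroid unit vectors equals *angle_deg*
    within 1° (small seeded jitter keeps structures non-identical). The
    two centroid distances differ so that rings never fuse at small
    angles, and the chair ring stays clear of both aryl rings under the
    bond-perception rule.
    """
    if not 0.0 <= angle_deg <= 180.0:
        raise ValueError(f"angle_deg must be in [0, 180], got {angle_deg}")
    rng = np.random.default_rng(seed)

    # chair piperidine surrogate: N + 5 C, mean plane normal along z
    chair_radius = math.sqrt(_SATURATED_CC**2 - 0.25)
    chair = _hexagon(chair_radius)
    chair[:, 2] = 0.25 * np.array([1, -1, 1, -1, 1, -1])
    chair -= chair[0]  # nitrogen (atom 0) at origin
    elements = ["N", "C", "C", "C", "C", "C"]
    coords = [chair]

    # aryl rings, face-on to the anchor→centroid direction, in the xz-plane
    u1 = np.array([0.0, 0.0, 1.0])
    theta = math.radians(angle_deg)
    u2 = np.array([math.sin(theta), 0.0, math.cos(theta)])
    for direction, dist in ((u1, _RING1_DIST), (u2, _RING2_DIST)):
        ring = _hexagon(_AROMATIC_CC) @ _rotation_to(direction).T + dist * direction
        coords.append(ring)
        elements.extend(["C"] * 6)

    xyz = np.vstack(coords)
    if jitter > 0:
        xyz = xyz + rng.normal(scale=jitter, size=xyz.shape)
    return Conformer(
        conformer_id=conformer_id,
        analog_id=analog_id,
        elements=tuple(elements),
        coords=xyz,
        charge=1,
        comment=f"{analog_id} {conformer_id}",
    )


def _allocate_class_counts(mix: tuple[float, float, float], n: int) -> dict[str, int]:
    """Largest-remainder allocation so counts sum to n and honor the mix."""
    names = ("cis", "trans", "gauche")
    raw = [f * n for f in mix]
    counts = [int(math.floor(r)) for r in raw]
    remainders = sorted(
        range(3), key=lambda i: (raw[i] - counts[i], mix[i]), reverse=True
    )
    for i in remainders[: n - sum(counts)]:
        counts[i] += 1
    return dict(zip(names, counts))


def generate_ensemble(spec: EnsembleSpec) -> SyntheticEnsemble:
    """Build one complete synthetic analog ensemble with planted truth.

    The conformer at rank 0 sits at planted ΔG° = 0; the remaining planted
    ΔG° values are uniform on (0, ``dg_spread_kcal``]. Each conformer's
    planted CBS electronic energy is back-solved through the package's
    RRHO corrections so that electronic + thermal Gibbs energies reproduce
    the planted total ΔG° ordering exactly when noise is zero.
    """
    rng = np.random.default_rng(spec.seed)
    counts = _allocate_class_counts(spec.class_mix, spec.n_conformers)
    classes = [name for name in ("cis", "trans", "gauche") for _ in range(counts[name])]
    rng.shuffle(classes)

    n = spec.n_conformers
    dg = np.zeros(n)
    if n > 1:
        dg[1:] = np.sort(rng.uniform(0.0, spec.dg_spread_kcal, size=n - 1))

    conformers: list[Conformer] = []
    energy_records: list[EnergyRecord] = []
    frequency_sets: list[FrequencySet] = []
    truth_rows = []
    width = len(str(n - 1))
    base_freqs: np.ndarray | None = None
    for i in range(n):
        cid = f"{spec.analog_id}-{i:0{width}d}"
        cls = classes[i]
        lo, hi = CLASS_ANGLE_WINDOWS[cls]
        angle = float(rng.uniform(lo, hi))
        child_seed = int(rng.integers(0, 2**31 - 1))
        conf = generate_two_ring_probe(
            angle, seed=child_seed, analog_id=spec.analog_id, conformer_id=cid
        )
        n_modes = 3 * conf.n_atoms - 6
        if base_freqs is None:
            # conformers of one molecule share their mode structure; draw
            # the profile once and scatter it mildly per conformer
            n_high = n_modes - spec.n_low_modes
            base_freqs = np.concatenate(
                [
                    rng.uniform(*spec.low_mode_range, size=spec.n_low_modes),
                    rng.uniform(*spec.high_mode_range, size=n_high),
                ]
            )
        freqs = base_freqs + rng.normal(scale=spec.freq_jitter_cm1, size=n_modes)
        freqs = np.maximum(freqs, 10.0)  # never plant imaginary modes
        fset = FrequencySet(conformer_id=cid, frequencies=freqs)
        corr = thermo_corrections(conf, fset)

        # back-solve the planted CBS limit from the planted total ΔG°
        cbs_truth = spec.e_base_hartree + (dg[i] - corr.g_corr) * KCAL_TO_HARTREE
        a, b = spec.convergence_coeffs
        energies = {
            label: cbs_truth + a * nn**-4 + b * nn**-5
            for label, nn in (("DZ", 3), ("TZ", 4), ("QZ", 5))
        }
        energies["DFT"] = cbs_truth + spec.dft_offset_hartree
        if spec.noise_sigma_hartree > 0:
            for label in energies:
                energies[label] += rng.normal(scale=spec.noise_sigma_hartree)

        conformers.append(conf)
        energy_records.append(EnergyRecord(conformer_id=cid, energies=energies))
        frequency_sets.append(fset)
        truth_rows.append(
            {
                "conformer_id": cid,
                "planted_class": cls,
                "planted_angle_deg": angle,
                "planted_cbs_hartree": cbs_truth,
                "planted_dg_kcal": dg[i],
                "planted_rank": i,
            }
        )

    return SyntheticEnsemble(
        conformers=conformers,
        energy_records=energy_records,
        frequency_sets=frequency_sets,
        ground_truth=pd.DataFrame(truth_rows),
    )


def write_ensemble(ens: SyntheticEnsemble, out_dir: str | Path,
                   temperature: float = 310.15) -> Path:
    """Write XYZ/CSV files plus manifest; returns the manifest path.

    The ground-truth table is written alongside (``*_truth.csv``) but is
    not referenced by the manifest: the pipeline never consumes it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    analog_id = ens.conformers[0].analog_id
    xyz = out_dir / f"{analog_id}.xyz"
    energies = out_dir / f"{analog_id}_energies.csv"
    freqs = out_dir / f"{analog_id}_frequencies.csv"
    write_xyz_ensemble(ens.conformers, xyz)
    write_energy_table(ens.energy_records, energies)
    write_frequency_table(ens.frequency_sets, freqs)
    ens.ground_truth.to_csv(out_dir / f"{analog_id}_truth.csv", index=False)
    manifest = Manifest(
        analog_id=analog_id,
        xyz=xyz,
        energies=energies,
        frequencies=freqs,
        charge=1,
        temperature=temperature,
    )
    manifest_path = out_dir / f"{analog_id}_manifest.json"
    write_manifest(manifest, manifest_path)
    return manifest_path
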