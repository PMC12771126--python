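"""Published reference tables for the fentanyl-analog conformer study.

These small tables are *inputs* shipped for demonstrations, cross-checks
and the reproduction script; nothing here is computed by this package.

* :func:`analog31_basis_ladder` — relative Gibbs free energies (kcal/mol,
  310.15 K) of seven conformers of trans-3-methyl fentanyl (analog 31) at
  the haug-cc-pVNZ levels N = D, T, Q, 5. The DZ/TZ/QZ columns are the
  natural inputs to the three-point CBS extrapolation.
* :func:`pharmacology_table` — hMOR binding affinity (Ki, nM) and potency
  (EC50, nM) for fentanyl and its 33 analogs; censored assay entries are
  kept as ``">bound"`` strings.
* :func:`funnel_summary` — per-analog conformer counts surviving each
  funnel stage and the reported ensemble stabilization ΔG°{A} (kcal/mol).
"""

from __future__ import annotations

import pandas as pd

_ANALOG31_LADDER_ROWS = [
    # structure, haDZ, haTZ, haQZ, ha5Z  (ΔG°, kcal/mol, 310.15 K)
    ("265", 0.000, 0.000, 0.000, 0.000),
    ("151", 1.920, 2.207, 2.330, 2.321),
    ("161", 1.564, 1.870, 2.067, 2.101),
    ("128", 1.826, 2.078, 2.363, 2.431),
    ("207", 2.255, 2.320, 2.408, 2.449),
    ("261", 1.809, 1.658, 1.617, 1.611),
    ("250", 2.360, 2.397, 2.429, 2.448),
]

_PHARMACOLOGY_ROWS = [
    # analog, derivative name, Ki (nM), EC50 (nM); ">x" marks censored assays
    ("1", "fentanyl", 1.6, 32),
    ("2", "cyclopropyl", 2.4, 55),
    ("3", "p-methyl cyclopropyl", 7.2, ">1000"),
    ("4", "cyclobutyl", 5, 160),
    ("5", "cyclopentyl", 6.6, 600),
    ("6", "furanyl", 1.3, 9.3),
    ("7", "tetrahydrofuran", 31, 360),
    ("8", "acetyl", 64, ">2000"),
    ("9", "o-methyl acetyl", 43, ">1000"),
    ("10", "alpha-methyl acetyl", 19, ">500"),
    ("11", "acryl", 2.1, 68),
    ("12", "o-fluoro acryl", 1.1, 14),
    ("13", "p-fluoro acryl", 4.3, 84),
    ("14", "isobutyryl", 6.6, 137),
    ("15", "o-fluoro isobutyryl", 1.3, 42),
    ("16", "m-fluoro isobutyryl", 4.5, ">500"),
    ("17", "p-fluoro isobutyryl", 24, ">1000"),
    ("18", "p-chloro isobutyryl", 82, ">2000"),
    ("19", "pivaloyl", 4.5, 531),
    ("20", "butyryl", 3.5, 80),
    ("21", "o-fluoro butyryl", 0.7, 60),
    ("22", "methoxyacetyl", 17, ">500"),
    ("23", "o-fluoro", 0.4, 15),
    ("24", "m-fluoro", 10, 164),
    ("25", "p-fluoro", 4.2, 79),
    ("26", "o-methyl", 3.4, 58),
    ("27", "m-methyl", 5.5, 450),
    ("28", "p-methyl", 4.2, ">1000"),
    ("29", "p-chloro", 45, ">1000"),
    ("30", "cis-3-methyl", 0.32, 4.2),
    ("31", "trans-3-methyl", 1.1, 25),
    ("32", "furanylethyl", 8, 350),
    ("33", "beta-hydroxy", 6.2, 138),
    ("34", "beta-methyl", 14, ">500"),
]

_FUNNEL_ROWS = [
    # analog, sampled, dft_optimized, windowed, augmented_subset, dg_stab
    ("1", 229, 82, 60, 3, -0.34),
    ("2", 259, 89, 69, 7, -0.97),
    ("3", 177, 50, 37, 3, -0.57),
    ("4", 145, 61, 49, 4, -0.58),
    ("5", 253, 100, 77, 5, -0.81),
    ("6", 157, 70, 55, 6, -0.71),
    ("7", 485, 206, 146, 5, -0.98),
    ("8", 126, 40, 32, 3, -0.17),
    ("9", 213, 52, 49, 5, -0.52),
    ("10", 162, 65, 51, 3, -0.36),
    ("11", 172, 71, 51, 4, -0.33),
    ("12", 292, 136, 101, 4, -0.52),
    ("13", 228, 83, 60, 3, -0.66),
    ("14", 226, 83, 59, 4, -0.52),
    ("15", 288, 85, 61, 5, -0.83),
    ("16", 320, 127, 127, 6, -0.81),
    ("17", 246, 79, 53, 4, -0.62),
    ("18", 261, 71, 51, 4, -0.71),
    ("19", 167, 52, 52, 6, -0.76),
    ("20", 428, 170, 133, 3, -0.32),
    ("21", 655, 284, 210, 4, -1.27),
    ("22", 393, 168, 118, 5, -0.39),
    ("23", 315, 129, 91, 5, -0.80),
    ("24", 397, 173, 117, 5, -0.90),
    ("25", 235, 87, 62, 2, -0.31),
    ("26", 405, 143, 124, 3, -0.65),
    ("27", 450, 133, 102, 3, -0.66),
    ("28", 382, 95, 69, 7, -1.03),
    ("29", 295, 93, 71, 6, -0.95),
    ("30", 409, 114, 99, 5, -0.65),
    ("31", 427, 130, 83, 3, -0.67),
    ("32", 309, 137, 102, 5, -0.81),
    ("33", 503, 296, 246, 5, -0.94),
    ("34", 536, 238, 214, 4, -0.42),
]


def analog31_basis_ladder() -> pd.DataFrame:
    """ζ-level relative free energies for analog 31 (kcal/mol, 310.15 K)."""
    return pd.DataFrame(
        _ANALOG31_LADDER_ROWS, columns=["structure", "haDZ", "haTZ", "haQZ", "ha5Z"]
    )


def pharmacology_table() -> pd.DataFrame:
    """hMOR Ki / EC50 (nM) for fentanyl and 33 analogs."""
    return pd.DataFrame(
        _PHARMACOLOGY_ROWS, columns=["analog", "derivative", "ki_nm", "ec50_nm"]
    )


def funnel_summary() -> pd.DataFrame:
    """Per-analog survivor counts per funnel stage and reported ΔG°{A}."""
    return pd.DataFrame(
        _FUNNEL_ROWS,
        columns=["analog", "sampled", "dft_optimized", "windowed",
                 "augmented_subset", "dg_stab_kcal"],
    )
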