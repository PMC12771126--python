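"""Physical constants, atomic data and unit conversions.

All physical constants are CODATA 2018 (via :mod:`scipy.constants`).
Energies are exchanged in hartree between modules and converted to
kcal/mol only at reporting boundaries.
"""

from __future__ import annotations

import scipy.constants as _sc

# --- fundamental constants (SI) ---
PLANCK_J_S = _sc.h
BOLTZMANN_J_K = _sc.k
AVOGADRO = _sc.N_A
SPEED_OF_LIGHT_M_S = _sc.c
AMU_KG = _sc.atomic_mass

# --- gas constant in the unit systems used downstream ---
R_KCAL_MOL_K = 1.987204259e-3  # kcal mol^-1 K^-1
R_CAL_MOL_K = 1.987204259  # cal mol^-1 K^-1
R_L_BAR_MOL_K = 1e-2 * _sc.R  # L bar mol^-1 K^-1

# --- unit conversions ---
HARTREE_TO_KCAL = 627.509474
KCAL_TO_HARTREE = 1.0 / HARTREE_TO_KCAL
ANGSTROM_TO_M = 1e-10
BAR_TO_PA = 1e5

#: Default thermochemistry conditions: human physiological temperature.
DEFAULT_TEMPERATURE_K = 310.15
DEFAULT_PRESSURE_BAR = 1.0
#: Harmonic-frequency scale factor for wB97X-D/6-31++G** (anharmonicity proxy).
DEFAULT_FREQ_SCALE = 0.971

#: Electronic-energy level labels the pipeline understands.
LEVEL_VOCABULARY = frozenset(
    {
        "DZ",
        "TZ",
        "QZ",
        "5Z",
        "haDZ",
        "haTZ",
        "haQZ",
        "ha5Z",
        "DFT",
        "CBS(DTQ)",
        "CBS(haDTQ)",
    }
)

#: Most-abundant-isotope atomic masses (u), IUPAC/AME2020 values.
ATOMIC_MASS_U: dict[str, float] = {
    "H": 1.00782503207,
    "He": 4.00260325415,
    "Li": 7.01600455,
    "Be": 9.0121822,
    "B": 11.0093054,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "F": 18.99840322,
    "Ne": 19.9924401754,
    "Na": 22.9897692809,
    "Mg": 23.985041700,
    "Al": 26.98153863,
    "Si": 27.9769265325,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Ar": 39.9623831225,
    "K": 38.96370668,
    "Ca": 39.96259098,
    "Br": 78.9183371,
    "I": 126.904473,
}

#: Covalent radii (Å), Cordero et al. consensus values; C is sp3.
COVALENT_RADIUS_A: dict[str, float] = {
    "H": 0.31,
    "He": 0.28,
    "Li": 1.28,
    "Be": 0.96,
    "B": 0.84,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "F": 0.57,
    "Ne": 0.58,
    "Na": 1.66,
    "Mg": 1.41,
    "Al": 1.21,
    "Si": 1.11,
    "P": 1.07,
    "S": 1.05,
    "Cl": 1.02,
    "Ar": 1.06,
    "K": 2.03,
    "Ca": 1.76,
    "Br": 1.20,
    "I": 1.39,
}

#: Bond-perception slack added to the covalent-radius sum (Å).
BOND_TOLERANCE_A = 0.45

# fmt: off
PERIODIC_TABLE = frozenset({
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg", "Al",
    "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
    "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr", "Rb", "Sr",
    "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn",
    "Sb", "Te", "I", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Pm", "Sm",
    "Eu", "Gd", "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W",
    "Re", "Os", "Ir", "Pt", "Au", "Hg", "Tl", "Pb", "Bi", "Po", "At", "Rn",
    "Fr", "Ra", "Ac", "Th", "Pa", "U", "Np", "Pu", "Am", "Cm", "Bk", "Cf",
    "Es", "Fm", "Md", "No", "Lr", "Rf", "Db", "Sg", "Bh", "Hs", "Mt", "Ds",
    "Rg", "Cn", "Nh", "Fl", "Mc", "Lv", "Ts", "Og",
})
# fmt: on


def atomic_mass(symbol: str) -> float:
    """Most-abundant-isotope mass of *symbol* in u."""
    try:
        return ATOMIC_MASS_U[symbol]
    except KeyError:
        raise KeyError(f"no atomic mass tabulated for element {symbol!r}") from None


def covalent_radius(symbol: str) -> float:
    """Covalent radius of *symbol* in Å."""
    try:
        return COVALENT_RADIUS_A[symbol]
    except KeyError:
        raise KeyError(f"no covalent radius tabulated for element {symbol!r}") from None
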