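"""Ideal-gas rigid-rotor/harmonic-oscillator thermochemistry.

Given a geometry and its harmonic wavenumbers, computes the zero-point
energy and the thermal corrections H°corr, S°corr and G°corr at a stated
temperature and pressure (defaults: 310.15 K, 1 bar). Frequencies are
scaled uniformly — ZPE included — by a level-of-theory factor (default
0.971 for wB97X-D/6-31++G**) as a proxy for anharmonicity; no quasi-RRHO
damping of low modes is applied.

Contributions:

* translation — Sackur–Tetrode entropy, 3/2 RT thermal energy;
* rotation — classical rigid rotor from the principal moments of inertia
  with a symmetry number (default 1: the ligands are asymmetric);
* vibration — harmonic-oscillator sum over the scaled modes.

``H°corr = ZPE + E_trans + E_rot + E_vib + RT`` and
``G°corr = H°corr − T·S°corr`` hold identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import (
    AMU_KG,
    AVOGADRO,
    BAR_TO_PA,
    BOLTZMANN_J_K,
    DEFAULT_FREQ_SCALE,
    DEFAULT_PRESSURE_BAR,
    DEFAULT_TEMPERATURE_K,
    PLANCK_J_S,
    R_CAL_MOL_K,
    R_KCAL_MOL_K,
    R_L_BAR_MOL_K,
    SPEED_OF_LIGHT_M_S,
    atomic_mass,
)
from .geometry import principal_moments
from .io_formats import Conformer, FrequencySet

_J_PER_MOL_TO_KCAL = 1.0 / 4184.0


@dataclass(frozen=True)
class ThermoCorrections:
    """RRHO corrections for one conformer at (temperature, pressure)."""

    zpe: float  # kcal/mol
    h_corr: float  # kcal/mol
    s_corr: float  # cal/(mol K)
    g_corr: float  # kcal/mol
    temperature: float  # K
    pressure: float  # bar
    scale_factor: float


def scale_frequencies(freqs: Sequence[float], factor: float) -> np.ndarray:
    """Multiply wavenumbers elementwise by *factor* (> 0), preserving order.

    Non-positive input frequencies are imaginary modes and are rejected:
    the caller must drop saddle points explicitly, never silently.
    """
    if factor <= 0:
        raise ValueError(f"scale factor must be positive, got {factor}")
    freqs = np.asarray(freqs, dtype=float)
    bad = freqs[freqs <= 0]
    if bad.size:
        raise ValueError(
            f"imaginary/zero mode(s) present: {bad.tolist()} cm^-1; "
            "thermochemistry requires a true minimum"
        )
    return freqs * factor


def _vibrational_terms(freqs_cm1: np.ndarray, T: float) -> tuple[float, float, float]:
    """(ZPE, thermal vibrational energy) in kcal/mol and S_vib in cal/(mol K)."""
    theta = PLANCK_J_S * SPEED_OF_LIGHT_M_S * 100.0 * freqs_cm1 / BOLTZMANN_J_K  # K
    x = theta / T
    zpe = 0.5 * R_KCAL_MOL_K * float(np.sum(theta))
    expm = np.expm1(x)
    e_vib = R_KCAL_MOL_K * float(np.sum(theta / expm))
    s_vib = R_CAL_MOL_K * float(np.sum(x / expm - np.log1p(-np.exp(-x))))
    return zpe, e_vib, s_vib


def _translational_entropy(mass_amu: float, T: float, P_bar: float) -> float:
    """Sackur–Tetrode entropy in cal/(mol K)."""
    m = mass_amu * AMU_KG
    lam = (2.0 * math.pi * m * BOLTZMANN_J_K * T) / PLANCK_J_S**2  # 1/m^2
    q_trans = lam**1.5 * BOLTZMANN_J_K * T / (P_bar * BAR_TO_PA)
    return R_CAL_MOL_K * (math.log(q_trans) + 2.5)


def _rotational_terms(c: Conformer, T: float, sigma: int,
                      linear: bool) -> tuple[float, float]:
    """(E_rot kcal/mol, S_rot cal/(mol K)) for the classical rigid rotor."""
    moments = principal_moments(c) * AMU_KG * 1e-20  # kg m^2
    rot_theta = PLANCK_J_S**2 / (8.0 * math.pi**2 * BOLTZMANN_J_K)  # K * kg m^2
    if linear:
        i_eq = moments[-1]
        q_rot = T * i_eq / (sigma * rot_theta)
        return R_KCAL_MOL_K * T, R_CAL_MOL_K * (math.log(q_rot) + 1.0)
    thetas = rot_theta / moments  # K
    q_rot = math.sqrt(math.pi) / sigma * math.sqrt(T**3 / np.prod(thetas))
    return 1.5 * R_KCAL_MOL_K * T, R_CAL_MOL_K * (math.log(q_rot) + 1.5)


def thermo_corrections(
    c: Conformer,
    freqs: FrequencySet | None,
    temperature: float = DEFAULT_TEMPERATURE_K,
    pressure: float = DEFAULT_PRESSURE_BAR,
    sigma: int = 1,
    scale: float = DEFAULT_FREQ_SCALE,
) -> ThermoCorrections:
    """RRHO corrections for one conformer.

    For a single atom *freqs* may be None (translation only). Polyatomics
    must supply exactly 3N−6 (3N−5 when ``linear_flag``) positive
    wavenumbers; the mode count is checked, and the geometry itself must
    agree with the linear flag.
    """
    if temperature <= 0 or pressure <= 0:
        raise ValueError("temperature and pressure must be positive")
    n = c.n_atoms
    mass = sum(atomic_mass(sym) for sym in c.elements)
    s_trans = _translational_entropy(mass, temperature, pressure)
    e_trans = 1.5 * R_KCAL_MOL_K * temperature

    if n == 1:
        zpe = e_vib = s_vib = 0.0
        e_rot = s_rot = 0.0
    else:
        if freqs is None:
            raise ValueError("polyatomic conformer requires a FrequencySet")
        linear = freqs.linear_flag
        moments = principal_moments(c)
        geom_linear = moments[0] < 1e-8 * moments[-1]
        if geom_linear and not linear:
            raise ValueError(
                f"conformer {c.conformer_id!r} is collinear but linear_flag is unset"
            )
        expected = freqs.expected_count(n)
        if len(freqs.frequencies) != expected:
            raise ValueError(
                f"conformer {c.conformer_id!r}: {len(freqs.frequencies)} modes, "
                f"expected {expected} (3N-{5 if linear else 6} for N={n})"
            )
        scaled = scale_frequencies(freqs.frequencies, scale)
        zpe, e_vib, s_vib = _vibrational_terms(scaled, temperature)
        e_rot, s_rot = _rotational_terms(c, temperature, sigma, linear)

    s_corr = s_trans + s_rot + s_vib  # cal/(mol K); electronic degeneracy 1
    h_corr = zpe + e_trans + e_rot + e_vib + R_KCAL_MOL_K * temperature
    g_corr = h_corr - temperature * s_corr * 1e-3
    return ThermoCorrections(
        zpe=zpe,
        h_corr=h_corr,
        s_corr=s_corr,
        g_corr=g_corr,
        temperature=temperature,
        pressure=pressure,
        scale_factor=scale,
    )


def standard_state_offset(temperature: float = DEFAULT_TEMPERATURE_K) -> float:
    """Free-energy change (kcal/mol) from the 1 bar gas to the 1 mol/L solution
    standard state: ``RT ln(c° R T / p°)``.

    Roughly 2 kcal/mol at physiological temperature. It is identical for
    every conformer of one molecule, so it cancels in relative ΔG° and is
    reported only — never silently added to any correction.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    # c° RT / p° with c° = 1 mol/L, p° = 1 bar; R in L bar / (mol K)
    ratio = R_L_BAR_MOL_K * temperature
    return R_KCAL_MOL_K * temperature * math.log(ratio)
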