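# Methods

## Scope and model

`confunnel` post-processes conformer ensembles of a single flexible
molecule in solution. Its inputs are the outputs of quantum-chemistry
engines — optimized Cartesian geometries, electronic energies at named
basis-set levels (hartree), and harmonic vibrational wavenumbers — and
its outputs are relative Gibbs free energies, Boltzmann populations,
ensemble stabilization corrections and conformational taxonomies at a
stated temperature. The funnel stages run in a fixed order per analog:

1. duplicate removal (rotational constants + energy rule),
2. electronic-energy window on relative DFT energies,
3. RRHO thermochemistry per survivor,
4. CBS extrapolation and composite ΔG° = E_elec + G°corr,
5. Boltzmann percentages and stabilization ΔG°{A},
6. cis/trans/gauche classification and census.

The pipeline is deterministic: randomness exists only in the synthetic
generator, driven by one integer seed.

## CBS extrapolation

The complete-basis-set limit is estimated from energies at three
consecutive correlation-consistent levels with cardinal numbers
N = 3, 4, 5 (cc-pVDZ/TZ/QZ, or the heavy-atom-augmented haug- series):

    E_CBS = (243 E_DZ − 2048 E_TZ + 3125 E_QZ) / 1320.

Writing the basis-set error as a·N⁻⁴ + b·N⁻⁵, the coefficient triple
(3⁵, −2·4⁵, 5⁵) sums to the denominator 1320 and annihilates both error
terms identically, so on data of exactly that convergence form the
scheme returns the limit to rounding error. It is linear, hence equally
valid on absolute electronic energies and on relative free energies
whose thermal part is level-independent; both pathways are implemented
and agree by construction (asserted in the tests via the linearity
property). Two-point schemes, focal-point corrections and counterpoise
are out of scope.

## RRHO thermochemistry

Standard ideal-gas statistical mechanics at temperature T (default
310.15 K, human physiological) and pressure 1 bar:

- translation: Sackur–Tetrode entropy, 3/2 RT thermal energy;
- rotation: classical rigid rotor from the principal moments of inertia
  (most-abundant-isotope masses), symmetry number σ (default 1 — the
  ligands of interest are asymmetric), with the linear-rotor special
  case behind an explicit flag;
- vibration: harmonic-oscillator sums over the scaled wavenumbers, ZPE
  included in H°corr and G°corr.

H°corr = ZPE + E_trans + E_rot + E_vib + RT and
G°corr = H°corr − T·S°corr hold identically (tested to 1e-6 kcal/mol).
Units follow quantum-chemistry convention: energies in kcal/mol, entropy
in cal mol⁻¹ K⁻¹.

Anharmonicity is absorbed by scaling every harmonic wavenumber by a
level-of-theory factor, default 0.971 (appropriate for
ωB97X-D/6-31++G** frequencies); the factor multiplies the ZPE term as
well as the thermal terms (uniform scaling). No quasi-RRHO or free-rotor
damping of low modes is applied — scaled harmonics are the method, not a
fallback. Imaginary (negative) wavenumbers are preserved by the readers
and rejected by the thermochemistry with the offending mode named:
saddle points must be excluded deliberately, never silently.

The 1-bar-gas → 1-mol/L-solution standard-state change
RT·ln(c°RT/p°) evaluates to 2.00 kcal/mol at 310.15 K (1.90 at
298.15 K with the 1 bar convention used throughout). It is identical for
all conformers of one molecule, cancels in every relative quantity, and
is therefore only ever *reported*.

Physical constants are CODATA 2018 via scipy; the gas constant used in
all Boltzmann factors is R = 1.987204259×10⁻³ kcal mol⁻¹ K⁻¹; hartree →
kcal/mol is 627.509474. All constants live in one module
(`confunnel.constants`).

## Duplicate filtering

Conformers are sorted by ascending energy (ties broken by id, making the
result independent of file order) and scanned greedily; a candidate is a
duplicate of an already-kept conformer when **all three** rotational
constants differ by less than 1% relative to the kept conformer's values
**and** the energies differ by less than 0.1 kcal/mol. The kept twin is
therefore always the lowest-energy member of its duplicate group — the
conservative choice for downstream minima. An "any constant" variant is
exposed as a flag. Because the underlying tolerance relation is not
transitive, a connected-component formulation (duplicate graph, keep the
lowest-energy member of each component) is provided as an oracle;
`deduplicate(..., check_components=True)` reports any conformers on
which the two views disagree rather than hiding them.

## Conformation classification

Bond perception uses interatomic distance < sum of covalent radii
(Cordero values) + 0.45 Å. Aromatic-ring candidates are simple six-cycles
of the bond graph that are all-carbon and planar within 0.1 Å mean
out-of-plane deviation (this excludes chairs/boats and hetero-rings;
furan- or thiophene-containing analogs are classified by supplying the
two ring index sets explicitly). The anchor atom is the nitrogen inside
a saturated six-ring (the protonated piperidine nitrogen in the
fentanyl scaffold), falling back to any nitrogen.

The separation angle is measured between the two unit vectors from the
anchor to each ring centroid. Class boundaries: cis < 60°,
60° ≤ gauche < 135°, trans ≥ 135°. The literature describes the classes
only qualitatively (approximately parallel / ~90° / ~180°); these
boundaries are generous midpoints chosen by this package and exposed as
configuration. The anchor-to-centroid metric was preferred over
ring-plane normals because it is robust to ring tilt and matches the
"ring position" notion; the plane-normal metric can be computed from the
returned ring index sets if needed.

## Atom-matched RMSD

`rmsd_aligned` superposes two conformers with the Kabsch algorithm
(proper rotations only, determinant +1) and, when atom matching is
enabled, alternates minimum-cost per-element assignment (Hungarian
algorithm on squared distances) with re-superposition until the mapping
is stable (cap 50 iterations). Because that iteration is a local search,
it is restarted from the identity orientation and from every proper
alignment of the two structures' principal axes (axis permutations ×
sign flips, 24 proper rotations), keeping the best result. RMSD is
mass-unweighted over all atoms by default, with a heavy-atom-only flag
(the all-atom/heavy-atom choice is not standardized in the literature
this mirrors). An exhaustive within-element permutation search is
provided for small structures and doubles as the test oracle; on 50
random ≤8-atom pairs the multi-start search reproduces it exactly.

## Ensemble statistics

Populations and the stabilization correction use the same partition sum,
and the identity exp(−ΔG°{A}/RT) = Σ_i exp(−ΔG°_i/RT) is asserted in
tests. Percentages must be computed over the *complete* surviving
ensemble at one level; a request acknowledging an incomplete ensemble is
refused outright, because a partial high-accuracy subset (e.g. only the
conformers above 5% population recomputed with augmented basis sets)
would make the denominator unrepresentative. Population thresholds
("above 0.5%", "above 5%") use strict inequality. No degeneracy weights
are applied.

The pharmacology report is purely descriptive: Spearman rank and Pearson
(on log₁₀ nM) coefficients between a per-analog summary (typically
ΔG°{A}) and Ki or EC50. Censored assay entries (">500", ">1000",
">2000") enter the rank coefficient as ties at their bound and are
excluded from the Pearson coefficient; both analog lists are returned so
the treatment is auditable. No significance claim is attached.

## Synthetic-data generator

The generator emulates the statistical structure of a real ensemble so
that every stage has a known right answer:

- **Geometry** — an 18-atom probe: a chair six-ring containing the
  anchor nitrogen, plus two planar C₆ rings placed face-on at 5.0 and
  7.0 Å from the anchor with an exact centroid-separation angle
  (± small seeded jitter, within 1°). Idealized bond lengths (aromatic
  C–C 1.39 Å, saturated C–C 1.54 Å, C–N 1.47 Å); the two radial
  distances differ so rings never approach within bonding distance even
  at 0°, and the chair clears both rings under the bond-perception rule.
  Classification depends only on ring placement, so fuller chemical
  realism (hydrogens, substituents) is deliberately omitted.
- **Energies** — the conformer at rank 0 sits at planted ΔG° = 0 and the
  rest are uniform over (0, spread] with spread default 8 kcal/mol (the
  funnel's window width; populated conformers in practice cluster within
  ~3 kcal/mol of the minimum, which the default also exercises).
  DZ/TZ/QZ energies follow E_N = E_CBS + a N⁻⁴ + b N⁻⁵ around the
  planted CBS limit, plus optional declared Gaussian noise; a DFT-level
  energy (constant offset) feeds the dedup and window stages.
- **Frequencies** — 3N−6 positive modes, ten of them low-frequency
  (20–300 cm⁻¹) as in floppy drug-like molecules. One base mode set is
  drawn per ensemble and scattered per conformer (σ = 3 cm⁻¹), because
  conformers of one molecule share their mode structure; independent
  per-conformer draws would produce unphysically large spreads in
  G°corr.
- **Back-solved electronic truth** — the planted CBS limit of conformer
  i is E_base + (ΔG°_i − G°corr,i)/627.509474, with G°corr,i computed by
  the package's own RRHO code on the conformer's geometry and
  frequencies. A zero-noise pipeline run therefore reproduces the planted
  total ΔG° ordering exactly. This is a plumbing check by construction —
  the RRHO code itself is validated independently against closed-form
  oracles (Sackur–Tetrode, single-oscillator formulas), so no circularity
  reaches the physics.

What passing on synthetic data does **not** show: agreement with real
potential-energy surfaces, solvation physics (SMD or explicit water),
the statistics of real CREST pools, or real basis-set convergence beyond
the assumed N⁻⁴/N⁻⁵ form with small noise.

## Numerical choices and degenerate inputs

- Inclusive boundary on the energy window (a conformer at exactly
  8 kcal/mol is kept); the window applies to relative DFT electronic
  energies, not composite ΔG° (both configurable).
- Relative-energy reference ties break to the lexicographically smallest
  conformer id.
- A single atom has no rotational constants (error); a collinear
  polyatomic requires its linear flag and yields two equal finite
  constants with the degenerate flag set.
- Mixed basis-set levels in one relative-energy table are an error, to
  prevent silently mixing a partial augmented-level subset into a full
  ensemble.
- Missing energy cells in tables remain *absent levels*, never zeros.

## Problem sizes

The test suite and the reproduction script run on small ensembles
(10–45 conformers per analog, 18-atom probes, ≤8-atom RMSD oracle
cases, 100-ensemble property sweeps) — sizes at which the exhaustive
oracles (permutation search, duplicate-graph components, extended-
precision closed forms) are exact and fast, which is what makes them
trustworthy cross-checks. All statistics scale linearly or quadratically
in ensemble size, so nothing changes structurally at realistic ensemble
sizes (hundreds of conformers per analog).

## Known limitations

- No quantum-chemistry execution, no solvation model, no docking: the
  package trusts its input energies.
- Aromaticity perception is limited to planar all-carbon six-rings;
  hetero-aromatic rings must be supplied explicitly.
- Plain RRHO: hindered rotors and anharmonic (VPT2-style) corrections
  are intentionally not implemented.
- The greedy dedup order is a convention; where tolerance chains make
  the answer genuinely ambiguous the package reports the ambiguity
  instead of resolving it silently.
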