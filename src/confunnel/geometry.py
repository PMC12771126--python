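"""Molecular geometry: rotational constants, aromatic-ring detection,
cis/trans/gauche classification, and atom-matched rigid-body RMSD.

The conformation classes follow the fentanyl-family convention: the angle
between the two vectors running from the protonated piperidine nitrogen to
the centroids of the two phenyl rings. Roughly parallel rings (small angle)
are *cis*, rings on opposite sides (~180°) are *trans*, and an intermediate
~90° arrangement is *gauche*. The quantitative boundaries (60° and 135°)
are package defaults, exposed as parameters.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .constants import (
    AMU_KG,
    ANGSTROM_TO_M,
    BOND_TOLERANCE_A,
    PLANCK_J_S,
    atomic_mass,
    covalent_radius,
)
from .io_formats import Conformer

#: Default class boundaries (degrees) on the ring-centroid separation angle.
CIS_MAX_DEG = 60.0
TRANS_MIN_DEG = 135.0

#: Planarity cut for an aromatic six-ring: mean out-of-plane deviation (Å).
RING_PLANARITY_TOL_A = 0.1

_LINEAR_MOMENT_TOL = 1e-8  # relative, on the smallest principal moment


@dataclass(frozen=True)
class RotationalConstants:
    """Principal rotational constants in GHz, sorted ``A >= B >= C``."""

    A: float
    B: float
    C: float
    degenerate_flag: bool = False

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.A, self.B, self.C)


@dataclass(frozen=True)
class ConformationLabel:
    label: str  # "cis" | "trans" | "gauche"
    separation_angle: float  # degrees
    ring_atom_indices: tuple[frozenset, frozenset]
    anchor_index: int


@dataclass
class AlignmentResult:
    rmsd: float  # Å
    rotation: np.ndarray  # (3, 3) proper orthogonal
    translation: np.ndarray  # (3,) Å, applied after rotation of b
    atom_mapping: np.ndarray  # permutation: a[i] pairs with b[mapping[i]]


class ClassificationError(ValueError):
    """The conformer does not present exactly two classifiable rings."""


# ---------------------------------------------------------------------------
# rotational constants
# ---------------------------------------------------------------------------


def inertia_tensor(c: Conformer) -> np.ndarray:
    """Moment-of-inertia tensor (amu·Å²) about the center of mass."""
    masses = np.array([atomic_mass(sym) for sym in c.elements])
    xyz = c.coords - np.average(c.coords, axis=0, weights=masses)
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    ixx = np.sum(masses * (y * y + z * z))
    iyy = np.sum(masses * (x * x + z * z))
    izz = np.sum(masses * (x * x + y * y))
    ixy = -np.sum(masses * x * y)
    ixz = -np.sum(masses * x * z)
    iyz = -np.sum(masses * y * z)
    return np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])


def principal_moments(c: Conformer) -> np.ndarray:
    """Principal moments of inertia (amu·Å²), ascending."""
    return np.sort(np.linalg.eigvalsh(inertia_tensor(c)))


def _moment_to_ghz(moment_amu_a2: float) -> float:
    i_si = moment_amu_a2 * AMU_KG * ANGSTROM_TO_M**2
    return PLANCK_J_S / (8.0 * math.pi**2 * i_si) / 1e9


def rotational_constants(c: Conformer) -> RotationalConstants:
    """Rotational constants A ≥ B ≥ C in GHz from the inertia tensor.

    Linear (collinear) molecules get ``degenerate_flag`` and an infinite A
    with the two equal finite constants in B and C. A single atom has no
    rotational constants and raises ``ValueError``.
    """
    if c.n_atoms < 2:
        raise ValueError("rotational constants are undefined for a single atom")
    moments = principal_moments(c)
    if moments[0] < _LINEAR_MOMENT_TOL * moments[-1]:
        b = _moment_to_ghz(moments[1])
        return RotationalConstants(A=math.inf, B=b, C=_moment_to_ghz(moments[2]),
                                   degenerate_flag=True)
    ghz = sorted((_moment_to_ghz(m) for m in moments), reverse=True)
    return RotationalConstants(A=ghz[0], B=ghz[1], C=ghz[2])


# ---------------------------------------------------------------------------
# bond perception and ring detection
# ---------------------------------------------------------------------------


def bond_graph(c: Conformer, tolerance: float = BOND_TOLERANCE_A) -> nx.Graph:
    """Bonds from interatomic distances vs covalent-radius sums + *tolerance* Å."""
    g = nx.Graph()
    g.add_nodes_from(range(c.n_atoms))
    radii = np.array([covalent_radius(sym) for sym in c.elements])
    dist = np.linalg.norm(c.coords[:, None, :] - c.coords[None, :, :], axis=-1)
    cut = radii[:, None] + radii[None, :] + tolerance
    ii, jj = np.where((dist < cut) & np.triu(np.ones_like(dist, dtype=bool), k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


def _mean_plane_deviation(points: np.ndarray) -> float:
    centered = points - points.mean(axis=0)
    # smallest singular direction is the best-fit plane normal
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[-1]
    return float(np.mean(np.abs(centered @ normal)))


def six_membered_rings(c: Conformer, graph: nx.Graph | None = None) -> list[frozenset]:
    """All simple 6-cycles of the bond graph (any elements)."""
    graph = bond_graph(c) if graph is None else graph
    rings = {
        frozenset(cycle)
        for cycle in nx.simple_cycles(graph, length_bound=6)
        if len(cycle) == 6
    }
    return sorted(rings, key=sorted)


def detect_aromatic_six_rings(
    c: Conformer,
    planarity_tol: float = RING_PLANARITY_TOL_A,
    graph: nx.Graph | None = None,
) -> list[frozenset]:
    """Planar all-carbon six-rings (phenyl candidates).

    Saturated rings (chairs/boats) fail the planarity cut of
    *planarity_tol* Å mean out-of-plane deviation; hetero-rings fail the
    all-carbon requirement. Returns an empty list when nothing qualifies.
    """
    graph = bond_graph(c) if graph is None else graph
    out = []
    for ring in six_membered_rings(c, graph):
        if any(c.elements[i] != "C" for i in ring):
            continue
        if _mean_plane_deviation(c.coords[sorted(ring)]) <= planarity_tol:
            out.append(ring)
    return out


def _find_anchor_nitrogen(c: Conformer, graph: nx.Graph,
                          aromatic: Sequence[frozenset]) -> int:
    """The protonated-amine surrogate: a nitrogen inside a saturated six-ring."""
    aromatic_set = set(aromatic)
    candidates = []
    for ring in six_membered_rings(c, graph):
        if ring in aromatic_set:
            continue
        for i in ring:
            if c.elements[i] == "N":
                candidates.append(i)
    if not candidates:  # fall back to any nitrogen
        candidates = [i for i, sym in enumerate(c.elements) if sym == "N"]
    if not candidates:
        raise ClassificationError("no nitrogen atom found to anchor the classification")
    return min(candidates)


def classify_conformation(
    c: Conformer,
    rings: tuple[Sequence[int], Sequence[int]] | None = None,
    anchor_index: int | None = None,
    cis_max: float = CIS_MAX_DEG,
    trans_min: float = TRANS_MIN_DEG,
) -> ConformationLabel:
    """Label a conformer cis / gauche / trans from its two aryl rings.

    The separation angle is measured between the unit vectors from the
    anchor nitrogen to each ring centroid; ``angle < cis_max`` is *cis*,
    ``angle >= trans_min`` is *trans*, in between is *gauche*. Rings may be
    supplied explicitly (e.g. for furan/thiophene analogs); otherwise
    exactly two detected phenyl rings are required.
    """
    graph = bond_graph(c)
    if rings is None:
        detected = detect_aromatic_six_rings(c, graph=graph)
        if len(detected) != 2:
            raise ClassificationError(
                f"conformer {c.conformer_id!r}: found {len(detected)} qualifying "
                "aromatic six-rings, need exactly 2 (or supply ring index sets)"
            )
        ring_a, ring_b = detected
    else:
        ring_a, ring_b = (frozenset(rings[0]), frozenset(rings[1]))
    if anchor_index is None:
        anchor_index = _find_anchor_nitrogen(c, graph, (ring_a, ring_b))
    anchor = c.coords[anchor_index]
    angle = separation_angle(
        c.coords[sorted(ring_a)].mean(axis=0) - anchor,
        c.coords[sorted(ring_b)].mean(axis=0) - anchor,
    )
    if angle < cis_max:
        label = "cis"
    elif angle < trans_min:
        label = "gauche"
    else:
        label = "trans"
    return ConformationLabel(
        label=label,
        separation_angle=angle,
        ring_atom_indices=(ring_a, ring_b),
        anchor_index=anchor_index,
    )


def separation_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle in degrees between two vectors, in [0, 180]."""
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.degrees(math.acos(np.clip(cosang, -1.0, 1.0)))


# ---------------------------------------------------------------------------
# Kabsch superposition with optional per-element atom matching
# ---------------------------------------------------------------------------


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R, translation t minimizing ||p - (q R^T + t)||.

    Returns (R, t, q_aligned).
    """
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (q - qc).T @ (p - pc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = pc - qc @ rot.T
    return rot, t, q @ rot.T + t


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axes = vt
    if np.linalg.det(axes) < 0:
        axes = axes * np.array([[1.0], [1.0], [-1.0]])
    return axes


def _assign_per_element(elements: Sequence[str], pa: np.ndarray,
                        pb: np.ndarray) -> np.ndarray:
    """Minimum-cost pairing of b-atoms to a-atoms within each element class."""
    mapping = np.empty(len(elements), dtype=int)
    by_elem: dict[str, list[int]] = {}
    for i, sym in enumerate(elements):
        by_elem.setdefault(sym, []).append(i)
    for idx in by_elem.values():
        idx = np.array(idx)
        cost = np.linalg.norm(pa[idx][:, None, :] - pb[idx][None, :, :], axis=-1) ** 2
        rows, cols = linear_sum_assignment(cost)
        mapping[idx[rows]] = idx[cols]
    return mapping


def _rmsd(p: np.ndarray, q: np.ndarray) -> float:
    return float(np.sqrt(np.mean(np.sum((p - q) ** 2, axis=1))))


def rmsd_aligned(a: Conformer, b: Conformer, match_atoms: bool = True,
                 heavy_only: bool = False, max_iter: int = 50) -> AlignmentResult:
    """Mass-unweighted RMSD after optimal rigid superposition of *b* onto *a*.

    With ``match_atoms`` the atom correspondence is re-chosen within each
    element class by minimum-cost assignment, alternating with Kabsch
    superposition until the mapping is stable. The search is seeded from
    the identity frame and from the four proper principal-axes alignments
    of *b* onto *a* (the two-fold axis-flip ambiguity of the inertia
    frame), keeping the best result.
    """
    sel_a = [i for i, s in enumerate(a.elements) if not heavy_only or s != "H"]
    sel_b = [i for i, s in enumerate(b.elements) if not heavy_only or s != "H"]
    elems_a = [a.elements[i] for i in sel_a]
    elems_b = [b.elements[i] for i in sel_b]
    if sorted(elems_a) != sorted(elems_b):
        from collections import Counter

        diff = Counter(elems_a) - Counter(elems_b)
        diff.update(Counter(elems_b) - Counter(elems_a))
        raise ValueError(f"element multisets differ: {dict(diff)}")
    pa = np.asarray(a.coords[sel_a], dtype=float)
    pb = np.asarray(b.coords[sel_b], dtype=float)

    if not match_atoms:
        if elems_a != elems_b:
            raise ValueError("without atom matching, element orders must agree")
        rot, t, qb = _kabsch(pa, pb)
        return AlignmentResult(rmsd=_rmsd(pa, qb), rotation=rot, translation=t,
                               atom_mapping=np.arange(len(pa)))

    # candidate starting orientations of b: identity plus every proper
    # alignment of b's principal axes onto a's (axis order x sign flips)
    starts = [np.eye(3)]
    axes_a, axes_b = _principal_axes(pa), _principal_axes(pb)
    for order in itertools.permutations(range(3)):
        for signs in itertools.product((1.0, -1.0), repeat=3):
            m = np.zeros((3, 3))
            for row, (col, s) in enumerate(zip(order, signs)):
                m[row, col] = s
            if np.linalg.det(m) > 0:  # proper rotations only
                starts.append(axes_a.T @ m @ axes_b)

    best: AlignmentResult | None = None
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    for r0 in starts:
        pb0 = (pb - cb) @ r0.T + ca
        mapping = _assign_per_element(elems_a, pa, pb0)
        for _ in range(max_iter):
            rot, t, qb = _kabsch(pa, pb[mapping])
            # mapping convention: a[i] pairs with b[mapping[i]]
            new_mapping = _assign_per_element(elems_a, pa, (pb @ rot.T + t))
            if np.array_equal(new_mapping, mapping):
                break
            mapping = new_mapping
        rot, t, qb = _kabsch(pa, pb[mapping])
        result = AlignmentResult(rmsd=_rmsd(pa, qb), rotation=rot, translation=t,
                                 atom_mapping=mapping)
        if best is None or result.rmsd < best.rmsd:
            best = result
    assert best is not None
    return best


def brute_force_matched_rmsd(a: Conformer, b: Conformer) -> float:
    """Exhaustive search over all within-element atom permutations.

    Exponential; intended as an independent check for small structures
    (≲ 8 atoms per element class).
    """
    by_elem: dict[str, list[int]] = {}
    for i, sym in enumerate(a.elements):
        by_elem.setdefault(sym, []).append(i)
    if sorted(a.elements) != sorted(b.elements):
        raise ValueError("element multisets differ")
    b_by_elem: dict[str, list[int]] = {}
    for i, sym in enumerate(b.elements):
        b_by_elem.setdefault(sym, []).append(i)

    pa = np.asarray(a.coords, dtype=float)
    pb = np.asarray(b.coords, dtype=float)
    elems = sorted(by_elem)
    best = math.inf
    perm_lists = [list(itertools.permutations(b_by_elem[e])) for e in elems]
    for combo in itertools.product(*perm_lists):
        mapping = np.empty(len(a.elements), dtype=int)
        for elem, perm in zip(elems, combo):
            for ai, bi in zip(by_elem[elem], perm):
                mapping[ai] = bi
        _, _, qb = _kabsch(pa, pb[mapping])
        best = min(best, _rmsd(pa, qb))
    return best
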