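"""Duplicate-conformer removal by the rotational-constant / energy rule.

Two conformers are duplicates when all three rotational constants agree
within a relative tolerance (default 1%) *and* their energies agree within
an absolute tolerance (default 0.1 kcal/mol). The ensemble is scanned in
ascending energy order and each candidate is compared against the already
kept set, so the surviving representative of a duplicate group is its
lowest-energy member.

The tolerance relation is not transitive; ``connected_component_dedup``
provides an exhaustive graph-based cross-check, and ``deduplicate`` can
report where the greedy scan and the component view disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .constants import HARTREE_TO_KCAL
from .geometry import RotationalConstants, rotational_constants
from .io_formats import Conformer


@dataclass
class DedupDecision:
    kept_ids: list[str]
    removed: dict[str, str]  # removed id -> surviving twin id
    rot_tol: float
    e_tol: float
    discrepancies: list[str] = field(default_factory=list)


def _is_duplicate(
    kept: RotationalConstants,
    cand: RotationalConstants,
    de_kcal: float,
    rot_tol: float,
    e_tol: float,
    require_all: bool,
) -> bool:
    if abs(de_kcal) >= e_tol:
        return False
    close = [
        abs(a - b) < rot_tol * abs(a)
        for a, b in zip(kept.as_tuple(), cand.as_tuple())
    ]
    return all(close) if require_all else any(close)


def deduplicate(
    conformers: Sequence[Conformer],
    energies: Mapping[str, float],
    rot_tol: float = 0.01,
    e_tol: float = 0.1,
    energy_unit: str = "hartree",
    require_all_constants: bool = True,
    check_components: bool = False,
) -> DedupDecision:
    """Greedy lowest-energy-first duplicate removal.

    *energies* maps conformer id to the comparison-level energy; set
    ``energy_unit="kcal"`` if already in kcal/mol. Relative rotational
    agreement is measured against the kept (lower-energy) conformer.
    With ``check_components`` the result additionally records conformers
    on which the greedy scan and the duplicate-graph connected-component
    oracle disagree (possible for non-transitive tolerance chains).
    """
    if energy_unit not in ("hartree", "kcal"):
        raise ValueError(f"unknown energy unit {energy_unit!r}")
    factor = HARTREE_TO_KCAL if energy_unit == "hartree" else 1.0
    e_kcal: dict[str, float] = {}
    for c in conformers:
        if c.conformer_id not in energies:
            raise KeyError(f"no energy supplied for conformer {c.conformer_id!r}")
        e_kcal[c.conformer_id] = energies[c.conformer_id] * factor

    order = sorted(conformers, key=lambda c: (e_kcal[c.conformer_id], c.conformer_id))
    constants = {c.conformer_id: rotational_constants(c) for c in order}

    kept: list[str] = []
    removed: dict[str, str] = {}
    for cand in order:
        cid = cand.conformer_id
        twin = None
        for kid in kept:
            if _is_duplicate(
                constants[kid],
                constants[cid],
                e_kcal[cid] - e_kcal[kid],
                rot_tol,
                e_tol,
                require_all_constants,
            ):
                twin = kid
                break
        if twin is None:
            kept.append(cid)
        else:
            removed[cid] = twin

    decision = DedupDecision(kept_ids=kept, removed=removed, rot_tol=rot_tol, e_tol=e_tol)
    if check_components:
        oracle = connected_component_dedup(
            conformers, energies, rot_tol, e_tol, energy_unit, require_all_constants
        )
        decision.discrepancies = sorted(set(kept) ^ set(oracle))
    return decision


def connected_component_dedup(
    conformers: Sequence[Conformer],
    energies: Mapping[str, float],
    rot_tol: float = 0.01,
    e_tol: float = 0.1,
    energy_unit: str = "hartree",
    require_all_constants: bool = True,
) -> list[str]:
    """Exhaustive alternative: build the pairwise duplicate graph and keep
    the lowest-energy member of each connected component. O(n²); intended
    for cross-checks on small ensembles."""
    factor = HARTREE_TO_KCAL if energy_unit == "hartree" else 1.0
    e_kcal = {c.conformer_id: energies[c.conformer_id] * factor for c in conformers}
    constants = {c.conformer_id: rotational_constants(c) for c in conformers}
    g = nx.Graph()
    g.add_nodes_from(e_kcal)
    ordered = sorted(conformers, key=lambda c: (e_kcal[c.conformer_id], c.conformer_id))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1 :]:
            aid, bid = a.conformer_id, b.conformer_id
            if _is_duplicate(
                constants[aid],
                constants[bid],
                e_kcal[bid] - e_kcal[aid],
                rot_tol,
                e_tol,
                require_all_constants,
            ):
                g.add_edge(aid, bid)
    kept = [
        min(comp, key=lambda cid: (e_kcal[cid], cid))
        for comp in nx.connected_components(g)
    ]
    return sorted(kept, key=lambda cid: (e_kcal[cid], cid))
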