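import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from confunnel import (
    Conformer,
    classify_conformation,
    detect_aromatic_six_rings,
    generate_two_ring_probe,
    rmsd_aligned,
    rotational_constants,
)
from confunnel.constants import AMU_KG, PLANCK_J_S, atomic_mass
from confunnel.geometry import (
    ClassificationError,
    brute_force_matched_rmsd,
    principal_moments,
    six_membered_rings,
)

from .conftest import random_rotation


def _rigid_copy(c: Conformer, seed: int) -> Conformer:
    rng = np.random.default_rng(seed)
    rot = random_rotation(rng)
    return Conformer(
        c.conformer_id, c.analog_id, c.elements, c.coords @ rot.T + rng.normal(size=3)
    )


class TestRotationalConstants:
    def test_invariant_under_rigid_motion(self, water_like):
        ref = rotational_constants(water_like).as_tuple()
        moved = rotational_constants(_rigid_copy(water_like, 3)).as_tuple()
        np.testing.assert_allclose(moved, ref, rtol=1e-9)

    def test_homonuclear_diatomic_closed_form(self, nitrogen_diatomic):
        # B = h / (8 pi^2 mu r^2), reduced mass of two identical atoms = m/2
        r = 1.09768e-10
        mu = atomic_mass("N") * AMU_KG / 2.0
        b_ghz = PLANCK_J_S / (8 * math.pi**2 * mu * r**2) / 1e9
        rc = rotational_constants(nitrogen_diatomic)
        assert rc.degenerate_flag
        assert rc.B == pytest.approx(b_ghz, rel=1e-10)
        assert rc.C == pytest.approx(b_ghz, rel=1e-10)

    def test_bent_triatomic_matches_brute_force_diagonalization(self, water_like):
        import mpmath as mp

        mp.mp.dps = 40
        masses = [atomic_mass(s) for s in water_like.elements]
        com = np.average(water_like.coords, axis=0, weights=masses)
        xyz = water_like.coords - com
        tensor = mp.zeros(3, 3)
        for mass, (x, y, z) in zip(masses, xyz):
            mass, x, y, z = (mp.mpf(v) for v in (mass, x, y, z))
            tensor += mp.matrix(
                [
                    [mass * (y**2 + z**2), -mass * x * y, -mass * x * z],
                    [-mass * x * y, mass * (x**2 + z**2), -mass * y * z],
                    [-mass * x * z, -mass * y * z, mass * (x**2 + y**2)],
                ]
            )
        exact = sorted(float(v) for v in mp.eigsy(tensor, eigvals_only=True))
        np.testing.assert_allclose(principal_moments(water_like), exact, rtol=1e-10)

    def test_single_atom_rejected(self):
        atom = Conformer("a", "x", ("Ar",), np.zeros((1, 3)))
        with pytest.raises(ValueError):
            rotational_constants(atom)

    @given(scale=st.floats(0.5, 3.0))
    @settings(deadline=None, max_examples=25)
    def test_constants_scale_as_inverse_square(self, scale):
        base = generate_two_ring_probe(90.0, seed=5, jitter=0.0)
        scaled = Conformer("s", "x", base.elements, base.coords * scale)
        a = np.array(rotational_constants(base).as_tuple())
        b = np.array(rotational_constants(scaled).as_tuple())
        np.testing.assert_allclose(b, a / scale**2, rtol=1e-9)


class TestRingDetection:
    def test_benzene_one_ring(self, benzene_carbons):
        rings = detect_aromatic_six_rings(benzene_carbons)
        assert len(rings) == 1
        assert rings[0] == frozenset(range(6))

    def test_chair_excluded_by_planarity(self, cyclohexane_chair):
        assert six_membered_rings(cyclohexane_chair)  # the cycle exists...
        assert detect_aromatic_six_rings(cyclohexane_chair) == []  # ...but is not planar

    def test_probe_has_exactly_two_aromatic_rings(self):
        probe = generate_two_ring_probe(120.0, seed=9)
        rings = detect_aromatic_six_rings(probe)
        assert len(rings) == 2
        # graph-cycle oracle: aromatic rings must be 6-cycles of the bond graph
        all_cycles = set(six_membered_rings(probe))
        assert set(rings) <= all_cycles
        # neither contains a saturated-ring atom (indices 0-5 by construction)
        saturated = set(range(6))
        for ring in rings:
            assert not (set(ring) & saturated)


class TestClassification:
    @pytest.mark.parametrize(
        "angle,expected",
        [(0.0, "cis"), (10.0, "cis"), (90.0, "gauche"), (178.0, "trans")],
    )
    def test_probe_angles(self, angle, expected):
        label = classify_conformation(generate_two_ring_probe(angle, seed=2))
        assert label.label == expected
        assert label.separation_angle == pytest.approx(angle, abs=1.0)

    def test_invariant_under_rigid_motion_and_reindexing(self):
        probe = generate_two_ring_probe(75.0, seed=4)
        ref = classify_conformation(probe)
        moved = classify_conformation(_rigid_copy(probe, 11))
        assert moved.label == ref.label
        assert moved.separation_angle == pytest.approx(ref.separation_angle, abs=1e-6)
        rng = np.random.default_rng(12)
        perm = rng.permutation(probe.n_atoms)
        shuffled = Conformer(
            "p", "x", tuple(probe.elements[i] for i in perm), probe.coords[perm]
        )
        assert classify_conformation(shuffled).label == ref.label

    def test_wrong_ring_count_reports_count(self, benzene_carbons):
        with pytest.raises(ClassificationError, match="found 1"):
            classify_conformation(
                Conformer(
                    "b", "x", benzene_carbons.elements + ("N",),
                    np.vstack([benzene_carbons.coords, [[0.0, 0.0, 5.0]]]),
                )
            )

    def test_explicit_ring_sets_bypass_detection(self):
        # hetero second ring (furan-like): supply index sets explicitly
        probe = generate_two_ring_probe(100.0, seed=6)
        elements = list(probe.elements)
        elements[6] = "O"  # poison one detected ring
        modified = Conformer("m", "x", tuple(elements), probe.coords)
        label = classify_conformation(
            modified, rings=(list(range(6, 12)), list(range(12, 18)))
        )
        assert label.label == "gauche"


class TestRMSD:
    def test_identical_structures_zero(self):
        probe = generate_two_ring_probe(45.0, seed=1)
        assert rmsd_aligned(probe, probe).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rotated_translated_copy(self):
        probe = generate_two_ring_probe(45.0, seed=1)
        moved = _rigid_copy(probe, 2)
        result = rmsd_aligned(probe, moved, match_atoms=False)
        assert result.rmsd < 1e-8
        assert np.linalg.det(result.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_swapped_labels_need_matching(self):
        rng = np.random.default_rng(7)
        coords = rng.normal(size=(6, 3))
        a = Conformer("a", "x", ("C", "C", "H", "H", "O", "H"), coords)
        swapped = coords.copy()
        swapped[[2, 3]] = swapped[[3, 2]]  # exchange two hydrogens
        b = Conformer("b", "x", a.elements, swapped)
        assert rmsd_aligned(a, b, match_atoms=False).rmsd > 0.1
        assert rmsd_aligned(a, b, match_atoms=True).rmsd < 1e-8

    def test_symmetry_and_matching_never_hurts(self):
        rng = np.random.default_rng(8)
        for seed in range(5):
            n = int(rng.integers(4, 9))
            elems = tuple(rng.choice(["C", "H"], size=n))
            a = Conformer("a", "x", elems, rng.normal(size=(n, 3)) * 2)
            b = Conformer("b", "x", elems, rng.normal(size=(n, 3)) * 2)
            ab = rmsd_aligned(a, b).rmsd
            ba = rmsd_aligned(b, a).rmsd
            assert ab == pytest.approx(ba, abs=1e-10)
            assert ab <= rmsd_aligned(a, b, match_atoms=False).rmsd + 1e-12

    def test_matched_equals_exhaustive_permutation_search(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            elems = tuple(rng.choice(["C", "H", "O"], size=n))
            a = Conformer("a", "x", elems, rng.normal(size=(n, 3)) * 2)
            b = Conformer("b", "x", elems, rng.normal(size=(n, 3)) * 2)
            assert rmsd_aligned(a, b).rmsd == pytest.approx(
                brute_force_matched_rmsd(a, b), abs=1e-6
            )

    def test_element_mismatch_lists_imbalance(self):
        a = Conformer("a", "x", ("C", "H"), np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        b = Conformer("b", "x", ("C", "O"), np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        with pytest.raises(ValueError, match="differ"):
            rmsd_aligned(a, b)
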