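"""Geometry primitives against independent brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pisurvey.geometry import (GeometryError, build_hydrogens, dihedral,
                               fit_ring_plane, min_heavy_distance, place_atom,
                               random_rotation, rotation_about_axis, superpose,
                               tilt_angle)


def hexagon(z=0.0):
    ang = np.radians(60.0 * np.arange(6))
    return np.stack([np.cos(ang), np.sin(ang), np.full(6, z)], axis=1)


class TestPlaneFit:
    def test_planar_hexagon(self):
        plane = fit_ring_plane(hexagon())
        assert np.allclose(plane.centroid, [0, 0, 0], atol=1e-12)
        assert abs(abs(plane.unit_normal[2]) - 1.0) < 1e-12
        assert plane.rms_out_of_plane < 1e-12

    def test_translation_equivariance(self):
        shift = np.array([1.0, 2.0, 3.0])
        plane = fit_ring_plane(hexagon() + shift)
        assert np.allclose(plane.centroid, shift, atol=1e-12)
        assert abs(abs(plane.unit_normal[2]) - 1.0) < 1e-12

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pts = rng.normal(size=(7, 3)) * [2.0, 2.0, 0.2]
            plane = fit_ring_plane(pts)
            centered = pts - pts.mean(axis=0)
            # independent route: smallest eigenvector of the covariance
            evals, evecs = np.linalg.eigh(centered.T @ centered)
            oracle = evecs[:, 0]
            assert abs(np.dot(plane.unit_normal, oracle)) >= 1 - 1e-9

    def test_residual_not_beaten_by_random_planes(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        plane = fit_ring_plane(pts)
        centered = pts - pts.mean(axis=0)
        best = np.sqrt(np.mean((centered @ plane.unit_normal) ** 2))
        for _ in range(200):
            n = rng.normal(size=3)
            n /= np.linalg.norm(n)
            assert best <= np.sqrt(np.mean((centered @ n) ** 2)) + 1e-12

    def test_collinear_raises(self):
        pts = np.outer(np.arange(5), [1.0, 2.0, 3.0])
        with pytest.raises(GeometryError):
            fit_ring_plane(pts)


class TestTiltAngle:
    @pytest.mark.parametrize("angle,expected", [(0, 0), (90, 90), (120, 60),
                                                (30, 30), (150, 30)])
    def test_folds_into_quadrant(self, angle, expected):
        a = fit_ring_plane(hexagon())
        rot = rotation_about_axis([1, 0, 0], angle)
        b = fit_ring_plane(hexagon() @ rot.T)
        assert tilt_angle(a, b) == pytest.approx(expected, abs=1e-9)

    def test_symmetric_and_sign_free(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = fit_ring_plane(rng.normal(size=(5, 3)))
            b = fit_ring_plane(rng.normal(size=(5, 3)))
            assert tilt_angle(a, b) == pytest.approx(tilt_angle(b, a))
            flipped = type(b)(centroid=b.centroid, unit_normal=-b.unit_normal,
                              rms_out_of_plane=b.rms_out_of_plane)
            assert tilt_angle(a, flipped) == pytest.approx(tilt_angle(a, b))


class TestMinDistance:
    def test_two_atoms(self):
        assert min_heavy_distance([[0, 0, 0]], [[0, 0, 3.4]]) == pytest.approx(3.4)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = rng.normal(size=(20, 3)) * 5
            b = rng.normal(size=(20, 3)) * 5 + 3
            oracle = min(np.linalg.norm(p - q) for p in a for q in b)
            assert min_heavy_distance(a, b) == pytest.approx(oracle, abs=1e-12)
            assert min_heavy_distance(b, a) == pytest.approx(oracle, abs=1e-12)

    def test_empty_raises(self):
        with pytest.raises(GeometryError):
            min_heavy_distance(np.empty((0, 3)), [[0, 0, 0]])


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(4).normal(size=(6, 3))
        t = superpose(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
        assert t.rmsd < 1e-12

    def test_recovers_known_rotation(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            pts = rng.normal(size=(8, 3))
            rot = random_rotation(rng)
            shift = rng.normal(size=3)
            t = superpose(pts, pts @ rot.T + shift)
            assert np.allclose(t.rotation, rot, atol=1e-8)
            assert t.rmsd < 1e-9
            assert np.linalg.det(t.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_beats_rotation_grid_oracle(self):
        # Kabsch rmsd must not exceed any rotation in a coarse Euler grid
        rng = np.random.default_rng(6)
        mob = rng.normal(size=(6, 3))
        ref = mob @ random_rotation(rng).T + rng.normal(size=(6, 3)) * 0.3
        best = superpose(mob, ref).rmsd
        angles = np.arange(0, 360, 30.0)
        mc, rc = mob.mean(axis=0), ref.mean(axis=0)
        for a in angles:
            for b in angles[:6]:
                for c in angles:
                    rot = (rotation_about_axis([0, 0, 1], a)
                           @ rotation_about_axis([0, 1, 0], b)
                           @ rotation_about_axis([0, 0, 1], c))
                    moved = (mob - mc) @ rot.T + rc
                    rmsd = np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1)))
                    assert best <= rmsd + 1e-9

    def test_rmsd_invariant_to_prerotation(self):
        rng = np.random.default_rng(7)
        mob = rng.normal(size=(7, 3))
        ref = rng.normal(size=(7, 3))
        base = superpose(mob, ref).rmsd
        for _ in range(10):
            pre = random_rotation(rng)
            assert superpose(mob @ pre.T, ref).rmsd == pytest.approx(base,
                                                                     abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(GeometryError):
            superpose(np.zeros((4, 3)), np.zeros((5, 3)))


def dihedral_oracle(p1, p2, p3, p4):
    """Independent projection formula: angle between bond projections in
    the plane perpendicular to the central bond, signed by a triple
    product (no atan2)."""
    b2 = p3 - p2
    b2 = b2 / np.linalg.norm(b2)
    u = (p1 - p2) - np.dot(p1 - p2, b2) * b2
    v = (p4 - p3) - np.dot(p4 - p3, b2) * b2
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    if np.dot(np.cross(u, v), b2) < 0:
        ang = -ang
    return ang


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, 1, 0]) == \
            pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        assert dihedral([1, 1, 0], [1, 0, 0], [2, 0, 0], [2, -1, 0]) == \
            pytest.approx(180.0, abs=1e-12)

    def test_matches_projection_oracle(self):
        rng = np.random.default_rng(8)
        n_ok = 0
        while n_ok < 100:
            pts = rng.normal(size=(4, 3)) * 2
            try:
                ours = dihedral(*pts)
            except GeometryError:
                continue
            oracle = dihedral_oracle(*pts)
            if abs(oracle) > 179.999:  # +/-180 wrap ambiguity
                assert abs(abs(ours) - abs(oracle)) < 1e-9
            else:
                assert ours == pytest.approx(oracle, abs=1e-9)
            n_ok += 1

    def test_degenerate_raises(self):
        with pytest.raises(GeometryError):
            dihedral([0, 0, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0])


class TestPlaceAtom:
    @given(st.floats(-179.0, 180.0), st.floats(60.0, 150.0),
           st.floats(0.9, 1.8))
    @settings(max_examples=50, deadline=None)
    def test_internal_coordinates_recovered(self, torsion, angle, bond):
        p1 = np.array([0.3, -1.2, 0.4])
        p2 = np.array([0.0, 0.0, 0.0])
        p3 = np.array([1.5, 0.1, -0.2])
        x = place_atom(p1, p2, p3, bond, angle, torsion)
        assert np.linalg.norm(x - p3) == pytest.approx(bond, abs=1e-9)
        v1 = p2 - p3
        v2 = x - p3
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        assert np.degrees(np.arccos(cosang)) == pytest.approx(angle, abs=1e-6)
        assert dihedral(p1, p2, p3, x) == pytest.approx(torsion, abs=1e-6)


class TestBuildHydrogens:
    def test_tetrahedral_completion_three_known(self):
        c = np.zeros(3)
        nb = 1.5 * np.array([[1.0, 0, 0],
                             [np.cos(np.radians(109.47)),
                              np.sin(np.radians(109.47)), 0]])
        # third neighbour completing a near-tetrahedral frame
        third = place_atom(nb[0], nb[1], c, 1.5, 109.47, 120.0)
        h = build_hydrogens(c, np.vstack([nb, third]), 1)[0]
        assert np.linalg.norm(h - c) == pytest.approx(1.09, abs=1e-9)
        subs = [nb[0], nb[1], third, h]
        for i in range(4):
            for j in range(i + 1, 4):
                u = subs[i] / np.linalg.norm(subs[i])
                v = subs[j] / np.linalg.norm(subs[j])
                ang = np.degrees(np.arccos(np.clip(np.dot(u, v), -1, 1)))
                assert abs(ang - 109.47) < 2.0

    def test_methylene_pair(self):
        from pisurvey.templates import deoxyribose_template
        s = deoxyribose_template()
        h = build_hydrogens(s["C2'"], [s["C1'"], s["C3'"]], 2)
        for x in h:
            assert np.linalg.norm(x - s["C2'"]) == pytest.approx(1.09, abs=1e-9)
        u = (h[0] - s["C2'"]) / 1.09
        v = (h[1] - s["C2'"]) / 1.09
        hch = np.degrees(np.arccos(np.clip(np.dot(u, v), -1, 1)))
        assert abs(hch - 109.47) < 2.0

    def test_hydroxyl_dihedral_self_consistency(self):
        from pisurvey.templates import deoxyribose_template
        s = deoxyribose_template()
        h = build_hydrogens(s["O5'"], [s["C5'"]], 1, reference_dihedral=60.0,
                            pre_reference=s["C4'"])[0]
        assert dihedral(s["C4'"], s["C5'"], s["O5'"], h) == \
            pytest.approx(60.0, abs=1e-6)
        assert np.linalg.norm(h - s["O5'"]) == pytest.approx(0.96, abs=1e-9)

    def test_unsupported_count_raises(self):
        with pytest.raises(GeometryError):
            build_hydrogens(np.zeros(3), np.eye(3) * 0, 4)


class TestRigidInvariance:
    def test_tilt_and_distance_invariant(self):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3)) + [0, 0, 3]
        t0 = tilt_angle(fit_ring_plane(a), fit_ring_plane(b))
        d0 = min_heavy_distance(a, b)
        for _ in range(20):
            rot = random_rotation(rng)
            shift = rng.normal(size=3) * 10
            a2, b2 = a @ rot.T + shift, b @ rot.T + shift
            assert tilt_angle(fit_ring_plane(a2), fit_ring_plane(b2)) == \
                pytest.approx(t0, abs=1e-6)
            assert min_heavy_distance(a2, b2) == pytest.approx(d0, abs=1e-9)
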