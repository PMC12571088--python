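"""Procrustes machinery: resampling, superimposition, sliding, distances."""

import copy

import numpy as np
import pytest

from morphx.io_formats import LandmarkConfiguration, ROLE_FIXED
from morphx.shape_core import (
    BendingEnergyModel,
    _curve_neighbors,
    _slide_once,
    centroid_size,
    procrustes_distance,
    resample_equidistant,
    superimpose,
)

from conftest import random_configs


def _rot(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

class TestResampleEquidistant:
    def test_straight_segment(self):
        out = resample_equidistant(np.array([[0.0, 0.0], [1.0, 0.0]]), 5)
        assert np.allclose(out[:, 0], [0, 0.25, 0.5, 0.75, 1])
        assert np.allclose(out[:, 1], 0)

    def test_parametrization_invariance(self):
        uneven = np.array([[0, 0], [0.03, 0], [0.07, 0], [0.9, 0], [1, 0]], dtype=float)
        out = resample_equidistant(uneven, 5)
        assert np.allclose(out[:, 0], [0, 0.25, 0.5, 0.75, 1])

    def test_arc_chords_equal(self):
        # dense semicircle: equal arc spacing implies equal chord lengths
        t = np.linspace(0, np.pi, 100)
        arc = np.column_stack([np.cos(t), np.sin(t)])
        out = resample_equidistant(arc, 10)
        chords = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert chords.max() / chords.min() - 1 < 0.01

    def test_zero_length_polyline_is_error(self):
        with pytest.raises(ValueError):
            resample_equidistant(np.zeros((3, 2)), 4)


# ---------------------------------------------------------------------------
# centroid size & distances
# ---------------------------------------------------------------------------

class TestCentroidSize:
    def test_unit_square_closed_form(self):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert np.isclose(centroid_size(sq), np.sqrt(2.0))

    def test_homogeneity(self, rng):
        pts = rng.normal(size=(12, 2))
        assert np.isclose(centroid_size(2 * pts), 2 * centroid_size(pts))

    def test_matches_literal_formula(self, rng):
        pts = rng.normal(size=(9, 2))
        direct = np.sqrt(((pts - pts.mean(0)) ** 2).sum())
        assert abs(centroid_size(pts) - direct) <= 1e-12

    def test_coincident_points_error(self):
        with pytest.raises(ValueError):
            centroid_size(np.ones((4, 2)))


class TestProcrustesDistance:
    def test_identical_is_zero_and_symmetric(self, rng):
        a, b = rng.normal(size=(2, 8, 2))
        assert procrustes_distance(a, a) == 0.0
        assert procrustes_distance(a, b) == procrustes_distance(b, a)

    def test_triangle_inequality_exhaustive(self, rng):
        X = rng.normal(size=(10, 8, 2))
        from itertools import permutations

        for i, j, k in permutations(range(10), 3):
            dij = procrustes_distance(X[i], X[j])
            assert dij <= procrustes_distance(X[i], X[k]) + procrustes_distance(X[k], X[j]) + 1e-12

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            procrustes_distance(np.zeros((3, 2)), np.zeros((4, 2)))


# ---------------------------------------------------------------------------
# superimposition
# ---------------------------------------------------------------------------

class TestSuperimpose:
    def test_rotated_translated_copy_aligns_exactly(self, rng):
        cfgs = random_configs(rng, n=2, p=10)
        cfgs[1].points = cfgs[0].points @ _rot(np.pi / 2) + np.array([3.0, -1.0])
        al = superimpose(cfgs, slide=False)
        assert np.abs(al.coordinates[0] - al.coordinates[1]).max() <= 1e-8
        assert procrustes_distance(al.coordinates[0], al.coordinates[1]) <= 1e-8

    def test_unit_centroid_size_contract(self, aligned_species):
        X = aligned_species.coordinates
        cent = X.mean(axis=1)
        assert np.abs(cent).max() <= 1e-9
        cs = np.sqrt((X**2).sum(axis=(1, 2)))
        assert np.abs(cs - 1).max() <= 1e-9

    def test_consensus_is_mean_of_aligned(self, aligned_species):
        assert np.abs(
            aligned_species.consensus - aligned_species.coordinates.mean(axis=0)
        ).max() <= 1e-9

    def test_invariance_to_input_transforms(self, species_bundle):
        configs = species_bundle.configurations[:12]
        moved = [copy.deepcopy(c) for c in configs]
        rng = np.random.default_rng(5)
        for c in moved[::2]:
            c.points = c.points @ _rot(rng.uniform(0, 2 * np.pi)) * rng.uniform(
                0.5, 3.0
            ) + rng.normal(0, 5, size=2)
        for slide in (False, True):
            a = superimpose(configs, slide=slide)
            b = superimpose(moved, slide=slide)
            assert np.abs(a.coordinates - b.coordinates).max() <= 1e-8

    def test_already_aligned_set_is_fixed_point(self, rng):
        cfgs = random_configs(rng, n=5, p=12)
        al = superimpose(cfgs, slide=False)
        re_cfgs = [
            LandmarkConfiguration(
                c.specimen_id, c.species_id, al.coordinates[i], c.roles, c.curves
            )
            for i, c in enumerate(cfgs)
        ]
        al2 = superimpose(re_cfgs, slide=False)
        assert al2.iterations_run == 1 and al2.converged

    def test_structure_mismatch_is_error(self, rng):
        cfgs = random_configs(rng, n=2, p=10) + random_configs(rng, n=1, p=11)
        with pytest.raises(ValueError, match="mismatch"):
            superimpose(cfgs, slide=False)

    def test_degenerate_configuration_is_error(self, rng):
        with pytest.raises(ValueError):
            LandmarkConfiguration(
                "x__upper__1__right__001",
                "x",
                np.ones((5, 2)) * np.nan,
                np.array([ROLE_FIXED] * 5, dtype=object),
                [],
            )

    def test_brute_force_rotation_grid_oracle(self, rng):
        """Plain GPA must match an SVD-free alternating angle-scan oracle."""
        cfgs = random_configs(rng, n=3, p=10)
        al = superimpose(cfgs, slide=False, tol=1e-12)

        # oracle: alternate (scan rotation angle per specimen, update mean)
        def center_unit(Y):
            Y = Y - Y.mean(0)
            return Y / np.sqrt((Y**2).sum())

        X = np.stack([center_unit(c.points.copy()) for c in cfgs])
        cons = center_unit(X.mean(0))

        def best_angle(Y, ref):
            lo, hi = 0.0, 2 * np.pi
            step = 0.01
            best = 0.0
            for _ in range(8):  # successive grid refinement, far below 1e-4 rad
                grid = np.arange(lo, hi, step)
                sse = [((Y @ _rot(t) - ref) ** 2).sum() for t in grid]
                best = grid[int(np.argmin(sse))]
                lo, hi, step = best - step, best + step, step / 10
            return best

        for _ in range(200):
            for i in range(3):
                X[i] = X[i] @ _rot(best_angle(X[i], cons))
            new = center_unit(X.mean(0))
            if np.sqrt(np.mean((new - cons) ** 2)) < 1e-12:
                cons = new
                break
            cons = new
        # canonical orientation, as the output contract specifies
        vals, vecs = np.linalg.eigh(cons.T @ cons)
        v1 = vecs[:, -1]
        proj = cons @ v1
        skew = np.mean(proj**3)
        ref = skew if abs(skew) > 1e-12 else proj[np.argmax(np.abs(proj))]
        if ref < 0:
            v1 = -v1
        R = np.column_stack([v1, [-v1[1], v1[0]]])
        X = X @ R
        # stored consensus is the (unnormalized) arithmetic mean of the output
        assert np.abs(X.mean(0) - al.consensus).max() <= 1e-5
        assert np.abs(X - al.coordinates).max() <= 1e-5


# ---------------------------------------------------------------------------
# bending energy & sliding
# ---------------------------------------------------------------------------

class TestBendingEnergy:
    def test_affine_transform_has_zero_energy(self, rng):
        ref = rng.normal(size=(20, 2))
        bem = BendingEnergyModel(ref)
        A = rng.normal(size=(2, 2))
        affine = ref @ A + rng.normal(size=2)
        assert abs(bem.energy(affine)) <= 1e-8

    def test_matrix_symmetric_psd(self, rng):
        bem = BendingEnergyModel(rng.normal(size=(15, 2)))
        Le = bem.bending_matrix
        assert np.abs(Le - Le.T).max() <= 1e-10
        assert np.linalg.eigvalsh(Le).min() >= -1e-8


class TestSliding:
    def test_fixed_landmarks_never_move(self, species_bundle):
        cfg = species_bundle.configurations[0]
        other = species_bundle.configurations[1]
        X = cfg.points - cfg.points.mean(0)
        X = X / np.sqrt((X**2).sum())
        ref = other.points - other.points.mean(0)
        ref = ref / np.sqrt((ref**2).sum())  # a genuinely different shape
        semis, prevs, nexts = _curve_neighbors(cfg.curves, len(X))
        Le = BendingEnergyModel(ref).bending_matrix
        out = _slide_once(X.copy(), ref, Le, semis, prevs, nexts)
        fixed = np.flatnonzero(cfg.fixed_mask)
        assert np.array_equal(out[fixed], X[fixed])
        assert not np.allclose(out[semis], X[semis])

    def test_sliding_reduces_total_bending_energy(self, species_bundle):
        configs = species_bundle.configurations[:15]
        slid = superimpose(configs, slide=True)
        plain = superimpose(configs, slide=False)
        be_slid = sum(
            BendingEnergyModel(slid.consensus).energy(x) for x in slid.coordinates
        )
        be_plain = sum(
            BendingEnergyModel(plain.consensus).energy(x) for x in plain.coordinates
        )
        assert be_slid <= be_plain
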