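"""Texture matrices against hand examples and brute-force oracles."""

import numpy as np
import pytest

from radstab import (
    build_glcm,
    build_glrlm,
    build_glszm,
    build_ngtdm,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
    discretize_fbn,
)
from radstab.texture import DegenerateMatrixError, DIRECTIONS_3D
from conftest import make_disc, make_roi
import oracles


def random_disc(rng, shape=(4, 4, 4), n_levels=4, mask_prob=0.8):
    levels = rng.integers(1, n_levels + 1, shape)
    mask = rng.random(shape) < mask_prob
    if not mask.any():
        mask[0, 0, 0] = True
    grid = np.where(mask, levels, 0)
    return make_disc(grid, n_levels=n_levels), grid


class TestGLCM:
    def test_1d_hand_example(self):
        disc = make_disc(np.array([1, 1, 2]))
        p = build_glcm(disc).cells
        assert p[0, 0] == pytest.approx(0.5)
        assert p[0, 1] == pytest.approx(0.25)
        assert p[1, 0] == pytest.approx(0.25)

    def test_constant_roi_single_cell(self):
        disc = make_disc(np.ones((3, 3, 3), dtype=int))
        p = build_glcm(disc).cells
        assert p[0, 0] == pytest.approx(1.0)
        assert p.sum() == pytest.approx(1.0)

    def test_degenerate_single_voxel(self):
        disc = make_disc(np.array([1]))
        with pytest.raises(DegenerateMatrixError):
            build_glcm(disc)

    def test_matches_brute_force(self, rng):
        for _ in range(20):
            disc, grid = random_disc(rng)
            p = build_glcm(disc).cells
            ref = oracles.glcm_brute(grid)
            np.testing.assert_allclose(p[: ref.shape[0], : ref.shape[1]], ref, atol=1e-12)

    def test_symmetry_and_unit_mass(self, rng):
        for _ in range(10):
            disc, _ = random_disc(rng, shape=(5, 4, 3), n_levels=6)
            p = build_glcm(disc).cells
            assert p.sum() == pytest.approx(1.0)
            np.testing.assert_allclose(p, p.T)

    def test_feature_hand_values(self):
        disc = make_disc(np.array([1, 1, 2]))
        feats = glcm_features(build_glcm(disc))
        # P = [[0.5, 0.25], [0.25, 0]]
        assert feats["Inverse difference"] == pytest.approx(0.75)
        assert feats["Entropy"] == pytest.approx(1.5)  # -0.5 log 0.5 - 2*0.25 log 0.25
        assert len(feats) == 40

    def test_two_equiprobable_cells_entropy_one_bit(self):
        # Levels 1,2 alternating along x: pairs (1,2) and (2,1) only.
        disc = make_disc(np.array([1, 2, 1, 2]))
        feats = glcm_features(build_glcm(disc))
        # Diagonal pairs absent at distance 1: P(1,2)=P(2,1)=0.5.
        assert feats["Entropy"] == pytest.approx(1.0)

    def test_single_cell_matrix(self):
        disc = make_disc(np.ones(4, dtype=int))
        feats = glcm_features(build_glcm(disc))
        assert feats["Entropy"] == 0.0
        assert feats["Inverse diff. moment"] == pytest.approx(1.0)


class TestGLRLM:
    def test_1d_single_direction(self):
        disc = make_disc(np.array([1, 1, 2]))
        m = build_glrlm(disc, directions=[(1, 0, 0)])
        feats = glrlm_features(m)
        assert feats["Short-run emphasis"] == pytest.approx(0.625)
        assert feats["Run percentage"] == pytest.approx(2.0 / 3.0)
        assert len(feats) == 17

    def test_constant_1d_run(self):
        n = 5
        disc = make_disc(np.ones(n, dtype=int))
        feats = glrlm_features(build_glrlm(disc, directions=[(1, 0, 0)]))
        assert feats["Long-run emphasis"] == pytest.approx(n**2)
        assert feats["Short-run emphasis"] == pytest.approx(1.0 / n**2)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            disc, grid = random_disc(rng)
            mats = build_glrlm(disc).cells
            for mat, d in zip(mats, DIRECTIONS_3D):
                ref_runs = oracles.runs_brute(grid, d)
                ref = np.zeros_like(mat)
                for lev, length in ref_runs:
                    ref[lev - 1, length - 1] += 1
                np.testing.assert_array_equal(mat, ref)

    def test_run_mass_equals_voxels_per_direction(self, rng):
        disc, grid = random_disc(rng, shape=(5, 5, 4))
        n_vox = int((grid > 0).sum())
        for mat in build_glrlm(disc).cells:
            lengths = np.arange(1, mat.shape[1] + 1)
            assert (mat * lengths).sum() == n_vox


class TestGLSZM:
    def test_1d_hand_example(self):
        disc = make_disc(np.array([1, 1, 2]))
        feats = glszm_features(build_glszm(disc))
        assert feats["Small zone emphasis"] == pytest.approx(0.625)
        assert len(feats) == 12

    def test_constant_roi_one_zone(self):
        disc = make_disc(np.ones((3, 3, 3), dtype=int))
        mat = build_glszm(disc).cells
        assert mat.sum() == 1
        assert mat[0, 26] == 1  # one zone of size 27

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            disc, grid = random_disc(rng)
            mat = build_glszm(disc).cells
            ref = np.zeros_like(mat)
            for lev, size in oracles.zones_brute(grid):
                ref[lev - 1, size - 1] += 1
            np.testing.assert_array_equal(mat, ref)


class TestNGTDM:
    def test_1d_hand_example(self):
        disc = make_disc(np.array([1, 1, 2]))
        m = build_ngtdm(disc)
        s = m.cells["s"]
        assert s[0] == pytest.approx(0.5)
        assert s[1] == pytest.approx(1.0)
        feats = ngtdm_features(m)
        assert feats["Coarseness"] == pytest.approx(1.5)
        assert len(feats) == 11

    def test_constant_roi_epsilon_rule(self):
        disc = make_disc(np.ones((3, 3, 3), dtype=int))
        feats = ngtdm_features(build_ngtdm(disc))
        assert feats["Coarseness"] == pytest.approx(1e12)

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            disc, grid = random_disc(rng)
            m = build_ngtdm(disc)
            s_ref, n_ref = oracles.ngtdm_brute(grid)
            ng = len(s_ref)
            np.testing.assert_allclose(m.cells["s"][:ng], s_ref, atol=1e-10)
            np.testing.assert_allclose(m.cells["n"][:ng], n_ref)


class TestAffineInvariance:
    def test_texture_features_invariant_under_affine_gain(self, rng):
        """With FBN discretization, texture panels ignore affine rescaling."""
        vals = rng.normal(100, 15, (5, 5, 5))
        roi_a = make_roi(vals)
        roi_b = make_roi(vals * 1.8 + 40.0)
        da = discretize_fbn(roi_a, 8)
        db = discretize_fbn(roi_b, 8)
        for build, feat in (
            (build_glcm, glcm_features),
            (build_glrlm, glrlm_features),
            (build_glszm, glszm_features),
            (build_ngtdm, ngtdm_features),
        ):
            fa, fb = feat(build(da)), feat(build(db))
            for name in fa:
                np.testing.assert_allclose(fa[name], fb[name], rtol=1e-12, err_msg=name)
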