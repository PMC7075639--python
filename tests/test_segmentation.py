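"""Actin-guided segmentation: directors, γ scoring, z-line fraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zlinekit.angles import canonicalize
from zlinekit.segmentation import (compute_director_grid, gamma_score,
                                   segment_offtarget, zline_fraction)
from zlinekit.types import BinarySkeleton, OrientationField, SegmentationResult


def make_field(theta_value, shape=(32, 32), valid=None):
    theta = np.full(shape, float(theta_value))
    if valid is None:
        valid = np.ones(shape, dtype=bool)
    return OrientationField(theta=np.where(valid, theta, np.nan), valid=valid)


class TestDirectorGrid:
    def test_uniform_zero_angles(self):
        grid = compute_director_grid(make_field(0.0), grid_um=5.0, resolution=6.0)
        assert grid.grid_px == 30
        assert grid.populated.all()
        assert np.allclose(grid.theta[grid.populated], 0.0)
        assert np.allclose(grid.coherence[grid.populated], 1.0)

    def test_balanced_orthogonal_angles_degenerate(self):
        theta = np.zeros((30, 30))
        theta[:15] = 0.0
        theta[15:] = np.pi / 2
        fld = OrientationField(theta=theta, valid=np.ones((30, 30), bool))
        grid = compute_director_grid(fld, grid_um=5.0, resolution=6.0)
        assert grid.populated[0, 0]
        assert grid.degenerate[0, 0]
        assert not grid.usable[0, 0]

    def test_angles_concentrated_at_pi_over_4(self):
        rng = np.random.default_rng(11)
        theta = canonicalize(np.pi / 4 + rng.normal(0, 0.05, (30, 30)))
        fld = OrientationField(theta=theta, valid=np.ones((30, 30), bool))
        grid = compute_director_grid(fld, grid_um=5.0, resolution=6.0)
        # oracle: eigen-decomposition of the directly averaged tensor
        c2, s2 = np.cos(2 * theta).mean(), np.sin(2 * theta).mean()
        expected = 0.5 * np.arctan2(s2, c2)
        assert grid.theta[0, 0] == pytest.approx(expected, abs=1e-9)
        assert abs(grid.theta[0, 0] - np.pi / 4) < 0.02

    def test_unpopulated_tiles_flagged(self):
        valid = np.zeros((60, 60), dtype=bool)
        valid[:30, :30] = True
        fld = make_field(1.0, (60, 60), valid=valid)
        grid = compute_director_grid(fld, grid_um=5.0, resolution=6.0)
        assert grid.populated[0, 0]
        assert not grid.populated[1, 1]

    def test_oversized_grid_warns_single_tile(self):
        with pytest.warns(UserWarning, match="single grid"):
            grid = compute_director_grid(make_field(0.3, (20, 20)), grid_um=50.0,
                                         resolution=6.0)
        assert grid.theta.shape == (1, 1)


class TestGammaScore:
    @pytest.mark.parametrize("a, b, expected", [
        (0.0, np.pi / 2, 0.0),            # perpendicular
        (1.0, 1.0, 1.0),                  # parallel
        (0.0, np.pi / 4, np.cos(np.pi / 4)),
    ])
    def test_closed_forms(self, a, b, expected):
        assert gamma_score(a, b) == pytest.approx(expected)

    def test_45_degrees_is_offtarget_at_default_threshold(self):
        assert gamma_score(0.0, np.pi / 4) >= 0.7

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(0, np.pi), st.floats(0, np.pi))
    def test_symmetric_nematic_and_bounded(self, a, b):
        g = gamma_score(a, b)
        assert 0.0 <= g <= 1.0
        assert g == pytest.approx(gamma_score(b, a))
        assert g == pytest.approx(gamma_score(canonicalize(a + np.pi), b))


def build_case(skel_theta_map, actin_theta=0.0, shape=(32, 32)):
    """Skeleton + own-orientation field from {coord: theta}, uniform actin."""
    mask = np.zeros(shape, dtype=bool)
    theta = np.full(shape, np.nan)
    for (r, c), th in skel_theta_map.items():
        mask[r, c] = True
        theta[r, c] = th
    skeleton = BinarySkeleton(mask=mask, resolution=6.0)
    skel_field = OrientationField(theta=theta, valid=~np.isnan(theta))
    grid = compute_director_grid(make_field(actin_theta, shape), 5.0, 6.0)
    return skeleton, skel_field, grid


class TestSegmentOfftarget:
    def test_perpendicular_striations_all_kept(self):
        pixels = {(r, c): np.pi / 2 for c in (5, 10, 15) for r in range(4, 12)}
        skeleton, fld, grid = build_case(pixels, actin_theta=0.0)
        result = segment_offtarget(skeleton, fld, grid)
        assert result.n_z == result.n_alpha == len(pixels)
        assert zline_fraction(result) == 1.0

    def test_parallel_segments_all_removed(self):
        pixels = {(r, c): 0.0 for r in (5, 10) for c in range(4, 20)}
        skeleton, fld, grid = build_case(pixels, actin_theta=0.0)
        result = segment_offtarget(skeleton, fld, grid)
        assert result.n_z == 0
        assert zline_fraction(result) == 0.0

    def test_mixed_counts(self):
        pixels = {(r, c): np.pi / 2 for c in range(6) for r in range(5, 15)}   # 60 ⟂
        pixels.update({(20, c): 0.0 for c in range(2, 22)})                     # 20 ∥
        pixels.update({(25, c): 0.0 for c in range(2, 22)})                     # 20 ∥
        skeleton, fld, grid = build_case(pixels, actin_theta=0.0)
        result = segment_offtarget(skeleton, fld, grid)
        assert result.n_alpha == 100
        assert result.n_z == 60
        assert int(result.offtarget_mask.sum()) == 40
        assert zline_fraction(result) == pytest.approx(0.6)

    def test_boundary_gamma_exactly_at_threshold_is_offtarget(self):
        theta = np.arccos(0.7)  # γ against actin at 0 is exactly 0.7
        skeleton, fld, grid = build_case({(8, 8): theta}, actin_theta=0.0)
        result = segment_offtarget(skeleton, fld, grid, gamma_threshold=0.7)
        assert result.n_z == 0 and result.n_alpha == 1

    def test_partition_and_idempotence(self, mixed_phantom_result):
        seg = mixed_phantom_result.artifacts["segmentation"]
        union = seg.zline_skeleton.mask | seg.offtarget_mask | seg.unassigned_mask
        assert np.array_equal(union, mixed_phantom_result.artifacts["skeleton"].mask)
        assert not (seg.zline_skeleton.mask & seg.offtarget_mask).any()
        # re-running on the z-line skeleton removes nothing further
        fld = mixed_phantom_result.artifacts["orientation"]
        grid = mixed_phantom_result.artifacts["director_grid"]
        again = segment_offtarget(seg.zline_skeleton, fld, grid)
        assert again.n_z == again.n_alpha

    def test_monotone_in_threshold(self, mixed_phantom_result):
        skel = mixed_phantom_result.artifacts["skeleton"]
        fld = mixed_phantom_result.artifacts["orientation"]
        grid = mixed_phantom_result.artifacts["director_grid"]
        n_z = [segment_offtarget(skel, fld, grid, t).n_z
               for t in (0.0, 0.2, 0.5, 0.7, 0.9, 1.0)]
        assert n_z == sorted(n_z)

    def test_director_flip_by_pi_invariance(self):
        rng = np.random.default_rng(5)
        pixels = {(r, c): rng.uniform(0, np.pi)
                  for r in range(4, 28, 3) for c in range(4, 28, 3)}
        skeleton, fld, _ = build_case(pixels)
        base = make_field(0.4)
        flipped = OrientationField(theta=canonicalize(base.theta + np.pi),
                                   valid=base.valid)
        g1 = compute_director_grid(base, 5.0, 6.0)
        g2 = compute_director_grid(flipped, 5.0, 6.0)
        r1 = segment_offtarget(skeleton, fld, g1)
        r2 = segment_offtarget(skeleton, fld, g2)
        assert np.array_equal(r1.zline_skeleton.mask, r2.zline_skeleton.mask)
        assert np.array_equal(r1.offtarget_mask, r2.offtarget_mask)

    def test_shape_mismatch_rejected(self):
        skeleton, fld, grid = build_case({(5, 5): 0.1})
        bad = OrientationField(theta=np.zeros((16, 16)), valid=np.ones((16, 16), bool))
        with pytest.raises(ValueError):
            segment_offtarget(skeleton, bad, grid)


def brute_force_segment(skeleton, skel_field, actin_field, grid_px, threshold):
    """Independent per-pixel reclassification with per-grid direct summation."""
    h, w = skeleton.shape
    zline = np.zeros((h, w), dtype=bool)
    off = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if not skeleton.mask[r, c]:
                continue
            i, j = r // grid_px, c // grid_px
            angles = []
            for rr in range(i * grid_px, min((i + 1) * grid_px, h)):
                for cc in range(j * grid_px, min((j + 1) * grid_px, w)):
                    if actin_field.valid[rr, cc]:
                        angles.append(actin_field.theta[rr, cc])
            if not angles or not skel_field.valid[r, c]:
                continue
            M = np.zeros((2, 2))
            for th in angles:
                v = np.array([np.cos(th), np.sin(th)])
                M += 2 * np.outer(v, v) - np.eye(2)
            M /= len(angles)
            evals, evecs = np.linalg.eigh(M)
            if evals[-1] < 1e-9:
                continue
            director = np.arctan2(evecs[1, -1], evecs[0, -1]) % np.pi
            g = abs(np.cos(director - skel_field.theta[r, c]))
            if g >= threshold:
                off[r, c] = True
            else:
                zline[r, c] = True
    return zline, off


def test_brute_force_oracle_equivalence():
    """On a small image, vectorized segmentation matches exhaustive per-pixel
    reclassification with directly summed grid tensors, pixel for pixel."""
    rng = np.random.default_rng(123)
    shape = (64, 64)
    mask = rng.random(shape) < 0.15
    skel_theta = np.where(mask, rng.uniform(0, np.pi, shape), np.nan)
    skeleton = BinarySkeleton(mask=mask, resolution=6.0)
    skel_field = OrientationField(theta=skel_theta, valid=mask)
    actin_valid = rng.random(shape) < 0.8
    actin_theta = np.where(actin_valid, rng.uniform(0, np.pi, shape), np.nan)
    actin_field = OrientationField(theta=actin_theta, valid=actin_valid)

    grid = compute_director_grid(actin_field, grid_um=5.0, resolution=6.0)
    result = segment_offtarget(skeleton, skel_field, grid, 0.7)
    z_ref, off_ref = brute_force_segment(skeleton, skel_field, actin_field,
                                         grid.grid_px, 0.7)
    assert np.array_equal(result.zline_skeleton.mask, z_ref)
    assert np.array_equal(result.offtarget_mask, off_ref)


class TestZlineFraction:
    def test_ratio(self):
        skel = BinarySkeleton(mask=np.zeros((16, 16), bool))
        res = SegmentationResult(zline_skeleton=skel,
                                 offtarget_mask=np.zeros((16, 16), bool),
                                 unassigned_mask=np.zeros((16, 16), bool),
                                 gamma_map=np.full((16, 16), np.nan),
                                 n_alpha=100, n_z=60)
        assert zline_fraction(res) == pytest.approx(0.6)

    def test_empty_is_missing_not_zero(self):
        skel = BinarySkeleton(mask=np.zeros((16, 16), bool))
        res = SegmentationResult(zline_skeleton=skel,
                                 offtarget_mask=np.zeros((16, 16), bool),
                                 unassigned_mask=np.zeros((16, 16), bool),
                                 gamma_map=np.full((16, 16), np.nan),
                                 n_alpha=0, n_z=0)
        with pytest.warns(UserWarning):
            assert np.isnan(zline_fraction(res))
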