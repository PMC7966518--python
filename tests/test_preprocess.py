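"""Preprocessing: landmarks, standardization, mask conditioning, tissue medians."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from bhtyper import preprocess
from bhtyper.preprocess import (
    DegenerateLandmarkError,
    EmptyTissueError,
    PreprocessConfig,
    label_and_filter_lesions,
    learn_landmarks,
    resample_and_binarize_mask,
    standardize_intensities,
    tissue_medians,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mask_threshold": 0.0},
            {"mask_threshold": 1.0},
            {"min_lesion_voxels": -1},
            {"landmark_percentiles": (10.0, 10.0, 90.0)},
            {"landmark_percentiles": (0.0, 50.0)},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PreprocessConfig(**kwargs)


class TestLandmarks:
    def test_cohort_of_one_equals_own_percentiles(self, rng):
        vol = rng.uniform(1, 100, size=(8, 8, 8))
        pcts = (25.0, 50.0, 75.0)
        lm = learn_landmarks([vol], pcts)
        np.testing.assert_allclose(lm, np.percentile(vol, pcts))

    def test_duplicated_volume_changes_nothing(self, rng):
        vol = rng.uniform(1, 100, size=(8, 8, 8))
        np.testing.assert_allclose(learn_landmarks([vol]), learn_landmarks([vol, vol]))

    def test_two_volume_landmark_is_mean_of_percentiles(self):
        a = np.arange(1.0, 101.0).reshape(10, 10, 1)
        b = np.arange(2.0, 201.0, 2.0).reshape(10, 10, 1)
        lm = learn_landmarks([a, b], (50.0,))
        expected = (np.percentile(a, 50) + np.percentile(b, 50)) / 2
        assert lm[0] == pytest.approx(expected)

    def test_constant_volume_degenerate(self):
        with pytest.raises(DegenerateLandmarkError):
            learn_landmarks([np.full((5, 5, 5), 7.0)])

    def test_background_zeros_ignored(self, rng):
        vol = np.zeros((10, 10, 10))
        vol[:3] = rng.uniform(5, 10, size=(3, 10, 10))
        lm = learn_landmarks([vol], (50.0,))
        assert lm[0] == pytest.approx(np.percentile(vol[:3], 50))


class TestStandardization:
    def test_identity_when_landmarks_match(self, rng):
        vol = rng.uniform(1, 100, size=(8, 8, 8))
        own = np.percentile(vol, preprocess.DEFAULT_PERCENTILES)
        out = standardize_intensities(vol, own)
        np.testing.assert_allclose(out, vol, rtol=1e-12)

    def test_two_landmark_linear_interpolation(self, rng):
        vol = rng.uniform(0.5, 10.0, size=(12, 12, 12))
        pcts = (25.0, 75.0)
        out = standardize_intensities(vol, np.array([100.0, 300.0]), pcts)
        p25, p50, p75 = np.percentile(vol, (25, 50, 75))
        voxel = np.argwhere(np.isclose(vol, p50))
        if len(voxel):
            i, j, k = voxel[0]
            expected = 100 + (p50 - p25) / (p75 - p25) * 200
            assert out[i, j, k] == pytest.approx(expected)
        # landmark pinning is exact
        mapped = np.interp([p25, p75], [p25, p75], [100.0, 300.0])
        np.testing.assert_allclose(mapped, [100.0, 300.0])

    @given(
        vol=hnp.arrays(
            np.float64,
            (6, 6, 6),
            elements=st.floats(0.1, 1e4, allow_nan=False),
        )
    )
    def test_rank_order_preserved(self, vol):
        """Standardization is monotone: voxel rank order survives the mapping."""
        own = np.percentile(vol[vol > 0], preprocess.DEFAULT_PERCENTILES)
        if (np.diff(own) <= 0).any():
            return  # quantized input; standardization refuses such volumes
        out = standardize_intensities(vol, own + np.linspace(0, 50, own.size))
        order_in = np.argsort(vol.ravel(), kind="stable")
        order_out = np.argsort(out.ravel(), kind="stable")
        np.testing.assert_array_equal(order_in, order_out)

    def test_non_monotone_standard_landmarks_rejected(self, rng):
        vol = rng.uniform(1, 10, size=(6, 6, 6))
        with pytest.raises(ValueError, match="increasing"):
            standardize_intensities(vol, np.array([5.0, 4.0, 6.0]), (25.0, 50.0, 75.0))

    def test_tail_extrapolation_is_linear(self):
        vol = np.linspace(1, 100, 1000).reshape(10, 10, 10)
        pcts = (40.0, 60.0)
        own = np.percentile(vol, pcts)
        std = own * 2.0  # doubling map: slope 2 everywhere
        out = standardize_intensities(vol, std, pcts)
        np.testing.assert_allclose(out, vol * 2.0, rtol=1e-9)


def _trilinear_oracle(mask, src_affine, tgt_shape, tgt_affine):
    """Brute-force per-voxel trilinear evaluation."""
    inv = np.linalg.inv(src_affine)
    out = np.zeros(tgt_shape)
    for idx in np.ndindex(tgt_shape):
        p = inv @ tgt_affine @ np.array([*idx, 1.0])
        x, y, z = p[:3]
        acc = 0.0
        x0, y0, z0 = int(np.floor(x)), int(np.floor(y)), int(np.floor(z))
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    xi, yi, zi = x0 + dx, y0 + dy, z0 + dz
                    w = (
                        (1 - abs(x - xi)) * (1 - abs(y - yi)) * (1 - abs(z - zi))
                    )
                    if w <= 0:
                        continue
                    if 0 <= xi < mask.shape[0] and 0 <= yi < mask.shape[1] and 0 <= zi < mask.shape[2]:
                        acc += w * mask[xi, yi, zi]
        out[idx] = acc
    return out


class TestMaskResampling:
    def test_identity_grid_returns_input(self, rng):
        mask = (rng.random((6, 6, 6)) > 0.5).astype(float)
        eye = np.eye(4)
        out = resample_and_binarize_mask(mask, eye, mask.shape, eye)
        np.testing.assert_array_equal(out, mask.astype(np.uint8))

    def test_value_exactly_half_is_kept(self):
        mask = np.zeros((4, 4, 4))
        mask[1, 1, 1] = 0.5
        eye = np.eye(4)
        out = resample_and_binarize_mask(mask, eye, mask.shape, eye)
        assert out[1, 1, 1] == 1

    def test_upsampled_point_mask_does_not_enlarge(self):
        mask = np.zeros((7, 7, 7))
        mask[3, 3, 3] = 1.0
        src_affine = np.eye(4)
        tgt_affine = np.diag([0.5, 0.5, 0.5, 1.0])
        out = resample_and_binarize_mask(mask, src_affine, (14, 14, 14), tgt_affine)
        # voxels with trilinear value >= 0.5 lie within half a source voxel
        assert 1 <= out.sum() <= 8

    def test_matches_brute_force_trilinear(self, rng):
        mask = rng.random((5, 6, 4))
        src_affine = np.diag([1.0, 1.2, 0.9, 1.0])
        tgt_affine = np.diag([0.7, 0.8, 1.1, 1.0])
        tgt_shape = (7, 8, 3)
        out = resample_and_binarize_mask(mask, src_affine, tgt_shape, tgt_affine)
        oracle = (_trilinear_oracle(mask, src_affine, tgt_shape, tgt_affine) >= 0.5)
        np.testing.assert_array_equal(out.astype(bool), oracle)

    def test_bad_affine_rejected(self):
        with pytest.raises(preprocess.GeometryError):
            resample_and_binarize_mask(np.zeros((3, 3, 3)), np.eye(3), (3, 3, 3), np.eye(4))


def _flood_fill_sizes(binary):
    """Independent 26-connectivity component sizes via BFS."""
    binary = binary.astype(bool)
    seen = np.zeros_like(binary)
    sizes = []
    offsets = [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ]
    for start in zip(*np.nonzero(binary & ~seen)):
        if seen[start]:
            continue
        stack, count = [start], 0
        seen[start] = True
        while stack:
            x, y, z = stack.pop()
            count += 1
            for dx, dy, dz in offsets:
                p = (x + dx, y + dy, z + dz)
                if all(0 <= pi < si for pi, si in zip(p, binary.shape)):
                    if binary[p] and not seen[p]:
                        seen[p] = True
                        stack.append(p)
        sizes.append(count)
    return sorted(sizes)


class TestLesionFilter:
    def test_strict_size_threshold(self):
        grid = np.zeros((30, 30, 3), dtype=np.int32)
        # three disjoint slabs of 99, 100 and 101 voxels
        grid[0:9, 0:11, 0] = 1  # 99
        grid[12:22, 0:10, 0] = 2  # 100
        grid[0:9, 15:26, 0][:, :, ] = 3
        assert (grid == 3).sum() == 99
        grid[9, 15:17, 0] = 3  # 101
        out = label_and_filter_lesions(grid, 100)
        assert out.max() == 1
        assert (out == 1).sum() == 101

    def test_empty_mask_empty_labels(self):
        out = label_and_filter_lesions(np.zeros((5, 5, 5), dtype=np.int32), 100)
        assert out.max() == 0

    def test_relabelling_preserves_original_order(self):
        grid = np.zeros((12, 4, 4), dtype=np.int32)
        grid[0:2] = 5
        grid[4:6] = 2
        grid[8:10] = 9
        out = label_and_filter_lesions(grid, 10)
        assert set(np.unique(out)) == {0, 1, 2, 3}
        assert (out[grid == 2] == 1).all()
        assert (out[grid == 5] == 2).all()
        assert (out[grid == 9] == 3).all()

    def test_binary_blobs_match_flood_fill_oracle(self, rng):
        binary = rng.random((12, 12, 12)) > 0.72
        out = label_and_filter_lesions(binary.astype(np.int32), 5)
        surviving = sorted(
            int((out == lab).sum()) for lab in range(1, out.max() + 1)
        )
        oracle = [s for s in _flood_fill_sizes(binary) if s > 5]
        assert surviving == oracle


def _toy_maps(vol_len, wm_idx, gm_idx, csf_idx):
    shape = (vol_len, 1, 1)
    maps = {t: np.zeros(shape) for t in ("wm", "gm", "csf")}
    maps["wm"][wm_idx, 0, 0] = 1.0
    maps["gm"][gm_idx, 0, 0] = 1.0
    maps["csf"][csf_idx, 0, 0] = 1.0
    return maps


class TestTissueMedians:
    def test_odd_count_median(self):
        vol = np.array([1.0, 2.0, 3.0, 10.0, 20.0]).reshape(5, 1, 1)
        maps = _toy_maps(5, [0, 1, 2], [3], [4])
        tm = tissue_medians(vol, maps)
        assert tm.wm_median == 2.0
        assert tm.gm_median == 10.0
        assert tm.csf_median == 20.0

    def test_empty_tissue_class_named_in_error(self):
        vol = np.ones((3, 1, 1))
        maps = _toy_maps(3, [0, 1], [2], [])
        with pytest.raises(EmptyTissueError, match="csf"):
            tissue_medians(vol, maps)

    def test_lesion_exclusion_forces_even_median(self):
        vol = np.array([1.0, 2.0, 3.0, 4.0, 9.0, 9.0]).reshape(6, 1, 1)
        maps = _toy_maps(6, [0, 1, 2, 3], [4], [5])
        lesion = np.zeros((6, 1, 1), dtype=int)
        lesion[3, 0, 0] = 1  # removes value 4 from WM
        tm = tissue_medians(vol, maps, lesion)
        assert tm.wm_median == 2.0  # median of {1, 2, 3}
        assert sorted(tm.wm_voxel_intensities) == [1.0, 2.0, 3.0]

    def test_even_count_median_is_mean_of_middle_two(self, subject):
        vol = subject.volumes["fspgr"]
        tm = tissue_medians(vol, subject.tissue_maps, subject.lesion_labels)
        member = vol[(subject.tissue_maps["wm"] > 0.5) & (subject.lesion_labels == 0)]
        srt = np.sort(member)
        n = len(srt)
        oracle = srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2
        assert tm.wm_median == pytest.approx(float(oracle))
        # no lesion voxel contributes to the retained WM multiset
        assert len(tm.wm_voxel_intensities) == n
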