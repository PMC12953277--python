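import math

import numpy as np
import pytest

from fractalct.fractal import (
    BoxCountCurve,
    FDConfig,
    box_size_schedule,
    boxcount_curve,
    compute_fd,
    count_boxes,
    fit_fractal_dimension,
    local_fd_map,
)
from fractalct.preprocess import CTVolume, SegmentationMask, save_mask, save_volume
from fractalct.synthetic import make_phantom

MENGER_DIM = math.log(20) / math.log(3)


def naive_count_boxes(data: np.ndarray, s: int) -> int:
    """Independent oracle: explicit triple loop over the box grid."""
    idx = np.argwhere(data)
    lo = idx.min(axis=0)
    hi = idx.max(axis=0) + 1
    sub = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    count = 0
    for i in range(0, sub.shape[0], s):
        for j in range(0, sub.shape[1], s):
            for k in range(0, sub.shape[2], s):
                if sub[i : i + s, j : j + s, k : k + s].any():
                    count += 1
    return count


class TestSchedule:
    def test_pow2_cube(self):
        assert box_size_schedule((64, 64, 64), "pow2") == [1, 2, 4, 8, 16, 32]

    def test_ternary_cube(self):
        assert box_size_schedule((27, 27, 27), "ternary") == [1, 3, 9, 27]

    def test_degenerate_shape_raises(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            box_size_schedule((2, 2, 2), "pow2")

    def test_custom(self):
        assert box_size_schedule((50, 50, 50), "custom", custom=[5, 1, 10]) == [1, 5, 10]

    def test_unknown_scheme(self):
        with pytest.raises(ValueError):
            box_size_schedule((64, 64, 64), "golden")


class TestCountBoxes:
    def test_menger2_s3(self, menger2):
        assert count_boxes(menger2, 3) == 20

    def test_solid_cube_exact_tiling(self):
        cube = make_phantom("cube", 8)
        assert count_boxes(cube, 2) == 64

    @pytest.mark.parametrize("s", [1, 2, 5, 100])
    def test_single_voxel(self, s):
        m = np.zeros((7, 7, 7), dtype=np.uint8)
        m[3, 1, 5] = 1
        assert count_boxes(SegmentationMask(data=m), s) == 1

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="foreground"):
            count_boxes(SegmentationMask(data=np.zeros((4, 4, 4), dtype=np.uint8)), 2)

    def test_matches_naive_oracle_on_random_masks(self, rng):
        for _ in range(20):
            data = rng.random((20, 20, 20)) < rng.uniform(0.02, 0.6)
            if not data.any():
                continue
            for s in (1, 2, 3, 4, 5):
                assert count_boxes(data, s) == naive_count_boxes(data, s)


class TestCurve:
    def test_menger3_ternary_counts(self):
        curve = boxcount_curve(make_phantom("menger", 3), [1, 3, 9, 27])
        assert list(curve.sizes) == [1, 3, 9, 27]
        assert list(curve.counts) == [8000, 400, 20, 1]

    def test_cube_counts_exact(self, cube64):
        curve = boxcount_curve(cube64, [1, 2, 4, 8, 16, 32])
        np.testing.assert_array_equal(curve.counts, [(64 // s) ** 3 for s in curve.sizes])

    def test_counts_non_increasing(self, rng):
        for _ in range(10):
            data = rng.random((24, 24, 24)) < 0.3
            data[0, 0, 0] = True
            curve = boxcount_curve(data, [1, 2, 3, 4, 6, 8, 12])
            assert np.all(np.diff(curve.counts) <= 0)

    def test_curve_validation(self):
        with pytest.raises(ValueError):
            BoxCountCurve(sizes=[2, 1], counts=[4, 8])
        with pytest.raises(ValueError):
            BoxCountCurve(sizes=[1, 2], counts=[4, 0])


class TestFit:
    def test_solid_cube_dimension(self, cube64):
        sched = box_size_schedule(cube64.shape, "pow2")
        res = fit_fractal_dimension(boxcount_curve(cube64, sched))
        assert res.fd == pytest.approx(3.0, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_slab_dimension(self):
        slab = make_phantom("slab", 64)
        sched = box_size_schedule(slab.shape, "pow2")
        res = fit_fractal_dimension(boxcount_curve(slab, sched))
        assert res.fd == pytest.approx(2.0, abs=1e-9)

    def test_menger3_dimension(self):
        curve = boxcount_curve(make_phantom("menger", 3), [1, 3, 9, 27])
        res = fit_fractal_dimension(curve)
        assert res.fd == pytest.approx(MENGER_DIM, abs=1e-9)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_saturated_points_included_on_request(self):
        # the Menger curve is exactly collinear, so including (27, 1) is harmless
        curve = boxcount_curve(make_phantom("menger", 3), [1, 3, 9, 27])
        res = fit_fractal_dimension(curve, include_saturated=True)
        assert res.fd == pytest.approx(MENGER_DIM, abs=1e-9)
        assert res.n_points == 4

    def test_degenerate_flagged(self):
        m = np.zeros((8, 8, 8), dtype=np.uint8)
        m[2, 2, 2] = 1
        curve = boxcount_curve(SegmentationMask(data=m), [1, 2, 4], drop_saturated_tail=False)
        res = fit_fractal_dimension(curve)
        assert not res.ok
        assert math.isnan(res.fd)

    def test_best_window_recovers_clean_range(self):
        # planted curve: exact slope 2 for s <= 8, flat saturated tail after
        curve = BoxCountCurve(sizes=[1, 2, 4, 8, 16, 32], counts=[4096, 1024, 256, 64, 2, 2])
        res = fit_fractal_dimension(curve, fit_policy="best_window", min_points=3)
        assert res.fd == pytest.approx(2.0, abs=1e-9)
        assert set(res.fit_sizes) >= {1, 2, 4, 8}

    def test_translation_invariance_exact(self, menger2):
        base_curve = boxcount_curve(menger2, [1, 3, 9])
        for offset in ((0, 0, 0), (5, 1, 9), (17, 17, 17)):
            big = np.zeros((40, 40, 40), dtype=np.uint8)
            big[
                offset[0] : offset[0] + 9,
                offset[1] : offset[1] + 9,
                offset[2] : offset[2] + 9,
            ] = menger2.data
            curve = boxcount_curve(SegmentationMask(data=big), [1, 3, 9])
            np.testing.assert_array_equal(curve.counts, base_curve.counts)

    def test_scale_invariance_solid(self):
        cube = make_phantom("cube", 32)
        up = SegmentationMask(data=np.kron(cube.data, np.ones((2, 2, 2), dtype=np.uint8)))
        fd1 = fit_fractal_dimension(
            boxcount_curve(cube, box_size_schedule(cube.shape, "pow2"))
        ).fd
        fd2 = fit_fractal_dimension(
            boxcount_curve(up, box_size_schedule(up.shape, "pow2"))
        ).fd
        assert abs(fd1 - fd2) < 0.02

    def test_dimension_ordering_on_phantoms(self):
        fds = {}
        for kind, arg, sched in (
            ("line", 64, "pow2"),
            ("slab", 64, "pow2"),
            ("menger", 3, "ternary"),
            ("cube", 64, "pow2"),
        ):
            m = make_phantom(kind, arg)
            schedule = box_size_schedule(m.shape, sched)
            fds[kind] = fit_fractal_dimension(boxcount_curve(m, schedule)).fd
        assert fds["line"] < fds["slab"] < fds["menger"] < fds["cube"]
        for kind, expect in (("line", 1), ("slab", 2), ("menger", MENGER_DIM), ("cube", 3)):
            assert fds[kind] == pytest.approx(expect, abs=0.1)


class TestLocalFDMap:
    def test_map_shape(self, cube64):
        lm = local_fd_map(cube64, window=32, stride=16)
        assert lm.values.shape == (3, 3, 3)  # floor((64-32)/16)+1

    def test_solid_cube_local_values(self, cube64):
        lm = local_fd_map(cube64, window=32, stride=16)
        assert np.all(np.abs(lm.values - 3.0) < 0.1)
        assert lm.fd_max == pytest.approx(3.0, abs=0.1)

    def test_fd_max_is_map_max(self, menger2):
        big = np.zeros((16, 16, 16), dtype=np.uint8)
        big[:9, :9, :9] = menger2.data
        lm = local_fd_map(SegmentationMask(data=big), window=8, stride=4)
        assert lm.fd_max == np.nanmax(lm.values)

    def test_window_too_large_raises(self, menger2):
        with pytest.raises(ValueError, match="window"):
            local_fd_map(menger2, window=32, stride=16)

    def test_no_foreground_raises(self):
        empty = SegmentationMask(data=np.zeros((16, 16, 16), dtype=np.uint8))
        with pytest.raises(ValueError, match="valid window"):
            local_fd_map(empty, window=8, stride=8)


class TestComputeFD:
    def test_menger_phantom_end_to_end(self, tmp_path):
        m = make_phantom("menger", 3)
        vol = CTVolume(data=m.data * 100.0, spacing=(1, 1, 1))
        save_volume(vol, tmp_path / "v.nii")
        save_mask(m, tmp_path / "m.nii")
        cfg = FDConfig(schedule="ternary", crop_margin=0)
        row = compute_fd(tmp_path / "v.nii", tmp_path / "m.nii", cfg)
        assert row["fd"] == pytest.approx(MENGER_DIM, abs=0.02)
        assert row["voxels"] == 8000

    def test_deterministic_rows(self, tmp_path):
        m = make_phantom("menger", 2)
        vol = CTVolume(data=m.data * 50.0, spacing=(1, 1, 1))
        save_volume(vol, tmp_path / "v.nii")
        save_mask(m, tmp_path / "m.nii")
        cfg = FDConfig(schedule="ternary", crop_margin=0)
        r1 = compute_fd(tmp_path / "v.nii", tmp_path / "m.nii", cfg)
        r2 = compute_fd(tmp_path / "v.nii", tmp_path / "m.nii", cfg)
        assert r1 == r2

    def test_empty_mask_error_names_path(self, tmp_path):
        m = make_phantom("cube", 8)
        vol = CTVolume(data=m.data * 1.0, spacing=(1, 1, 1))
        save_volume(vol, tmp_path / "v.nii")
        empty = SegmentationMask(data=np.zeros((8, 8, 8), dtype=np.uint8))
        save_mask(empty, tmp_path / "empty.nii")
        with pytest.raises(ValueError, match="empty.nii"):
            compute_fd(tmp_path / "v.nii", tmp_path / "empty.nii")

    def test_resampled_input(self, tmp_path):
        # anisotropic input is brought to 1 mm before counting
        cube = np.ones((32, 32, 8), dtype=np.uint8)
        vol = CTVolume(data=cube * 10.0, spacing=(1.0, 1.0, 4.0))
        mask = SegmentationMask(data=cube, spacing=(1.0, 1.0, 4.0))
        save_volume(vol, tmp_path / "v.nii")
        save_mask(mask, tmp_path / "m.nii")
        row = compute_fd(tmp_path / "v.nii", tmp_path / "m.nii", FDConfig(crop_margin=0))
        assert row["fd"] == pytest.approx(3.0, abs=0.05)
        assert row["voxels"] == 32 * 32 * 32
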