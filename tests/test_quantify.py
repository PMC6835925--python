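"""Segmentation, SNR statistic, lambda sweep, quantification, MIP rendering."""

import numpy as np
import pytest

from mpiphantom import (
    PhantomSpec,
    acquire,
    background_subtract,
    dual_tube_metrics,
    kaczmarz,
    lambda_sweep,
    mip_render,
    segment,
    snr,
    volume_and_iron,
    voxelize,
)
from mpiphantom.phantom import Tube, VoxelGrid


def cylinder_volume(shape=(17, 17, 17), radius=3.0, length=10):
    """Binary cylinder along x on a unit grid."""
    vals = np.zeros(shape)
    y, z = np.meshgrid(np.arange(shape[1]), np.arange(shape[2]), indexing="ij")
    disc = ((y - shape[1] // 2) ** 2 + (z - shape[2] // 2) ** 2) <= radius**2
    lo = (shape[0] - length) // 2
    vals[lo : lo + length, disc] = 1.0
    return vals


class TestSegment:
    def test_binary_cylinder_segmented_exactly(self):
        vals = cylinder_volume()
        seg = segment(vals, axis=0)
        assert not seg.failed
        np.testing.assert_array_equal(seg.object_mask, vals > 0)

    def test_noisy_cylinder_dice_above_09(self):
        rng = np.random.default_rng(0)
        vals = cylinder_volume()
        truth = vals > 0
        noisy = np.clip(vals + 0.10 * rng.standard_normal(vals.shape), 0.0, None)
        seg = segment(noisy, axis=0)
        inter = (seg.object_mask & truth).sum()
        dice = 2.0 * inter / (seg.object_mask.sum() + truth.sum())
        assert dice > 0.9

    def test_all_zero_flagged(self):
        seg = segment(np.zeros((9, 9, 9)))
        assert seg.failed
        assert "no positive" in seg.reason

    def test_uniform_volume_flagged(self):
        seg = segment(np.ones((9, 9, 9)))
        assert seg.failed

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        vals = cylinder_volume() + 0.05 * rng.standard_normal((17, 17, 17))
        vals = np.clip(vals, 0, None)
        a = segment(vals, axis=0)
        b = segment(vals, axis=0)
        np.testing.assert_array_equal(a.object_mask, b.object_mask)

    def test_masks_disjoint(self):
        seg = segment(cylinder_volume(), axis=0)
        assert not (seg.object_mask & seg.background_mask).any()


class TestSnr:
    def test_flat_object_over_flat_background(self):
        vals = np.ones((9, 9, 9))
        obj = np.zeros_like(vals, dtype=bool)
        obj[3:6, 3:6, 3:6] = True
        vals[obj] = 10.0
        from mpiphantom.quantify import SegmentationResult
        from scipy import ndimage

        seg = SegmentationResult(
            object_mask=obj,
            background_mask=~ndimage.binary_dilation(obj, np.ones((3, 3, 3), bool)),
        )
        assert snr(vals, seg) == pytest.approx(10.0)
        vals[obj] = 1.0
        assert snr(vals, seg) == pytest.approx(1.0)

    def test_invariant_under_global_scaling(self):
        vals = cylinder_volume() + 0.1
        seg = segment(vals, axis=0)
        assert snr(vals, seg) == pytest.approx(snr(3.7 * vals, seg), rel=1e-12)

    def test_snr_decreases_with_noise(self):
        rng = np.random.default_rng(2)
        base = cylinder_volume()
        values = []
        for level in (0.02, 0.08, 0.2):
            noisy = np.clip(base + level * rng.standard_normal(base.shape), 0, None)
            seg = segment(noisy, axis=0)
            values.append(snr(noisy, seg))
        assert values[0] > values[1] > values[2]


class TestVolumeAndIron:
    @pytest.mark.parametrize("diameter", [1.0, 2.0, 3.0])
    @pytest.mark.parametrize("conc", [10.0, 1.0, 0.1])
    def test_ground_truth_iron_exact(self, small_grid, diameter, conc):
        # perfect segmentation = the full support of the rasterized tube;
        # iron error is then pure voxelization (< 1%)
        from scipy import ndimage

        from mpiphantom.quantify import SegmentationResult

        phantom = PhantomSpec.single(diameter, conc)
        grid = voxelize(phantom, small_grid)
        support = grid.values > 0
        seg = SegmentationResult(
            object_mask=support,
            background_mask=~ndimage.binary_dilation(support, np.ones((3, 3, 3), bool)),
        )
        report = volume_and_iron(grid, seg, None, phantom.total_iron_umol)
        assert report.iron_umol == pytest.approx(phantom.total_iron_umol, rel=0.01)

    def test_empty_mask_flagged(self, small_grid):
        seg = segment(np.zeros(small_grid.shape))
        report = volume_and_iron(small_grid, seg, 90.0, 0.9)
        assert report.failed
        assert report.volume_ul == 0.0 and report.iron_umol == 0.0

    def test_deviation_arithmetic(self, small_grid):
        phantom = PhantomSpec.single(3.0, 10.0)
        grid = voxelize(phantom, small_grid)
        seg = segment(grid.values, axis=0)
        report = volume_and_iron(grid, seg, 90.0, 0.9)
        assert report.volume_deviation_percent == pytest.approx(
            100.0 * (report.volume_ul / 90.0 - 1.0)
        )


class TestLambdaSweep:
    def test_noiseless_sweep_well_defined_everywhere(self, small_matrix, small_grid):
        # noiseless data: every lambda reconstructs and segments, SNR is
        # finite and far above 1, and the argmax lies on the grid
        grid = voxelize(PhantomSpec.single(3.0, 10.0), small_grid)
        raw = acquire(small_matrix, grid, seed=0, noise_sigma=0.0)
        lambdas = np.logspace(0, -4, 5)
        table, best = lambda_sweep(
            small_matrix, background_subtract(raw), lambdas=lambdas, axis=0
        )
        assert len(table) == 5
        assert not table["segmentation_failed"].any()
        assert np.all(np.isfinite(table["snr"])) and np.all(table["snr"] > 10.0)
        assert best in lambdas

    def test_noisy_sweep_argmax_on_valid_entries(self, small_matrix, small_grid):
        grid = voxelize(PhantomSpec.single(3.0, 0.2), small_grid)
        raw = acquire(small_matrix, grid, seed=7)
        table, best = lambda_sweep(
            small_matrix,
            background_subtract(raw),
            lambdas=np.logspace(0, -4, 5),
            axis=0,
        )
        valid = table[np.isfinite(table["snr"])]
        assert best == valid.loc[valid["snr"].idxmax(), "lambda"] or np.isnan(best)

    def test_two_lambdas_with_failure_takes_valid_one(self):
        # degenerate 1x1 "matrix": lam huge -> zero volume -> failed segment
        s = np.array([[1.0 + 0j]])
        u = np.array([1.0 + 0j])
        grid = VoxelGrid((1, 1, 1), (1.0, 1.0, 1.0))
        table, best = lambda_sweep(s, u, lambdas=[1e8, 1e-6], axis=0)
        assert np.isnan(best) or best == pytest.approx(1e-6)

    def test_requires_two_lambdas(self, small_matrix):
        with pytest.raises(ValueError):
            lambda_sweep(small_matrix, np.zeros(small_matrix.n_rows), lambdas=[1.0])


class TestDualTube:
    def test_equal_tubes_no_shadowing(self, small_matrix, small_grid):
        # identical tubes, well separated: peak ratio 1 within 5%
        t1 = Tube(2.0, 40.0, 10.0, offset_mm=(-4.5, 0.0))
        t2 = Tube(2.0, 40.0, 10.0, offset_mm=(+4.5, 0.0))
        spec = PhantomSpec(tubes=(t1, t2), assembly="dual")
        grid = voxelize(spec, small_grid)
        raw = acquire(small_matrix, grid, seed=0, noise_sigma=0.0)
        recon = kaczmarz(small_matrix, background_subtract(raw), lam=1e-2, iterations=5)
        report = dual_tube_metrics(recon, spec)
        assert report.iron_ratio == pytest.approx(1.0)
        assert report.shadowing_ratio == pytest.approx(1.0, abs=0.05)

    def test_shadowing_nonincreasing_with_iron_ratio(self, small_matrix, small_grid):
        ratios = {}
        for pair, iron_ratio in (((3.0, 3.0), 1.0), ((2.0, 1.0), 4.0), ((3.0, 1.0), 9.0)):
            spec = PhantomSpec.dual(pair, 10.0)
            grid = voxelize(spec, small_grid)
            raw = acquire(small_matrix, grid, seed=1, noise_sigma=0.0)
            recon = kaczmarz(
                small_matrix, background_subtract(raw), lam=1e-2, iterations=5
            )
            report = dual_tube_metrics(recon, spec)
            assert report.iron_ratio == pytest.approx(iron_ratio)
            ratios[iron_ratio] = report.shadowing_ratio
        assert ratios[1.0] >= ratios[4.0] >= ratios[9.0]

    def test_iron_ratios_from_geometry(self):
        assert PhantomSpec.dual((3.0, 1.0), 10.0).tubes[0].iron_umol / PhantomSpec.dual(
            (3.0, 1.0), 10.0
        ).tubes[1].iron_umol == pytest.approx(9.0)

    def test_single_tube_rejected(self, tube3_recon_noiseless):
        phantom, _, recon = tube3_recon_noiseless
        with pytest.raises(ValueError, match="dual"):
            dual_tube_metrics(recon, phantom)


class TestMipRender:
    def test_single_bright_voxel(self):
        vals = np.zeros((7, 7, 7))
        vals[2, 3, 5] = 1.0
        mip = mip_render(vals, axis=2)
        assert mip.shape == (7, 7)
        assert mip[2, 3] == 1.0 and mip.sum() == 1.0

    def test_zero_threshold_is_plain_mip(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, (6, 6, 6))
        np.testing.assert_array_equal(mip_render(vals, 0.0, axis=1), vals.max(axis=1))

    @pytest.mark.parametrize("axis", [0, 1, 2])
    def test_axis_consistent_with_transpose_oracle(self, axis):
        rng = np.random.default_rng(axis)
        vals = rng.uniform(0, 1, (5, 6, 7))
        thr = np.where(vals >= 0.5 * vals.max(), vals, 0.0)
        np.testing.assert_array_equal(mip_render(vals, 0.5, axis=axis), thr.max(axis=axis))

    def test_upscale(self):
        vals = np.zeros((5, 5, 5))
        vals[2, 2, 2] = 1.0
        mip = mip_render(vals, axis=0, upscale=4)
        assert mip.shape == (20, 20)
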