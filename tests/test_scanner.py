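"""Virtual scanner: system matrix physics, acquisition noise, row selection."""

import numpy as np
import pytest
from scipy import stats

from mpiphantom import (
    PhantomSpec,
    ScannerConfig,
    acquire,
    block_average,
    build_system_matrix,
    default_grid,
    mcp3_distribution,
    select_frequencies,
    voxelize,
)
from mpiphantom.phantom import VoxelGrid
from mpiphantom.scanner import EmptySelectionError


class TestScannerConfig:
    def test_drive_frequencies_near_25khz(self, small_config):
        for f in small_config.drive_frequencies_hz:
            assert 20e3 < f < 30e3

    def test_trajectory_closes(self, small_config):
        n = small_config.trajectory_samples
        for d in small_config.drive_divisors:
            assert n % d == 0

    def test_non_integer_divisor_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            ScannerConfig(drive_divisors=(16, 15, 14.5))

    def test_drive_fov_consistent_with_default_grid(self):
        cfg = ScannerConfig()
        grid = default_grid()
        fov = cfg.drive_fov_mm()
        for axis in range(3):
            lo, hi = grid.extent_mm(axis)
            # grid coverage within ~10% of the FFP excursion
            assert (hi - lo) <= 1.1 * fov[axis]


class TestSystemMatrix:
    def test_delta_phantom_returns_matrix_column(self, small_matrix, small_grid):
        grid = small_grid.copy_empty()
        idx = (6, 6, 6)
        grid.values[idx] = 1.0
        raw = acquire(small_matrix, grid, seed=0, noise_sigma=0.0)
        flat = np.ravel_multi_index(idx, small_grid.shape)
        np.testing.assert_allclose(
            raw.frames[0], small_matrix.data.astype(np.complex128)[:, flat], rtol=1e-6
        )

    def test_zero_moment_distribution_gives_zero_matrix(self, small_config, small_grid):
        dist = mcp3_distribution(310.0)
        null = type(dist)(
            beta=dist.beta, mu1=dist.mu1, mu2=dist.mu2,
            sigma1=dist.sigma1, sigma2=dist.sigma2,
            ms_molar=1e-30, temperature=310.0,
        )
        tiny = VoxelGrid.centered((5, 5, 5), (1.5, 1.5, 0.75))
        matrix = build_system_matrix(small_config, null, tiny)
        assert np.max(np.abs(matrix.data)) < 1e-25

    def test_mirror_symmetric_voxels_have_equal_row_magnitudes(self, mcp3_body):
        # divisors with odd lcm/d per axis: a half-trajectory shift negates
        # the drive, so mirrored voxels see negated fields and the spectra
        # agree in magnitude bin by bin
        cfg = ScannerConfig(drive_divisors=(6, 10, 14), sample_rate_hz=200e3,
                            sf_snr_target=None)
        grid = VoxelGrid.centered((5, 5, 5), (2.0, 2.0, 1.0))
        matrix = build_system_matrix(cfg, mcp3_body, grid)
        plus = np.ravel_multi_index((3, 3, 3), grid.shape)
        minus = np.ravel_multi_index((1, 1, 1), grid.shape)
        np.testing.assert_allclose(
            np.abs(matrix.data[:, plus]), np.abs(matrix.data[:, minus]),
            rtol=1e-4, atol=1e-9 * np.abs(matrix.data).max(),
        )

    def test_seed_independent_and_reproducible(self, small_config, mcp3_body):
        tiny = VoxelGrid.centered((5, 5, 5), (1.5, 1.5, 0.75))
        a = build_system_matrix(small_config, mcp3_body, tiny)
        b = build_system_matrix(small_config, mcp3_body, tiny)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.noise_sigma == b.noise_sigma


class TestAcquire:
    def test_noiseless_is_exact_forward_map(self, small_matrix, small_grid):
        grid = voxelize(PhantomSpec.single(3.0, 10.0), small_grid)
        raw = acquire(small_matrix, grid, seed=3, noise_sigma=0.0)
        expected = small_matrix.data.astype(np.complex128) @ grid.values.ravel()
        np.testing.assert_array_equal(raw.frames[0], expected)
        assert np.all(raw.background == 0)

    def test_linearity_noiseless(self, small_matrix, small_grid):
        g1 = voxelize(PhantomSpec.single(3.0, 4.0), small_grid)
        g2 = voxelize(PhantomSpec.single(2.0, 6.0), small_grid)
        both = small_grid.copy_empty()
        both.values = g1.values + g2.values
        u1 = acquire(small_matrix, g1, seed=0, noise_sigma=0.0).frames[0]
        u2 = acquire(small_matrix, g2, seed=0, noise_sigma=0.0).frames[0]
        u12 = acquire(small_matrix, both, seed=0, noise_sigma=0.0).frames[0]
        np.testing.assert_allclose(u12, u1 + u2, atol=1e-9 * np.abs(u12).max())

    def test_deterministic_given_seed(self, small_matrix, small_grid):
        grid = voxelize(PhantomSpec.single(3.0, 1.0), small_grid)
        a = acquire(small_matrix, grid, seed=11)
        b = acquire(small_matrix, grid, seed=11)
        np.testing.assert_array_equal(a.frames, b.frames)
        np.testing.assert_array_equal(a.background, b.background)

    def test_empty_phantom_signal_distributed_as_background(self, small_matrix, small_grid):
        raw = acquire(small_matrix, small_grid.copy_empty(), seed=5, frames=5)
        take = slice(0, 200)
        sig = np.concatenate([raw.frames[:, take].real.ravel(), raw.frames[:, take].imag.ravel()])
        bg = np.concatenate([raw.background[:, take].real.ravel(), raw.background[:, take].imag.ravel()])
        assert stats.ks_2samp(sig, bg).pvalue > 0.01

    def test_block_average_reduces_noise_sqrt5(self, small_matrix, small_grid):
        # Monte Carlo over seeds: std of 5-frame block means vs raw frames
        raws, avgs = [], []
        for seed in range(40):
            raw = acquire(small_matrix, small_grid.copy_empty(), seed=seed, frames=10)
            raws.append(raw.frames.real.std())
            avgs.append(block_average(raw.frames, 5).real.std())
        ratio = np.mean(raws) / np.mean(avgs)
        assert ratio == pytest.approx(np.sqrt(5.0), rel=0.10)

    def test_geometry_mismatch_rejected(self, small_matrix):
        other = VoxelGrid.centered((9, 9, 9), (1.5, 1.5, 0.75))
        with pytest.raises(ValueError, match="geometry"):
            acquire(small_matrix, other, seed=0)


class TestSelectFrequencies:
    def test_threshold_zero_keeps_all(self, small_matrix):
        sub = select_frequencies(small_matrix, 0.0)
        assert sub.n_rows == small_matrix.n_rows

    def test_selection_monotone_in_threshold(self, small_matrix):
        n6 = select_frequencies(small_matrix, 6.0).n_rows
        n24 = select_frequencies(small_matrix, 24.0).n_rows
        assert n24 <= n6 <= small_matrix.n_rows

    def test_infinite_threshold_errors(self, small_matrix):
        with pytest.raises(EmptySelectionError):
            select_frequencies(small_matrix, np.inf)

    def test_ordering_preserved(self, small_matrix):
        sub = select_frequencies(small_matrix, 10.0)
        orig = small_matrix.row_snr >= 10.0
        np.testing.assert_array_equal(sub.frequency_hz, small_matrix.frequency_hz[orig])
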