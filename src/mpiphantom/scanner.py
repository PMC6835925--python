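"""Virtual field-free-point scanner: system matrices and raw signals.

The selection field B_sel(r) = G r (diagonal gradient) has its zero at the
grid center; three orthogonal sinusoidal drive fields B_d,i(t) = A_i
sin(2 pi f_i t) sweep the field-free point along a 3D Lissajous trajectory.
The drive frequencies derive from one sample rate through integer divisors,
f_i = f_s / d_i, so the trajectory closes after lcm(d) samples.

Tracer at r sees B(r, t) = G r + B_d(t); its equilibrium moment is
m(r, t) = M(|B|) n_Fe(r) B/|B| with M the molar magnetization curve of the
tracer and n_Fe the iron amount in the voxel.  One ideal receive channel
per axis picks up u_i(t) = d m_i / d t (unit sensitivity); the system
matrix holds the Fourier components of the unit-concentration response of
every voxel, from which measurements follow by linearity plus additive
complex Gaussian noise.  A background acquisition (noise only) accompanies
every measurement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .magnetism import MomentDistribution, moment_average_langevin
from .phantom import VoxelGrid

__all__ = [
    "ScannerConfig",
    "SystemMatrix",
    "RawSignal",
    "EmptySelectionError",
    "build_system_matrix",
    "acquire",
    "select_frequencies",
    "default_grid",
    "full_resolution_grid",
]


@dataclass(frozen=True)
class ScannerConfig:
    """Acquisition settings of the virtual scanner.

    Defaults give a desk-scale instrument in the 25 kHz family: sample rate
    800 kHz with divisors (32, 30, 33) -> drive frequencies (25.0, 26.7,
    24.2) kHz, trajectory period 5280 samples (6.6 ms), drive amplitude
    12 mT per axis and selection gradients (1.25, 1.25, 2.5) T/m.
    ``sf_snr_target`` calibrates the noise floor so that the median
    mid-band system-matrix row reaches that SNR; None means noiseless.
    """

    drive_amplitude_t: tuple[float, float, float] = (0.012, 0.012, 0.012)
    drive_divisors: tuple[int, int, int] = (32, 30, 33)
    sample_rate_hz: float = 800e3
    gradient_t_per_m: tuple[float, float, float] = (1.25, 1.25, 2.5)
    bandwidth_hz: tuple[float, float] = (0.0, np.inf)
    sf_snr_target: float | None = 100.0
    snr_threshold: float = 5.0
    frames: int = 5
    block_average: int = 5
    temperature: float = 310.0

    def __post_init__(self) -> None:
        if any(a <= 0 for a in self.drive_amplitude_t):
            raise ValueError("drive amplitudes must be strictly positive")
        if any(g <= 0 for g in self.gradient_t_per_m):
            raise ValueError("gradients must be strictly positive")
        for d in self.drive_divisors:
            if d != int(d) or d < 2:
                raise ValueError(
                    "drive divisors must be integers >= 2 so the trajectory "
                    "period is an integer multiple of the sample interval"
                )
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be strictly positive")
        if self.frames < 1 or self.block_average < 1:
            raise ValueError("frames and block_average must be >= 1")

    @property
    def drive_frequencies_hz(self) -> tuple[float, float, float]:
        return tuple(self.sample_rate_hz / d for d in self.drive_divisors)

    @property
    def trajectory_samples(self) -> int:
        return math.lcm(*(int(d) for d in self.drive_divisors))

    @property
    def trajectory_period_s(self) -> float:
        return self.trajectory_samples / self.sample_rate_hz

    def drive_fov_mm(self) -> tuple[float, float, float]:
        """Peak-to-peak FFP excursion per axis, 2 A_i / G_i, in mm."""
        return tuple(
            2.0 * a / g * 1e3
            for a, g in zip(self.drive_amplitude_t, self.gradient_t_per_m)
        )

    @classmethod
    def test_scale(cls, **overrides) -> "ScannerConfig":
        """Small configuration for fast simulations (1680-sample trajectory)."""
        defaults = dict(drive_divisors=(16, 15, 14), sample_rate_hz=400e3)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def full_scale(cls, **overrides) -> "ScannerConfig":
        """Preclinical-scanner-like configuration (53856-sample trajectory)."""
        defaults = dict(drive_divisors=(102, 96, 99), sample_rate_hz=2.5e6)
        defaults.update(overrides)
        return cls(**defaults)


def default_grid(shape=(17, 17, 17), voxel_size_mm=(1.2, 1.2, 0.6)) -> VoxelGrid:
    """Desk-scale reconstruction grid matched to the default drive FOV."""
    return VoxelGrid.centered(shape, voxel_size_mm)


def full_resolution_grid() -> VoxelGrid:
    """Full-resolution grid: 33^3 voxels of 0.8 x 0.8 x 0.4 mm^3."""
    return VoxelGrid.centered((33, 33, 33), (0.8, 0.8, 0.4))


@dataclass
class SystemMatrix:
    """Frequency-component x voxel forward operator.

    Rows are indexed by (channel, DFT bin); ``row_snr`` is the row rms over
    voxels divided by the calibrated per-component noise floor sigma.
    """

    data: np.ndarray  # (n_rows, n_voxels) complex
    frequency_hz: np.ndarray  # (n_rows,)
    channel: np.ndarray  # (n_rows,) int
    bin_index: np.ndarray  # (n_rows,) int
    row_snr: np.ndarray  # (n_rows,)
    noise_sigma: float
    config: ScannerConfig
    grid: VoxelGrid
    distribution: MomentDistribution

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]


def _magnetization_table(
    dist: MomentDistribution, b_max: float, temperature: float, n: int = 8193
):
    """Dense M(|B|) lookup (Am^2/mol) for fast interpolation along trajectories."""
    b = np.linspace(0.0, b_max, n)
    m = dist.ms_molar * moment_average_langevin(dist, b, temperature=temperature)
    return b, m


def build_system_matrix(
    config: ScannerConfig,
    dist: MomentDistribution,
    grid: VoxelGrid,
    dtype=np.complex64,
    chunk_voxels: int = 256,
) -> SystemMatrix:
    """Simulate the system function of a tracer on a grid.

    For every voxel the induced signal of a unit concentration (1 mmol
    Fe/l) is simulated along one closed trajectory period and Fourier
    transformed; the time derivative is applied spectrally (multiplication
    by i 2 pi f), which is exact for the periodic steady state.  The DC bin
    and components outside the configured bandwidth are discarded.
    Deterministic: no randomness enters the system function.
    """
    n_t = config.trajectory_samples
    fs = config.sample_rate_hz
    t = np.arange(n_t) / fs
    amps = np.asarray(config.drive_amplitude_t)
    freqs = np.asarray(config.drive_frequencies_hz)
    grads = np.asarray(config.gradient_t_per_m)
    drive = amps[:, None] * np.sin(2.0 * np.pi * freqs[:, None] * t[None, :])  # (3, n_t)

    coords_m = grid.world_coords() * 1e-3  # (n_vox, 3)
    n_vox = coords_m.shape[0]
    voxel_volume_m3 = grid.voxel_volume_mm3 * 1e-9
    # unit concentration 1 mmol/l = 1 mol/m^3 -> iron per voxel in mol
    n_fe = voxel_volume_m3

    b_static = coords_m * grads[None, :]  # (n_vox, 3)
    b_max = float(np.sqrt(((np.abs(b_static) + amps[None, :]) ** 2).sum(axis=1)).max())
    tb, tm = _magnetization_table(dist, b_max * 1.001, config.temperature)

    n_bins = n_t // 2 + 1
    f_bins = np.arange(n_bins) * fs / n_t
    lo, hi = config.bandwidth_hz
    keep = (f_bins >= lo) & (f_bins <= hi)
    keep[0] = False  # DC carries no induced signal
    kept_bins = np.flatnonzero(keep)
    omega = 2j * np.pi * f_bins[kept_bins]

    rows_per_channel = kept_bins.size
    data = np.empty((3 * rows_per_channel, n_vox), dtype=dtype)

    for start in range(0, n_vox, chunk_voxels):
        sl = slice(start, min(start + chunk_voxels, n_vox))
        b = b_static[sl, :, None] + drive[None, :, :]  # (chunk, 3, n_t)
        b_norm = np.sqrt((b**2).sum(axis=1))  # (chunk, n_t)
        m_mag = np.interp(b_norm, tb, tm) * n_fe  # Am^2 per unit conc
        with np.errstate(invalid="ignore", divide="ignore"):
            scale = np.where(b_norm > 0.0, m_mag / b_norm, 0.0)
        for ch in range(3):
            moment = scale * b[:, ch, :]  # (chunk, n_t)
            spec = np.fft.rfft(moment, axis=1)[:, kept_bins] / n_t
            data[ch * rows_per_channel : (ch + 1) * rows_per_channel, sl] = (
                spec * omega[None, :]
            ).T

    frequency_hz = np.tile(f_bins[kept_bins], 3)
    channel = np.repeat(np.arange(3), rows_per_channel)
    bin_index = np.tile(kept_bins, 3)

    row_rms = np.sqrt(np.mean(np.abs(data.astype(np.complex128)) ** 2, axis=1))
    if config.sf_snr_target is None:
        sigma = 0.0
        row_snr = np.full(row_rms.shape, np.inf)
    else:
        f_lo, f_hi = np.percentile(frequency_hz, [33.0, 67.0])
        mid = (frequency_hz >= f_lo) & (frequency_hz <= f_hi) & (row_rms > 0)
        ref = np.median(row_rms[mid]) if mid.any() else np.median(row_rms)
        sigma = float(ref / config.sf_snr_target)
        with np.errstate(divide="ignore"):
            row_snr = np.where(sigma > 0, row_rms / sigma, np.inf)

    return SystemMatrix(
        data=data,
        frequency_hz=frequency_hz,
        channel=channel,
        bin_index=bin_index,
        row_snr=row_snr,
        noise_sigma=sigma,
        config=config,
        grid=grid.copy_empty(),
        distribution=dist,
    )


@dataclass
class RawSignal:
    """Measured frequency components per frame, with paired background.

    ``frames`` and ``background`` are (n_frames, n_rows) complex arrays on
    the frequency grid of the generating system matrix.
    """

    frames: np.ndarray
    background: np.ndarray
    frequency_hz: np.ndarray
    channel: np.ndarray
    noise_sigma: float
    seed: int | None
    block_average: int = 1

    def __post_init__(self) -> None:
        if self.frames.shape != self.background.shape:
            raise ValueError("background frame count must equal signal frame count")


def acquire(
    matrix: SystemMatrix,
    phantom_grid: VoxelGrid,
    seed: int | None = None,
    frames: int | None = None,
    noise_sigma: float | None = None,
) -> RawSignal:
    """Simulate a phantom measurement u = S c + eps plus a background run.

    Noise is stationary complex Gaussian, independent per frame and per
    frequency component, with standard deviation ``noise_sigma`` on real
    and imaginary parts (defaults to the matrix noise floor).  Deterministic
    given the seed.
    """
    if not matrix.grid.same_geometry(phantom_grid):
        raise ValueError("phantom grid geometry does not match the system matrix")
    n_frames = matrix.config.frames if frames is None else int(frames)
    sigma = matrix.noise_sigma if noise_sigma is None else float(noise_sigma)
    c = phantom_grid.values.reshape(-1)
    clean = matrix.data.astype(np.complex128) @ c
    rng = np.random.default_rng(seed)

    def noise():
        return sigma * (
            rng.standard_normal((n_frames, matrix.n_rows))
            + 1j * rng.standard_normal((n_frames, matrix.n_rows))
        )

    eps = noise() if sigma > 0 else np.zeros((n_frames, matrix.n_rows), complex)
    bg = noise() if sigma > 0 else np.zeros((n_frames, matrix.n_rows), complex)
    return RawSignal(
        frames=clean[None, :] + eps,
        background=bg,
        frequency_hz=matrix.frequency_hz,
        channel=matrix.channel,
        noise_sigma=sigma,
        seed=seed,
        block_average=matrix.config.block_average,
    )


class EmptySelectionError(RuntimeError):
    """SNR threshold left no frequency components."""


def select_frequencies(matrix: SystemMatrix, snr_threshold: float) -> SystemMatrix:
    """Keep rows whose SNR meets the threshold; ordering is preserved."""
    keep = matrix.row_snr >= snr_threshold
    if not keep.any():
        raise EmptySelectionError(
            f"no rows reach SNR {snr_threshold:g} "
            f"(max available {matrix.row_snr.max():g})"
        )
    return SystemMatrix(
        data=matrix.data[keep],
        frequency_hz=matrix.frequency_hz[keep],
        channel=matrix.channel[keep],
        bin_index=matrix.bin_index[keep],
        row_snr=matrix.row_snr[keep],
        noise_sigma=matrix.noise_sigma,
        config=matrix.config,
        grid=matrix.grid,
        distribution=matrix.distribution,
    )


def subset_signal(signal: RawSignal, keep: np.ndarray) -> RawSignal:
    """Restrict a raw signal to a boolean row subset (matching a submatrix)."""
    return RawSignal(
        frames=signal.frames[:, keep],
        background=signal.background[:, keep],
        frequency_hz=signal.frequency_hz[keep],
        channel=signal.channel[keep],
        noise_sigma=signal.noise_sigma,
        seed=signal.seed,
        block_average=signal.block_average,
    )
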