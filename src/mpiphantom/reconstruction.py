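"""Regularized Kaczmarz reconstruction of concentration volumes.

Solves min_c ||S c - u||^2 + lam_abs ||c||^2 by row action on the augmented
system [S, sqrt(lam_abs) I], the standard iterative scheme of field-free-
point imaging.  The regularization factor is specified *relative* to the
mean row energy, lam_abs = lam * mean_i ||s_i||^2, so the conventional
sweep grid 10^0 ... 10^-6 is meaningful across system matrices of different
scale.  Rows are visited sequentially by row index (deterministic); an
optional projection after every sweep keeps the volume real-valued and
non-negative, the community default for tracer concentrations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .phantom import VoxelGrid
from .scanner import RawSignal, SystemMatrix

__all__ = ["ReconVolume", "background_subtract", "block_average", "kaczmarz"]

logger = logging.getLogger(__name__)


@dataclass
class ReconVolume:
    """Reconstructed concentration volume with its provenance."""

    grid: VoxelGrid
    lam: float
    iterations: int
    nonneg: bool
    provenance: dict = field(default_factory=dict)

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def block_average(frames: np.ndarray, factor: int) -> np.ndarray:
    """Average consecutive groups of ``factor`` frames.

    The frame count must be a multiple of the factor; noise standard
    deviation drops by sqrt(factor) per block.
    """
    frames = np.asarray(frames)
    n = frames.shape[0]
    if factor < 1 or n % factor:
        raise ValueError(f"frame count {n} is not a multiple of block factor {factor}")
    return frames.reshape(n // factor, factor, -1).mean(axis=1)


def background_subtract(signal: RawSignal, factor: int | None = None) -> np.ndarray:
    """Background-corrected, block-averaged measurement spectrum (1-D).

    The frame-averaged background is removed from the block-averaged
    measurement frames; the blocks are then averaged into a single spectrum
    for reconstruction.
    """
    if signal.background is None or signal.background.size == 0:
        raise ValueError("raw signal has no paired background acquisition")
    factor = signal.block_average if factor is None else factor
    blocks = block_average(signal.frames, factor)
    return blocks.mean(axis=0) - signal.background.mean(axis=0)


def kaczmarz(
    matrix: SystemMatrix | np.ndarray,
    spectrum: np.ndarray,
    lam: float = 1e-2,
    iterations: int = 5,
    nonneg: bool = True,
    grid: VoxelGrid | None = None,
) -> ReconVolume:
    """Regularized Kaczmarz solve; returns the volume after ``iterations`` sweeps.

    Bit-reproducible given matrix, spectrum, lam and iteration count: the
    row order is fixed and no randomness is used.  Zero-energy rows are
    skipped (logged once).  ``lam >= 0``; lam = 0 gives the unregularized
    row action.  A bare array may be passed instead of a SystemMatrix for
    desk-scale linear algebra; supply ``grid`` to shape the result (or the
    flat solution vector is stored on a synthetic (n, 1, 1) grid).
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if isinstance(matrix, SystemMatrix):
        s = matrix.data
        out_grid = matrix.grid.copy_empty() if grid is None else grid.copy_empty()
        provenance = {
            "n_rows": int(s.shape[0]),
            "noise_sigma": matrix.noise_sigma,
        }
    else:
        s = np.asarray(matrix)
        out_grid = (
            grid.copy_empty()
            if grid is not None
            else VoxelGrid((s.shape[1], 1, 1), (1.0, 1.0, 1.0))
        )
        provenance = {"n_rows": int(s.shape[0])}
    u = np.asarray(spectrum)
    if u.ndim != 1 or u.size != s.shape[0]:
        raise ValueError(
            f"spectrum length {u.size} does not match matrix rows {s.shape[0]}"
        )

    s = s.astype(np.complex128, copy=False)
    u = u.astype(np.complex128, copy=False)
    energies = np.einsum("ij,ij->i", s, s.conj()).real
    alive = energies > 0
    if not alive.all():
        logger.info("skipping %d zero-energy rows", int((~alive).sum()))
    lam_abs = lam * (energies[alive].mean() if alive.any() else 0.0)
    sqrt_lam = np.sqrt(lam_abs)

    n = s.shape[1]
    c = np.zeros(n, dtype=np.complex128)
    v = np.zeros(s.shape[0], dtype=np.complex128)
    rows = np.flatnonzero(alive)
    for _ in range(iterations):
        for i in rows:
            alpha = (u[i] - s[i] @ c - sqrt_lam * v[i]) / (energies[i] + lam_abs)
            c += alpha * s[i].conj()
            v[i] += alpha * sqrt_lam
        if nonneg:
            c = np.maximum(c.real, 0.0).astype(np.complex128)

    values = np.maximum(c.real, 0.0) if nonneg else c.real
    out_grid.values = values.reshape(out_grid.shape)
    provenance.update({"lam": lam, "lam_abs": lam_abs, "iterations": iterations})
    return ReconVolume(
        grid=out_grid,
        lam=lam,
        iterations=iterations,
        nonneg=nonneg,
        provenance=provenance,
    )
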