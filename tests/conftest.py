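"""Shared fixtures: tracer distributions, desk-scale scanner geometry and
session-cached system matrices (the expensive simulated objects)."""

import numpy as np
import pytest

from mpiphantom import (
    PhantomSpec,
    ScannerConfig,
    acquire,
    background_subtract,
    build_system_matrix,
    default_grid,
    kaczmarz,
    mcp3_distribution,
    voxelize,
)


@pytest.fixture(scope="session")
def mcp3():
    """Canonical multicore tracer at magnetometry temperature (295 K)."""
    return mcp3_distribution(295.0)


@pytest.fixture(scope="session")
def mcp3_body():
    """Canonical multicore tracer at body temperature (310 K)."""
    return mcp3_distribution(310.0)


@pytest.fixture(scope="session")
def small_grid():
    """13^3 grid, 1.5 x 1.5 x 0.75 mm voxels (19.5 x 19.5 x 9.75 mm FOV)."""
    return default_grid((13, 13, 13), (1.5, 1.5, 0.75))


@pytest.fixture(scope="session")
def small_config():
    return ScannerConfig.test_scale()


@pytest.fixture(scope="session")
def small_matrix(small_config, small_grid, mcp3_body):
    """Test-scale system matrix (1680-sample trajectory, 2520 x 2197)."""
    return build_system_matrix(small_config, mcp3_body, small_grid)


@pytest.fixture(scope="session")
def default_matrix(mcp3_body):
    """Default desk-scale system matrix (17^3 grid, 5280-sample trajectory)."""
    return build_system_matrix(ScannerConfig(), mcp3_body, default_grid())


@pytest.fixture(scope="session")
def tube3_recon_noiseless(small_matrix, small_grid):
    """Noiseless 5-sweep reconstruction of the 3 mm / 90 uL / 10 mmol/l tube."""
    phantom = PhantomSpec.single(3.0, 10.0, axis="x")
    truth = voxelize(phantom, small_grid)
    raw = acquire(small_matrix, truth, seed=0, noise_sigma=0.0)
    recon = kaczmarz(small_matrix, background_subtract(raw), lam=1e-6, iterations=5)
    return phantom, truth, recon
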