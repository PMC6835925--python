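"""File I/O: delimited curve/spectrum tables, HDF5 containers, NIfTI volumes.

Curve tables are comma- or tab-delimited with a header row whose column
names carry the units: the field column is ``field_T`` (flux density) or
``field_Am`` (applied field H, converted via B = mu0 H on read), the
magnetization column ``magnetization_Am2_per_molFe``.  System matrices and
raw signals go into a single HDF5 container with named datasets; volumes
are written as NIfTI with the voxel size in the affine.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .magnetism import MU_0, MagnetizationCurve, MomentDistribution
from .mh_fit import FitResult
from .mps import DriveProtocol, HarmonicSpectrum
from .phantom import VoxelGrid
from .reconstruction import ReconVolume
from .scanner import RawSignal, ScannerConfig, SystemMatrix

__all__ = [
    "read_curve",
    "write_curve",
    "write_spectrum",
    "read_spectrum",
    "write_fit_report",
    "save_volume",
    "load_volume",
    "save_system_matrix",
    "load_system_matrix",
    "save_raw_signal",
    "load_raw_signal",
    "load_config",
]

FIELD_T = "field_T"
FIELD_AM = "field_Am"
MAG_COL = "magnetization_Am2_per_molFe"


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_curve(path, temperature: float = 295.0) -> MagnetizationCurve:
    """Read an M(H) table; accepts field in T or A/m by column name."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    df.columns = [c.strip() for c in df.columns]
    if FIELD_T in df.columns:
        field_t = df[FIELD_T].to_numpy(dtype=float)
    elif FIELD_AM in df.columns:
        field_t = df[FIELD_AM].to_numpy(dtype=float) * MU_0
    else:
        raise ValueError(
            f"no field column: expected '{FIELD_T}' or '{FIELD_AM}', "
            f"got {list(df.columns)}"
        )
    if MAG_COL not in df.columns:
        raise ValueError(f"missing magnetization column '{MAG_COL}'")
    return MagnetizationCurve(
        field_t=field_t,
        magnetization=df[MAG_COL].to_numpy(dtype=float),
        temperature=temperature,
    )


def write_curve(curve: MagnetizationCurve, path) -> None:
    path = Path(path)
    pd.DataFrame({FIELD_T: curve.field_t, MAG_COL: curve.magnetization}).to_csv(
        path, sep=_sep_for(path), index=False
    )


def write_spectrum(spectrum: HarmonicSpectrum, path) -> None:
    """Write (harmonic, frequency, amplitude) as a delimited table."""
    path = Path(path)
    pd.DataFrame(
        {
            "harmonic": spectrum.harmonics,
            "frequency_Hz": spectrum.frequencies_hz,
            "amplitude_Am2_per_molFe": spectrum.amplitudes,
        }
    ).to_csv(path, sep=_sep_for(path), index=False)


def read_spectrum(path, protocol: DriveProtocol | None = None) -> HarmonicSpectrum:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    return HarmonicSpectrum(
        harmonics=df["harmonic"].to_numpy(dtype=int),
        amplitudes=df["amplitude_Am2_per_molFe"].to_numpy(dtype=float),
        protocol=protocol or DriveProtocol(),
    )


def write_fit_report(fit: FitResult, summary: dict, path) -> None:
    """Human-readable key/value/uncertainty/unit report plus the summary."""
    dist = fit.distribution
    u = fit.uncertainties
    lines = [
        "parameter\tvalue\tuncertainty\tunit",
        f"beta\t{dist.beta:.4f}\t{u.get('beta', np.nan):.4f}\t-",
        f"mu1\t{dist.mu1 / 1e-18:.4f}\t{u.get('mu1', np.nan) / 1e-18:.4f}\taAm2",
        f"mu2\t{dist.mu2 / 1e-18:.4f}\t{u.get('mu2', np.nan) / 1e-18:.4f}\taAm2",
        f"sigma1\t{dist.sigma1:.4f}\t{u.get('sigma1', np.nan):.4f}\t-",
        f"sigma2\t{dist.sigma2:.4f}\t{u.get('sigma2', np.nan):.4f}\t-",
        f"ms_molar\t{dist.ms_molar:.4f}\t{u.get('ms_molar', np.nan):.4f}\tAm2/mol(Fe)",
        f"residual_norm\t{fit.residual_norm:.6g}\t\t",
        f"converged\t{fit.converged}\t\t",
    ]
    for key, value in summary.items():
        lines.append(f"{key}\t{value:.6g}\t\t" if isinstance(value, float) else f"{key}\t{value}\t\t")
    Path(path).write_text("\n".join(lines) + "\n")


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.diag(list(grid.voxel_size_mm) + [1.0])
    aff[:3, 3] = grid.origin_mm
    return aff


def save_volume(volume: ReconVolume | VoxelGrid, path) -> None:
    """Write a concentration volume as NIfTI (mm voxel size in the affine)."""
    grid = volume.grid if isinstance(volume, ReconVolume) else volume
    img = nib.Nifti1Image(grid.values.astype(np.float64), _affine(grid))
    img.header.set_zooms(grid.voxel_size_mm)
    nib.save(img, str(path))


def load_volume(path) -> VoxelGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    aff = img.affine
    return VoxelGrid(
        shape=data.shape,
        voxel_size_mm=tuple(np.abs(np.diag(aff)[:3])),
        origin_mm=tuple(aff[:3, 3]),
        values=np.clip(data, 0.0, None),
    )


def _config_to_yaml(config: ScannerConfig) -> str:
    return yaml.safe_dump(dataclasses.asdict(config))


def _dist_to_json(dist: MomentDistribution) -> str:
    return json.dumps(dataclasses.asdict(dist))


def save_system_matrix(matrix: SystemMatrix, path) -> None:
    """HDF5 layout: /matrix/data, /rows/{frequency_Hz,channel,bin,snr},
    /grid/{shape,voxel_size_mm,origin_mm}, config and tracer as attributes."""
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix/data", data=matrix.data, compression="gzip", track_times=False)
        f.create_dataset("rows/frequency_Hz", data=matrix.frequency_hz, track_times=False)
        f.create_dataset("rows/channel", data=matrix.channel, track_times=False)
        f.create_dataset("rows/bin", data=matrix.bin_index, track_times=False)
        f.create_dataset("rows/snr", data=matrix.row_snr, track_times=False)
        f.create_dataset("grid/shape", data=np.array(matrix.grid.shape), track_times=False)
        f.create_dataset("grid/voxel_size_mm", data=np.array(matrix.grid.voxel_size_mm), track_times=False)
        f.create_dataset("grid/origin_mm", data=np.array(matrix.grid.origin_mm), track_times=False)
        f.attrs["noise_sigma"] = matrix.noise_sigma
        f.attrs["config_yaml"] = _config_to_yaml(matrix.config)
        f.attrs["distribution_json"] = _dist_to_json(matrix.distribution)


def load_system_matrix(path) -> SystemMatrix:
    with h5py.File(path, "r") as f:
        config_dict = yaml.safe_load(f.attrs["config_yaml"])
        for key in ("drive_amplitude_t", "drive_divisors", "gradient_t_per_m", "bandwidth_hz"):
            config_dict[key] = tuple(config_dict[key])
        dist = MomentDistribution(**json.loads(f.attrs["distribution_json"]))
        grid = VoxelGrid(
            shape=tuple(int(n) for n in f["grid/shape"][()]),
            voxel_size_mm=tuple(f["grid/voxel_size_mm"][()]),
            origin_mm=tuple(f["grid/origin_mm"][()]),
        )
        return SystemMatrix(
            data=f["matrix/data"][()],
            frequency_hz=f["rows/frequency_Hz"][()],
            channel=f["rows/channel"][()],
            bin_index=f["rows/bin"][()],
            row_snr=f["rows/snr"][()],
            noise_sigma=float(f.attrs["noise_sigma"]),
            config=ScannerConfig(**config_dict),
            grid=grid,
            distribution=dist,
        )


def save_raw_signal(signal: RawSignal, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal/frames", data=signal.frames, compression="gzip", track_times=False)
        f.create_dataset("signal/background", data=signal.background, compression="gzip", track_times=False)
        f.create_dataset("rows/frequency_Hz", data=signal.frequency_hz, track_times=False)
        f.create_dataset("rows/channel", data=signal.channel, track_times=False)
        f.attrs["noise_sigma"] = signal.noise_sigma
        f.attrs["seed"] = -1 if signal.seed is None else signal.seed
        f.attrs["block_average"] = signal.block_average


def load_raw_signal(path) -> RawSignal:
    with h5py.File(path, "r") as f:
        seed = int(f.attrs["seed"])
        return RawSignal(
            frames=f["signal/frames"][()],
            background=f["signal/background"][()],
            frequency_hz=f["rows/frequency_Hz"][()],
            channel=f["rows/channel"][()],
            noise_sigma=float(f.attrs["noise_sigma"]),
            seed=None if seed < 0 else seed,
            block_average=int(f.attrs["block_average"]),
        )


def load_config(path) -> dict:
    """Load a YAML configuration file, resolving a single level of includes.

    A top-level ``include:`` entry (path or list of paths, relative to the
    config file) is loaded first and overridden by the file's own keys.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    includes = raw.pop("include", None)
    if includes is None:
        return raw
    if isinstance(includes, (str, Path)):
        includes = [includes]
    merged: dict = {}
    for inc in includes:
        with open(path.parent / inc) as fh:
            merged.update(yaml.safe_load(fh) or {})
    merged.update(raw)
    return merged
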