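"""Raw-spectra container and HDF5 import/export.

The native container is a single binary file of little-endian 32-bit floats in
``(channel, frame, a_line, k_sample)`` order plus a YAML sidecar holding the
dimensions, the wavenumber range, source parameters and pixel pitches. The
HDF5 layout mirrors the same dimension-order contract for interoperability.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import yaml

from .grid import KGrid
from .polarimetry import StokesField
from .tomogram import RawSpectra

_RESERVED = {"shape", "k_min", "k_max", "center_wavelength_um", "fwhm_bandwidth_um",
             "pixel_pitch_x_um"}


def _sidecar_path(base: Path) -> Path:
    return base.with_suffix(".yaml")


def _data_path(base: Path) -> Path:
    return base.with_suffix(".raw")


def save_container(base_path: str | Path, raw: RawSpectra) -> tuple[Path, Path]:
    """Write ``<base>.raw`` (float32 LE) and ``<base>.yaml``; returns both paths."""
    base = Path(base_path)
    data_file, sidecar = _data_path(base), _sidecar_path(base)
    raw.data.astype("<f4").tofile(data_file)
    extra = {k: v for k, v in raw.meta.items() if k not in _RESERVED}
    meta = {
        "shape": [int(n) for n in raw.data.shape],
        "k_min": float(raw.grid.k_min),
        "k_max": float(raw.grid.k_max),
        "center_wavelength_um": float(raw.grid.center_wavelength),
        "fwhm_bandwidth_um": float(raw.grid.fwhm_bandwidth),
        "pixel_pitch_x_um": float(raw.pixel_pitch_x),
        **extra,
    }
    sidecar.write_text(yaml.safe_dump(meta, sort_keys=True))
    return data_file, sidecar


def load_container(base_path: str | Path) -> RawSpectra:
    """Read a container written by :func:`save_container`."""
    base = Path(base_path)
    meta = yaml.safe_load(_sidecar_path(base).read_text())
    shape = tuple(meta["shape"])
    data = np.fromfile(_data_path(base), dtype="<f4").reshape(shape).astype(float)
    grid = KGrid(
        k_values=np.linspace(meta["k_min"], meta["k_max"], shape[-1]),
        center_wavelength=meta["center_wavelength_um"],
        fwhm_bandwidth=meta["fwhm_bandwidth_um"],
    )
    extra = {k: v for k, v in meta.items() if k not in _RESERVED - {"pixel_pitch_x_um"}
             and k != "shape"}
    return RawSpectra(data=data, grid=grid, meta=extra)


def save_raw_hdf5(path: str | Path, raw: RawSpectra) -> None:
    """Export raw spectra to HDF5 with the (channel, frame, a_line, k) contract."""
    with h5py.File(path, "w") as f:
        f.create_dataset("spectra", data=raw.data.astype("<f4"))
        f.create_dataset("k_values", data=raw.grid.k_values)
        f.attrs["center_wavelength_um"] = raw.grid.center_wavelength
        f.attrs["fwhm_bandwidth_um"] = raw.grid.fwhm_bandwidth
        f.attrs["pixel_pitch_x_um"] = raw.pixel_pitch_x
        for key, val in raw.meta.items():
            if isinstance(val, (int, float, str, bool)):
                f.attrs[f"meta_{key}"] = val


def load_raw_hdf5(path: str | Path) -> RawSpectra:
    with h5py.File(path, "r") as f:
        data = np.asarray(f["spectra"], dtype=float)
        grid = KGrid(
            k_values=np.asarray(f["k_values"], dtype=float),
            center_wavelength=float(f.attrs["center_wavelength_um"]),
            fwhm_bandwidth=float(f.attrs["fwhm_bandwidth_um"]),
        )
        meta = {key[5:]: f.attrs[key] for key in f.attrs if key.startswith("meta_")}
        meta["pixel_pitch_x_um"] = float(f.attrs["pixel_pitch_x_um"])
    return RawSpectra(data=data, grid=grid, meta=meta)


def save_stokes_hdf5(path: str | Path, s: StokesField) -> None:
    """Export a Stokes field (band, frame, z, x) to HDF5."""
    with h5py.File(path, "w") as f:
        for name in ("i", "q", "u", "v"):
            f.create_dataset(name, data=getattr(s, name))


def load_stokes_hdf5(path: str | Path) -> StokesField:
    with h5py.File(path, "r") as f:
        return StokesField(**{name: np.asarray(f[name], dtype=float)
                              for name in ("i", "q", "u", "v")})
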