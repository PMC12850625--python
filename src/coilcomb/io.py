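"""HDF5 containers for CSI datasets and field sets, plus NIfTI map export.

There is no community-standard interchange format for raw multi-channel CSI,
so the package documents its own HDF5 layouts.  Complex arrays are stored as
float pairs (a trailing axis of length 2: real, imaginary).

CSI layout::

    /csi/data   float (nx, ny, nz, n_channels, n_fid, 2)
    /csi/noise  float (n_samples, n_channels, 2)        [optional]
    attrs: nucleus, dwell_s, fov_mm, voxel_mm, f0_mhz, carrier_ppm,
           axes ("x y z channel fid complex")

Field layout::

    /fields/e      float (n_channels, nx, ny, nz, 3, 2)  [optional]
    /fields/b1m    float (n_channels, nx, ny, nz, 2)     [optional]
    /fields/sigma  float (nx, ny, nz)                    [optional]
    attrs: frequency_hz, voxel_m
"""

from __future__ import annotations

import numpy as np

import h5py
import nibabel as nib

from .emeval import FieldSet
from .sigmodel import CsiDataset

__all__ = [
    "write_csi",
    "read_csi",
    "write_fieldset",
    "read_fieldset",
    "save_map_nifti",
]

_CSI_ATTRS = ("nucleus", "dwell_s", "fov_mm", "voxel_mm")


def _to_pairs(a: np.ndarray) -> np.ndarray:
    return np.stack([a.real, a.imag], axis=-1)


def _from_pairs(a: np.ndarray) -> np.ndarray:
    return a[..., 0] + 1j * a[..., 1]


def write_csi(path, ds: CsiDataset) -> None:
    """Write a :class:`CsiDataset` to the package's HDF5 layout (lossless)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("csi")
        g.create_dataset("data", data=_to_pairs(ds.data))
        if ds.noise_scan is not None:
            g.create_dataset("noise", data=_to_pairs(ds.noise_scan))
        g.attrs["nucleus"] = ds.nucleus
        g.attrs["dwell_s"] = ds.dwell_s
        g.attrs["fov_mm"] = np.asarray(ds.fov_mm, dtype=float)
        g.attrs["voxel_mm"] = np.asarray(ds.voxel_size_mm, dtype=float)
        g.attrs["f0_mhz"] = ds.f0_mhz
        g.attrs["carrier_ppm"] = ds.carrier_ppm
        g.attrs["axes"] = "x y z channel fid complex"


def read_csi(path) -> CsiDataset:
    """Read a :class:`CsiDataset`; errors name any missing dataset/attribute."""
    with h5py.File(path, "r") as f:
        if "csi" not in f or "data" not in f["csi"]:
            raise KeyError(f"{path}: missing required dataset /csi/data")
        g = f["csi"]
        for attr in _CSI_ATTRS:
            if attr not in g.attrs:
                raise KeyError(f"{path}: missing required attribute {attr!r} on /csi")
        data = _from_pairs(np.asarray(g["data"]))
        noise = _from_pairs(np.asarray(g["noise"])) if "noise" in g else None
        return CsiDataset(
            data=data,
            voxel_size_mm=tuple(g.attrs["voxel_mm"]),
            fov_mm=tuple(g.attrs["fov_mm"]),
            nucleus=str(g.attrs["nucleus"]),
            dwell_s=float(g.attrs["dwell_s"]),
            noise_scan=noise,
            f0_mhz=float(g.attrs["f0_mhz"]) if "f0_mhz" in g.attrs else None,
            carrier_ppm=float(g.attrs.get("carrier_ppm", 0.0)),
        )


def write_fieldset(path, fs: FieldSet) -> None:
    """Write a :class:`FieldSet` to the documented HDF5 layout."""
    with h5py.File(path, "w") as f:
        g = f.create_group("fields")
        if fs.e_fields is not None:
            g.create_dataset("e", data=_to_pairs(fs.e_fields))
        if fs.b1_minus is not None:
            g.create_dataset("b1m", data=_to_pairs(fs.b1_minus))
        if fs.conductivity is not None:
            g.create_dataset("sigma", data=np.asarray(fs.conductivity, dtype=float))
        g.attrs["frequency_hz"] = fs.frequency_hz
        g.attrs["voxel_m"] = fs.voxel_volume_m3 ** (1.0 / 3.0)


def read_fieldset(path) -> FieldSet:
    """Read a :class:`FieldSet` from the documented HDF5 layout."""
    with h5py.File(path, "r") as f:
        if "fields" not in f:
            raise KeyError(f"{path}: missing required group /fields")
        g = f["fields"]
        e = _from_pairs(np.asarray(g["e"])) if "e" in g else None
        b1m = _from_pairs(np.asarray(g["b1m"])) if "b1m" in g else None
        sigma = np.asarray(g["sigma"]) if "sigma" in g else None
        if "voxel_m" not in g.attrs:
            raise KeyError(f"{path}: missing required attribute 'voxel_m' on /fields")
        voxel_m = float(g.attrs["voxel_m"])
        return FieldSet(
            e_fields=e,
            b1_minus=b1m,
            conductivity=sigma,
            voxel_volume_m3=voxel_m**3,
            frequency_hz=float(g.attrs.get("frequency_hz", 0.0)),
        )


def save_map_nifti(path, volume: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    """Save a scalar 3D map (e.g. an SNR or ratio map) as NIfTI-1."""
    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise ValueError("NIfTI export expects a 3-D scalar map")
    affine = np.diag(list(voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))
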