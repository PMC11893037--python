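"""File formats: HDF5 raw k-space container and NIfTI image volumes.

The raw container is this package's exchange format for simulated (or
converted) acquisitions:

    /kdata    complex (coils, excitations, samples)
    /traj     float   (excitations, samples, 3)   cycles/mm
    /bellows  float   (excitations,)
    attrs: tr_s, fov_mm, res_mm, seed

Image-like data travel as NIfTI-1 with the voxel spacing in the affine;
4D is used for respiratory series and for deformation fields (3
displacement components).
"""

from __future__ import annotations

import numpy as np
import h5py
import nibabel as nib

from .phantom import BellowsTrace, KSpaceData
from .trajectory import TrajectorySet


class SchemaError(ValueError):
    """Raised when a raw container is missing or inconsistent."""


_REQUIRED = ("kdata", "traj", "bellows")


def write_raw(path, kdata: KSpaceData, seed: int | None = None,
              extra_attrs: dict | None = None) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("kdata", data=np.asarray(kdata.samples,
                                                   dtype=np.complex128))
        fh.create_dataset("traj", data=np.asarray(kdata.traj.coords,
                                                  dtype=np.float64))
        fh.create_dataset("bellows", data=kdata.bellows.values)
        fh.attrs["tr_s"] = float(kdata.bellows.dt_s)
        fh.attrs["fov_mm"] = float(kdata.traj.fov_mm)
        fh.attrs["res_mm"] = float(kdata.traj.res_mm)
        fh.attrs["noise_sd"] = float(kdata.noise_sd)
        if seed is not None:
            fh.attrs["seed"] = int(seed)
        for k, v in (extra_attrs or {}).items():
            fh.attrs[k] = v


def read_raw(path) -> KSpaceData:
    with h5py.File(path, "r") as fh:
        for name in _REQUIRED:
            if name not in fh:
                raise SchemaError(f"raw container missing dataset {name!r}")
        kdata = fh["kdata"][()]
        traj = fh["traj"][()]
        bellows = fh["bellows"][()]
        if kdata.shape[1:] != traj.shape[:2]:
            raise SchemaError(
                f"kdata {kdata.shape} inconsistent with traj {traj.shape}")
        if bellows.shape[0] != traj.shape[0]:
            raise SchemaError(
                f"bellows length {bellows.shape[0]} != excitations "
                f"{traj.shape[0]}")
        for attr in ("tr_s", "fov_mm", "res_mm"):
            if attr not in fh.attrs:
                raise SchemaError(f"raw container missing attribute {attr!r}")
        res_mm = float(fh.attrs["res_mm"])
        ts = TrajectorySet(
            coords=traj, excitation_order=np.arange(traj.shape[0]),
            kmax=1.0 / (2.0 * res_mm), fov_mm=float(fh.attrs["fov_mm"]),
            res_mm=res_mm)
        trace = BellowsTrace(values=bellows, dt_s=float(fh.attrs["tr_s"]))
        return KSpaceData(samples=kdata, traj=ts, bellows=trace,
                          noise_sd=float(fh.attrs.get("noise_sd", 0.0)))


def write_nifti(path, data: np.ndarray, voxel_mm: float | tuple = 1.0,
                descrip: str = "") -> None:
    """Write a 3D volume or 4D series/field; spacing goes in the affine."""
    if np.iscomplexobj(data):
        data = np.abs(data)
    spacing = ((voxel_mm,) * 3 if np.isscalar(voxel_mm)
               else tuple(voxel_mm))
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def read_nifti(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Returns (array, spacing_mm); 4D arrays keep their 4th axis."""
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float64), spacing


def write_series_nifti(path, volumes_bxyz: np.ndarray,
                       voxel_mm: float, descrip: str = "") -> None:
    """Respiratory series (B, nx, ny, nz) stored as x,y,z,B NIfTI."""
    data = np.moveaxis(np.abs(volumes_bxyz), 0, -1)
    write_nifti(path, data, voxel_mm, descrip)


def read_series_nifti(path) -> tuple[np.ndarray, float]:
    data, spacing = read_nifti(path)
    if data.ndim != 4:
        raise ValueError("expected a 4D series NIfTI")
    return np.moveaxis(data, -1, 0), spacing[0]
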