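"""File formats: NIfTI volumes and HDF5 sinogram containers."""

from __future__ import annotations

import os
from typing import Optional

import h5py
import nibabel as nib
import numpy as np

from .core import Sinogram, ValidationError, VoxelVolume
from .scanner import ScannerModel


def write_volume(volume: VoxelVolume, path) -> None:
    """Write a volume as NIfTI (float32 data, voxel sizes in the affine)."""
    vsz = volume.voxel_size_mm
    affine = np.diag(list(vsz[::-1]) + [1.0] * (4 - len(vsz)))
    img = nib.Nifti1Image(np.asarray(volume.values, dtype=np.float32).T,
                          affine)
    img.header.set_zooms(vsz[::-1])
    img.header["descrip"] = _descrip(volume)
    nib.save(img, str(path))


def _descrip(volume: VoxelVolume) -> bytes:
    tag = volume.role
    if volume.energy_kev is not None:
        tag += f"@{volume.energy_kev:g}keV"
    return tag.encode()[:79]


def read_volume(path, role: Optional[str] = None,
                energy_kev: Optional[float] = None) -> VoxelVolume:
    """Read a NIfTI volume; role/energy from the header unless overridden."""
    if not os.path.exists(str(path)):
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32).T
    zooms = img.header.get_zooms()[: data.ndim][::-1]
    descrip = bytes(img.header["descrip"].tobytes()).rstrip(b"\x00").decode(
        errors="replace")
    if role is None:
        tag = descrip.split("@")[0]
        role = tag if tag in ("mu_map", "activity", "hu", "label") else "activity"
    if energy_kev is None and "@" in descrip and role == "mu_map":
        energy_kev = float(descrip.split("@")[1].replace("keV", ""))
    return VoxelVolume(data.astype(np.float32), tuple(float(z) for z in zooms),
                       role, energy_kev)


SINO_DATASET = "sinogram"


def write_sinogram(sino: Sinogram, path) -> None:
    """Write a sinogram plus geometry metadata to an HDF5 container."""
    with h5py.File(str(path), "w") as f:
        d = f.create_dataset(SINO_DATASET, data=sino.values,
                             chunks=True, compression="gzip")
        d.attrs["content"] = sino.content
        d.attrs["has_tof"] = sino.has_tof
        if sino.energy_kev is not None:
            d.attrs["energy_kev"] = sino.energy_kev
        if sino.scanner is not None:
            sc = sino.scanner
            d.attrs["n_angles"] = sc.n_angles
            d.attrs["n_radial"] = sc.n_radial
            d.attrs["fov_mm"] = sc.fov_mm


def read_sinogram(path, scanner: Optional[ScannerModel] = None) -> Sinogram:
    """Read an HDF5 sinogram; validates geometry against ``scanner``."""
    if not os.path.exists(str(path)):
        raise FileNotFoundError(f"no such sinogram file: {path}")
    with h5py.File(str(path), "r") as f:
        d = f[SINO_DATASET]
        values = d[...]
        content = str(d.attrs["content"])
        has_tof = bool(d.attrs["has_tof"])
        energy = float(d.attrs["energy_kev"]) if "energy_kev" in d.attrs else None
        if scanner is not None and "n_angles" in d.attrs:
            if int(d.attrs["n_angles"]) != scanner.n_angles or \
                    int(d.attrs["n_radial"]) != scanner.n_radial:
                raise ValidationError(
                    "sinogram geometry does not match the scanner model")
    return Sinogram(values, content, has_tof, scanner, energy)
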