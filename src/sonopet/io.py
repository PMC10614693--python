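"""File formats: HDF5 RF container, NIfTI volumes/maps, CSV tables.

The RF container layout: datasets ``samples[burst, element, time]`` and
``element_positions_mm``, with scalar attributes ``fs_mhz``,
``speed_of_sound_m_s``, ``pressure_kpa``, ``seed`` and per-burst arrays
``burst_times_s`` and ``focus_index``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .field_model import PressureField
from .pam import PAMImage
from .pet_quant import PETVolume, ROIMask
from .synthetic import RFRecording

__all__ = [
    "save_rf",
    "load_rf",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "pam_to_nifti",
    "field_to_nifti",
    "pam_to_csv",
]


def save_rf(rec: RFRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=rec.samples, compression="gzip")
        f.create_dataset("element_positions_mm", data=rec.element_positions_mm)
        f.create_dataset("element_x_mm", data=rec.element_positions_mm[:, 0])
        f.create_dataset("burst_times_s", data=rec.burst_times_s)
        f.create_dataset("focus_index", data=rec.focus_index)
        f.attrs["fs_mhz"] = rec.sampling_rate_mhz
        f.attrs["speed_of_sound_m_s"] = rec.speed_of_sound_m_s
        f.attrs["pressure_kpa"] = rec.pressure_kpa
        if rec.seed is not None:
            f.attrs["seed"] = rec.seed
        if rec.animal_id is not None:
            f.attrs["animal_id"] = rec.animal_id


def load_rf(path) -> RFRecording:
    with h5py.File(path, "r") as f:
        return RFRecording(
            samples=f["samples"][()],
            sampling_rate_mhz=float(f.attrs["fs_mhz"]),
            element_positions_mm=f["element_positions_mm"][()],
            burst_times_s=f["burst_times_s"][()],
            focus_index=f["focus_index"][()],
            pressure_kpa=float(f.attrs.get("pressure_kpa", np.nan)),
            speed_of_sound_m_s=float(f.attrs.get("speed_of_sound_m_s", 1540.0)),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
            animal_id=str(f.attrs["animal_id"]) if "animal_id" in f.attrs else None,
        )


def _affine(voxel_mm) -> np.ndarray:
    aff = np.diag(list(voxel_mm) + [1.0])
    return aff


def save_volume(vol: PETVolume, path) -> None:
    """Write a PET volume as float32 NIfTI with mm voxel spacings; the
    units string is stored in the header description."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), _affine(vol.voxel_size_mm))
    img.header["descrip"] = vol.units.encode()
    nib.save(img, str(path))


def load_volume(path, units: str | None = None, **meta) -> PETVolume:
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    if units is None:
        descr = bytes(img.header["descrip"].tobytes()).split(b"\x00")[0].decode()
        units = descr if descr in ("Bq/cc", "%ID/cc") else "Bq/cc"
    return PETVolume(
        data=np.asarray(img.dataobj, dtype=np.float64),
        voxel_size_mm=voxel,
        units=units,
        **meta,
    )


def save_mask(roi: ROIMask, path) -> None:
    img = nib.Nifti1Image(roi.mask.astype(np.uint8), _affine(roi.voxel_size_mm))
    nib.save(img, str(path))


def load_mask(path, label: str = "custom") -> ROIMask:
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return ROIMask(mask=np.asarray(img.dataobj) > 0, voxel_size_mm=voxel, label=label)


def pam_to_nifti(image: PAMImage, path) -> None:
    """Export a PAM map as a (lateral, depth, 1) NIfTI volume."""
    dl, dz = image.pixel_mm
    data = image.intensity[:, :, None].astype(np.float32)
    img = nib.Nifti1Image(data, _affine((dl or 1.0, dz or 1.0, 1.0)))
    nib.save(img, str(path))


def pam_to_csv(image: PAMImage, path) -> None:
    """CSV grid: first row depth coordinates, first column lateral."""
    with open(path, "w") as fh:
        fh.write("lateral_mm\\depth_mm," + ",".join(f"{z:.4f}" for z in image.depth_mm) + "\n")
        for x, row in zip(image.lateral_mm, image.intensity):
            fh.write(f"{x:.4f}," + ",".join(f"{v:.8g}" for v in row) + "\n")


def field_to_nifti(field: PressureField, path) -> None:
    """Export a simulated pressure-amplitude field for inspection."""
    img = nib.Nifti1Image(field.amplitude.astype(np.float32), _affine(field.grid.spacing_mm))
    nib.save(img, str(path))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
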