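"""File formats: float32 TIFF / NIfTI images, HDF5 sinograms with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import tifffile

from .geometry import Image2D, ProjectionGeometry, Sinogram

__all__ = [
    "save_image",
    "load_image",
    "save_sinogram",
    "load_sinogram",
]


def save_image(image: Image2D, path: str | Path) -> None:
    """Write a single-channel float32 image as .tif/.tiff or .nii/.nii.gz."""
    path = Path(path)
    v = image.values.astype(np.float32)
    if path.suffix in (".tif", ".tiff"):
        tifffile.imwrite(
            path, v, resolution=(1.0 / image.pixel_size, 1.0 / image.pixel_size)
        )
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps({"pixel_size_mm": image.pixel_size})
        )
    elif path.name.endswith((".nii", ".nii.gz")):
        affine = np.diag([image.pixel_size, image.pixel_size, 1.0, 1.0])
        nib.save(nib.Nifti1Image(v[:, :, None], affine), str(path))
    else:
        raise ValueError(f"unsupported image format: {path.name}")


def load_image(path: str | Path) -> Image2D:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        v = np.asarray(tifffile.imread(path), dtype=np.float64)
        sidecar = path.with_suffix(path.suffix + ".json")
        ps = 1.0
        if sidecar.exists():
            ps = float(json.loads(sidecar.read_text())["pixel_size_mm"])
        return Image2D(v, ps)
    if path.name.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        v = np.asarray(img.dataobj, dtype=np.float64)
        if v.ndim == 3:
            v = v[:, :, 0]
        return Image2D(v, float(abs(img.affine[0, 0])) or 1.0)
    raise ValueError(f"unsupported image format: {path.name}")


def save_sinogram(
    sino: Sinogram, path: str | Path, geom: ProjectionGeometry | None = None
) -> None:
    """HDF5 container (`values`, `angles` + attributes) with a JSON sidecar."""
    path = Path(path)
    meta = {}
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=sino.values)
        f.create_dataset("angles", data=sino.angles)
        if geom is not None:
            f.attrs["det_spacing"] = geom.det_spacing
            f.attrs["beam_type"] = geom.beam_type
            meta = {"det_spacing": geom.det_spacing, "beam_type": geom.beam_type}
    meta.update({"n_angles": int(sino.n_angles), "n_det": int(sino.n_det)})
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_sinogram(path: str | Path) -> Sinogram:
    with h5py.File(path, "r") as f:
        return Sinogram(f["values"][()], f["angles"][()])
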