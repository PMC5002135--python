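"""Readers and writers for the package's on-disk formats.

Images travel as NIfTI (``.nii`` / ``.nii.gz``) or 8/16-bit grayscale
PNG; k-space data as an HDF5 container with ``/coeffs_real``,
``/coeffs_imag`` and ``/mask`` datasets; phantoms as an image + label
pair with a JSON sidecar recording seed and geometry.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
from PIL import Image

from .kspace_ops import KSpaceData, SamplingMask
from .phantom import PhantomImage

__all__ = [
    "read_image",
    "write_image",
    "save_kspace",
    "load_kspace",
    "save_phantom",
    "save_recon_metadata",
]


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2-D grayscale image as a float array.

    PNG intensities are scaled to [0, 1] by the dtype maximum; NIfTI
    data are returned as stored (a 3-D volume with a singleton last
    axis is squeezed).
    """
    path = Path(path)
    if _is_nifti(path):
        data = np.asanyarray(nib.load(path).dataobj).squeeze()
        if data.ndim != 2:
            raise ValueError(f"{path} does not contain a single 2-D slice")
        return np.asarray(data, dtype=float)
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"{path} is not a grayscale image")
    if arr.dtype == np.uint8:
        return arr / 255.0
    if arr.dtype in (np.uint16, np.int32):  # PIL mode I;16 loads as int32
        return arr / 65535.0
    return arr.astype(float)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a real 2-D image to NIfTI (as float) or PNG (16-bit, rescaled)."""
    path = Path(path)
    arr = np.asarray(image, dtype=float)
    if _is_nifti(path):
        nib.save(nib.Nifti1Image(arr.astype(np.float32), affine=np.eye(4)), path)
        return
    lo, hi = arr.min(), arr.max()
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    Image.fromarray((scaled * 65535).astype(np.uint16)).save(path)


def save_kspace(path: str | Path, kdata: KSpaceData) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coeffs_real", data=kdata.coeffs.real)
        f.create_dataset("coeffs_imag", data=kdata.coeffs.imag)
        f.create_dataset("mask", data=kdata.mask.grid)
        f.attrs["height"], f.attrs["width"] = kdata.shape
        f.attrs["rate"] = kdata.mask.rate


def load_kspace(path: str | Path) -> KSpaceData:
    with h5py.File(path, "r") as f:
        coeffs = f["coeffs_real"][()] + 1j * f["coeffs_imag"][()]
        mask = SamplingMask(f["mask"][()])
    return KSpaceData(coeffs=coeffs, mask=mask)


def save_phantom(prefix: str | Path, phantom: PhantomImage, fmt: str = "nii.gz") -> None:
    """Write image, labels, and a JSON sidecar under a common prefix."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_image(prefix.with_name(prefix.name + f"_image.{fmt}"), phantom.image)
    if fmt.startswith("nii"):
        nib.save(
            nib.Nifti1Image(phantom.labels.astype(np.int16), affine=np.eye(4)),
            prefix.with_name(prefix.name + f"_labels.{fmt}"),
        )
    else:
        Image.fromarray(phantom.labels.astype(np.uint8)).save(
            prefix.with_name(prefix.name + f"_labels.{fmt}")
        )
    sidecar = dict(phantom.meta)
    sidecar["shape"] = list(phantom.shape)
    prefix.with_name(prefix.name + "_meta.json").write_text(json.dumps(sidecar, indent=2))


def save_recon_metadata(path: str | Path, **fields) -> None:
    """Dump run provenance (configs, seeds, convergence info) as JSON."""
    Path(path).write_text(json.dumps(fields, indent=2, default=str))
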