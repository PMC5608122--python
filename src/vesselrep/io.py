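"""NIfTI image and YAML config helpers.

Images are 2D magnitude slices stored as NIfTI with the in-plane pixel
spacing in the header; configs round-trip through YAML.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = ["write_image", "read_image", "load_yaml", "dump_yaml"]


def write_image(path: str | Path, array: np.ndarray, pixel_spacing_mm: float) -> Path:
    """Write a 2D array as NIfTI (.nii or .nii.gz), spacing in the affine."""
    path = Path(path)
    affine = np.diag([pixel_spacing_mm, pixel_spacing_mm, 1.0, 1.0])
    img = nib.Nifti1Image(np.asarray(array, dtype=np.float32)[:, :, None], affine)
    img.header.set_zooms((pixel_spacing_mm, pixel_spacing_mm, 1.0))
    nib.save(img, str(path))
    return path


def read_image(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a 2D NIfTI slice; returns (array, pixel_spacing_mm)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError(f"{path}: expected a single 2D slice")
        data = data[:, :, 0]
    zooms = img.header.get_zooms()
    return data, float(zooms[0])


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(doc: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
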