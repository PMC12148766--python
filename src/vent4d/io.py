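"""NIfTI-1 reading/writing for the package's volume types.

Volumes are stored with a diagonal affine built from (spacing, origin);
displacement fields are 4-D with the last dimension holding the (x, y, z)
components in mm; masks are uint8.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .core import DisplacementField, FunctionImage, HUImage, LungMask
from .phantom import DoseGrid

__all__ = [
    "save_volume",
    "load_hu",
    "load_mask",
    "load_field",
    "load_function",
    "load_dose",
    "save_field",
]


def _affine(spacing, origin):
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_volume(path, values, spacing, origin, dtype=None):
    arr = np.asarray(values)
    if dtype is not None:
        arr = arr.astype(dtype)
    nib.save(nib.Nifti1Image(arr, _affine(spacing, origin)), str(path))


def save_field(path, field: DisplacementField):
    save_volume(path, field.u, field.spacing, field.origin)


def _grid_of(img: nib.Nifti1Image):
    aff = img.affine
    spacing = np.abs(np.diag(aff)[:3])
    origin = aff[:3, 3]
    return spacing, origin


def load_hu(path) -> HUImage:
    img = nib.load(str(path))
    spacing, origin = _grid_of(img)
    return HUImage(np.asarray(img.dataobj, dtype=float), spacing, origin)


def load_mask(path) -> LungMask:
    img = nib.load(str(path))
    spacing, origin = _grid_of(img)
    return LungMask(np.asarray(img.dataobj) > 0, spacing, origin)


def load_field(path) -> DisplacementField:
    img = nib.load(str(path))
    spacing, origin = _grid_of(img)
    u = np.asarray(img.dataobj, dtype=float)
    if u.ndim == 5:  # some writers insert a singleton time axis
        u = u[:, :, :, 0, :]
    return DisplacementField(u, spacing, origin)


def load_function(path, kind: str) -> FunctionImage:
    img = nib.load(str(path))
    spacing, origin = _grid_of(img)
    return FunctionImage(np.asarray(img.dataobj, dtype=float), kind, spacing, origin)


def load_dose(path) -> DoseGrid:
    img = nib.load(str(path))
    spacing, origin = _grid_of(img)
    return DoseGrid(np.asarray(img.dataobj, dtype=float), spacing, origin)
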