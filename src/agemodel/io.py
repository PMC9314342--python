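"""NIfTI I/O for images and vector fields.

Scalar images map to plain 2D/3D NIfTI volumes.  Vector fields are
stored 5D with the vector running along the last axis (NIfTI vector
intent), component order matching the grid axis order (x, y[, z]).
Uncompressed ``.nii`` is the default output format so that repeated
saves of the same model are byte-identical (gzip embeds a timestamp);
``.nii.gz`` is accepted transparently on load.
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

from .grid import DisplacementField, ScalarImage, VectorField

__all__ = ["save_image", "load_image", "save_vector_field", "load_vector_field"]

_VECTOR_INTENT = 1007  # NIFTI_INTENT_VECTOR


def _affine(spacing, ndim):
    aff = np.eye(4)
    for i in range(ndim):
        aff[i, i] = spacing[i]
    return aff


def save_image(image: ScalarImage, path) -> None:
    img = nib.Nifti1Image(image.data, _affine(image.spacing, image.ndim))
    nib.save(img, str(path))


def load_image(path) -> ScalarImage:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data)
    zooms = img.header.get_zooms()[: data.ndim]
    return ScalarImage(data, tuple(float(z) for z in zooms))


def save_vector_field(field: VectorField, path) -> None:
    d = field.ndim
    grid = field.grid_shape
    # 5D layout (X, Y, Z, 1, d); 2D grids get a singleton third axis
    arr = field.data.reshape(grid + (1,) * (3 - d) + (1, d))
    img = nib.Nifti1Image(arr, _affine(field.spacing, d))
    img.header.set_intent(_VECTOR_INTENT)
    nib.save(img, str(path))


def load_vector_field(path, as_displacement: bool = False,
                      diffeomorphic: bool = False):
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    d = arr.shape[-1]
    grid = tuple(s for s in arr.shape[:-1] if s != 1) or arr.shape[:d]
    arr = arr.reshape(grid + (d,))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:d])
    if as_displacement:
        return DisplacementField(arr, zooms, diffeomorphic=diffeomorphic)
    return VectorField(arr, zooms)
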