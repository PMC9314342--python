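"""Grid-based images and vector fields: the substrate of the aging model.

All algebra in this package runs on the voxel grid.  Coordinates are
0-based voxel indices and every vector quantity (velocities,
displacements) is stored in **voxel units**; the 0.5-voxel BCH
subdivision rule is natural in these units.  Physical spacing is carried
through I/O as metadata but is not used to rescale vectors — a
documented limitation for strongly anisotropic data.

Conventions fixed here and relied on everywhere else:

* ``warp(image, disp)`` samples ``image`` at ``x + u(x)`` (pullback-style
  resampling map).
* Out-of-grid samples use border replication (clamp), which avoids
  spurious boundary gradients when fields are composed repeatedly.
* Derivatives are central differences on the interior, one-sided at the
  borders (``numpy.gradient``).
* Vector arrays have shape ``(*grid_shape, d)`` with component order
  matching axis order.
"""

from __future__ import annotations

import dataclasses
from functools import lru_cache

import numpy as np
from scipy import ndimage

__all__ = [
    "GridMismatchError",
    "ScalarImage",
    "VectorField",
    "DisplacementField",
    "warp",
    "compose",
    "field_norm",
    "lie_bracket",
    "jacobian_determinant",
    "zero_displacement",
    "interior",
]


class GridMismatchError(ValueError):
    """Two grid objects that must share a grid do not."""


def _as_float(data) -> np.ndarray:
    arr = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise ValueError("grid data must be finite")
    return arr


@dataclasses.dataclass
class ScalarImage:
    """An intensity volume on a regular 2D or 3D grid.

    Parameters
    ----------
    data : ndarray
        Real-valued array, 2D or 3D.
    spacing : tuple of float, optional
        Physical size per voxel along each axis; defaults to 1.0.
    origin : tuple of float, optional
        Physical position of voxel index 0.
    """

    data: np.ndarray
    spacing: tuple = None
    origin: tuple = None

    def __post_init__(self):
        self.data = _as_float(self.data)
        if self.data.ndim not in (2, 3):
            raise ValueError(f"expected a 2D or 3D image, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        if self.spacing is None:
            self.spacing = (1.0,) * self.data.ndim
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.data.ndim or any(s <= 0 for s in self.spacing):
            raise ValueError(f"invalid spacing {self.spacing} for ndim={self.data.ndim}")
        if self.origin is not None:
            self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def copy(self) -> "ScalarImage":
        return ScalarImage(self.data.copy(), self.spacing, self.origin)


@dataclasses.dataclass
class VectorField:
    """A d-component vector per voxel on a d-dimensional grid.

    ``data`` has shape ``(*grid_shape, d)``; values are in voxel units.
    """

    data: np.ndarray
    spacing: tuple = None

    def __post_init__(self):
        self.data = _as_float(self.data)
        d = self.data.ndim - 1
        if d not in (2, 3) or self.data.shape[-1] != d:
            raise ValueError(
                f"vector data of shape {self.data.shape} does not match a "
                "(*grid, d) layout with d in (2, 3)"
            )
        if self.spacing is None:
            self.spacing = (1.0,) * d
        self.spacing = tuple(float(s) for s in self.spacing)

    @property
    def grid_shape(self):
        return self.data.shape[:-1]

    @property
    def ndim(self):
        return self.data.ndim - 1

    def copy(self):
        return type(self)(self.data.copy(), self.spacing)


@dataclasses.dataclass
class DisplacementField(VectorField):
    """Discretized spatial map φ(x) = x + u(x), stored as displacement u.

    ``diffeomorphic=True`` marks fields produced by a group exponential,
    whose interior Jacobian determinant is strictly positive.
    """

    diffeomorphic: bool = False

    def copy(self):
        return DisplacementField(self.data.copy(), self.spacing, self.diffeomorphic)


@lru_cache(maxsize=32)
def _identity_coords(shape) -> np.ndarray:
    """Voxel-index coordinate grid of shape (d, *shape)."""
    return np.indices(shape, dtype=np.float64)


def _check_same_grid(a_shape, b_shape):
    if tuple(a_shape) != tuple(b_shape):
        raise GridMismatchError(f"grid shapes differ: {tuple(a_shape)} vs {tuple(b_shape)}")


def _sample_scalar(arr, coords, order=1):
    return ndimage.map_coordinates(arr, coords, order=order, mode="nearest")


def _sample_vector(u, coords):
    """Linearly resample vector array u (*grid, d) at coords (d, *grid)."""
    d = u.shape[-1]
    out = np.empty_like(u)
    for i in range(d):
        out[..., i] = ndimage.map_coordinates(u[..., i], coords, order=1, mode="nearest")
    return out


def zero_displacement(shape, spacing=None) -> DisplacementField:
    shape = tuple(shape)
    return DisplacementField(
        np.zeros(shape + (len(shape),)), spacing, diffeomorphic=True
    )


def warp(image: ScalarImage, disp: DisplacementField, interp: str = "linear") -> ScalarImage:
    """Resample ``image`` through ``disp``: output(x) = image(x + u(x)).

    ``interp`` is ``"linear"`` for intensity images or ``"nearest"`` for
    label images.  Warping with an exactly-zero field returns the input
    bit-exactly.
    """
    _check_same_grid(image.shape, disp.grid_shape)
    if interp not in ("linear", "nearest"):
        raise ValueError(f"unknown interpolator {interp!r}")
    u = disp.data
    if not u.any():
        return ScalarImage(image.data.copy(), image.spacing, image.origin)
    coords = _identity_coords(image.shape) + np.moveaxis(u, -1, 0)
    order = 1 if interp == "linear" else 0
    out = _sample_scalar(image.data, coords, order=order)
    return ScalarImage(out, image.spacing, image.origin)


def compose(d1: DisplacementField, d2: DisplacementField) -> DisplacementField:
    """Displacement of φ1∘φ2: u(x) = u2(x) + u1(x + u2(x)).

    With the pullback warp convention, ``warp(I, compose(d1, d2))``
    equals ``warp(warp(I, d2), d1)`` up to interpolation error.
    """
    _check_same_grid(d1.grid_shape, d2.grid_shape)
    u1, u2 = d1.data, d2.data
    if not u2.any():
        return d1.copy()
    if not u1.any():
        return d2.copy()
    coords = _identity_coords(d2.grid_shape) + np.moveaxis(u2, -1, 0)
    out = u2 + _sample_vector(u1, coords)
    return DisplacementField(out, d1.spacing,
                             diffeomorphic=d1.diffeomorphic and d2.diffeomorphic)


def field_norm(field) -> float:
    """Frobenius norm over all voxels and components: sqrt(ΣΣ|a_ij|²).

    This is the magnitude used both for reference-template selection and
    for the aging-rate ratios.  Accepts a VectorField, DisplacementField
    or bare ndarray.
    """
    data = field if isinstance(field, np.ndarray) else field.data
    return float(np.sqrt(np.sum(np.square(np.asarray(data), dtype=np.float64))))


def _component_gradients(u):
    """List over components i of list over axes j of ∂u_i/∂x_j."""
    d = u.shape[-1]
    return [np.gradient(u[..., i]) for i in range(d)]


def lie_bracket(u: VectorField, v: VectorField) -> VectorField:
    """Lie bracket [u, v](x) = (Du)(x)·v(x) − (Dv)(x)·u(x).

    The sign convention is fixed so that u + v + ½[u, v] is the
    second-order BCH approximation of log(exp(u)∘exp(v)) under this
    package's composition convention.  Derivatives are central on the
    interior, one-sided at borders.
    """
    _check_same_grid(u.grid_shape, v.grid_shape)
    ua, va = u.data, v.data
    d = ua.shape[-1]
    gu = _component_gradients(ua)
    gv = _component_gradients(va)
    out = np.zeros_like(ua)
    for i in range(d):
        acc = out[..., i]
        for j in range(d):
            acc += gu[i][j] * va[..., j] - gv[i][j] * ua[..., j]
    return VectorField(out, u.spacing)


def jacobian_determinant(disp: DisplacementField) -> ScalarImage:
    """Per-voxel det(I + Du) of the map φ(x) = x + u(x).

    Strict positivity on the interior certifies local topology
    preservation (no folding).
    """
    u = disp.data
    d = u.shape[-1]
    g = _component_gradients(u)  # g[i][j] = ∂u_i/∂x_j
    J = [[g[i][j] + (1.0 if i == j else 0.0) for j in range(d)] for i in range(d)]
    if d == 2:
        det = J[0][0] * J[1][1] - J[0][1] * J[1][0]
    else:
        det = (
            J[0][0] * (J[1][1] * J[2][2] - J[1][2] * J[2][1])
            - J[0][1] * (J[1][0] * J[2][2] - J[1][2] * J[2][0])
            + J[0][2] * (J[1][0] * J[2][1] - J[1][1] * J[2][0])
        )
    return ScalarImage(det, disp.spacing)


def interior(arr_or_image, margin: int = 1):
    """View of the interior of an array/image, ``margin`` voxels from every border."""
    if isinstance(arr_or_image, np.ndarray):
        data = arr_or_image
        ndim = data.ndim if data.shape[-1] != data.ndim - 1 else data.ndim - 1
    else:
        data = arr_or_image.data
        ndim = (len(arr_or_image.grid_shape)
                if hasattr(arr_or_image, "grid_shape") else data.ndim)
    sl = (slice(margin, -margin),) * ndim
    return data[sl]
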