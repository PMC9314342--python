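"""Lie-group numerics on stationary velocity fields (SVFs).

An SVF v parameterizes a diffeomorphism through the group exponential
φ = exp(v) (log-Euclidean framework).  Compositions of exponentials are
folded back into a single SVF with the Baker–Campbell–Hausdorff (BCH)
series

    log(exp(u) exp(v)) = u + v + ½[u,v] + 1/12([u,[u,v]] + [v,[v,u]]) + …

truncated at the double-commutator terms by default.  Because the BCH
approximation is only valid for small fields, a field being folded in is
first split into n equal parts so that its maximum voxelwise magnitude
divided by n stays below half a voxel.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .grid import (
    DisplacementField,
    GridMismatchError,
    VectorField,
    compose,
    field_norm,
    lie_bracket,
    _identity_coords,
    _sample_vector,
)

__all__ = [
    "SVF",
    "ConvergenceError",
    "group_exp",
    "group_log",
    "bch_pair",
    "bch_sequence",
    "invert_displacement",
    "max_voxel_magnitude",
]

#: BCH subdivision / scaling-and-squaring step bound, in voxels.
MAX_STEP = 0.5


class ConvergenceError(RuntimeError):
    """An iterative scheme failed to contract; carries the residual norm."""

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual


@dataclasses.dataclass
class SVF:
    """A stationary velocity field with free-form provenance tags."""

    field: VectorField
    meta: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        if isinstance(self.field, np.ndarray):
            self.field = VectorField(self.field)

    @property
    def data(self) -> np.ndarray:
        return self.field.data

    @property
    def grid_shape(self):
        return self.field.grid_shape

    def scaled(self, s: float) -> "SVF":
        """s·v — exact scaling in the one-parameter subgroup."""
        return SVF(VectorField(self.data * float(s), self.field.spacing))

    @classmethod
    def zeros(cls, grid_shape, spacing=None) -> "SVF":
        shape = tuple(grid_shape)
        return cls(VectorField(np.zeros(shape + (len(shape),)), spacing))


def max_voxel_magnitude(field) -> float:
    """Maximum voxelwise Euclidean vector magnitude."""
    data = field if isinstance(field, np.ndarray) else field.data
    data = np.asarray(data)
    if data.size == 0:
        return 0.0
    return float(np.sqrt(np.sum(data**2, axis=-1)).max())


def group_exp(v: SVF, max_step: float = MAX_STEP) -> DisplacementField:
    """Group exponential exp(v) by scaling and squaring.

    The smallest K ≥ 0 with max|v|/2^K < ``max_step`` voxels is chosen;
    v/2^K is then self-composed K times.  The result is flagged
    diffeomorphic: every squaring composes two near-identity maps, so
    the interior Jacobian determinant stays strictly positive.
    """
    if isinstance(v, (VectorField, np.ndarray)):
        v = SVF(v if isinstance(v, VectorField) else VectorField(v))
    m = max_voxel_magnitude(v)
    K = 0
    while m / (2**K) >= max_step:
        K += 1
    disp = DisplacementField(v.data / (2**K), v.field.spacing)
    for _ in range(K):
        disp = compose(disp, disp)
    disp.diffeomorphic = True
    return disp


def invert_displacement(disp: DisplacementField, iters: int = 20) -> DisplacementField:
    """Numerical inverse of φ(x) = x + u(x) by fixed point u_inv = −u(x + u_inv)."""
    u = disp.data
    ident = _identity_coords(disp.grid_shape)
    u_inv = np.zeros_like(u)
    for _ in range(iters):
        coords = ident + np.moveaxis(u_inv, -1, 0)
        u_inv = -_sample_vector(u, coords)
    return DisplacementField(u_inv, disp.spacing, diffeomorphic=disp.diffeomorphic)


def _residual(disp: DisplacementField, v: SVF) -> DisplacementField:
    """disp ⊖ exp(v): displacement of disp composed with the inverse of exp(v)."""
    return compose(disp, invert_displacement(group_exp(v)))


def group_log(
    disp: DisplacementField,
    iters: int = 40,
    tol: float = 1e-3,
    delta: float = 0.5,
    max_input: float = 5.0,
) -> SVF:
    """Discrete group logarithm by damped fixed-point iteration.

    Starting from v₀ = u, iterate v ← v + δ·(disp ⊖ exp(v)) where ⊖ is
    the displacement of the composition with the numerical inverse.  The
    iteration stops when the root-mean-square update per voxel falls
    below ``tol`` (voxels) or after ``iters`` iterations.  The residual
    norm ‖exp(v) ⊖ disp‖ is reported in the returned SVF's meta.

    Raises
    ------
    ConvergenceError
        If the input is outside the contraction domain (max|u| >
        ``max_input`` voxels) or the final RMS residual exceeds half a
        voxel, i.e. the fixed point clearly failed to contract.
    """
    m = max_voxel_magnitude(disp)
    if m > max_input:
        raise ConvergenceError(
            f"displacement too large for the log map: max |u| = {m:.3f} voxels "
            f"exceeds the contraction bound {max_input}", residual=m)
    n_vox = math.sqrt(max(disp.data.size // disp.data.shape[-1], 1))
    v = SVF(VectorField(disp.data.copy(), disp.spacing))
    res_norm = np.inf
    for _ in range(iters):
        r = _residual(disp, v)
        res_norm = field_norm(r)
        if delta * res_norm / n_vox < tol:
            break
        v = SVF(VectorField(v.data + delta * r.data, disp.spacing))
    final = _residual(disp, v)
    res_norm = field_norm(final)
    rms = res_norm / n_vox
    if rms > 0.5:
        raise ConvergenceError(
            f"group_log did not converge: RMS residual {rms:.3f} voxels",
            residual=res_norm)
    v.meta["log_residual_norm"] = res_norm
    return v


def bch_pair(u: SVF, v: SVF, order: int = 3) -> SVF:
    """BCH approximation of log(exp(u)∘exp(v)) truncated at ``order``.

    order 1: u + v; order 2: + ½[u,v]; order 3 (default): +
    1/12([u,[u,v]] + [v,[v,u]]).
    """
    if order not in (1, 2, 3):
        raise ValueError(f"invalid BCH order {order}; expected 1, 2 or 3")
    if tuple(u.grid_shape) != tuple(v.grid_shape):
        raise GridMismatchError(
            f"grid shapes differ: {tuple(u.grid_shape)} vs {tuple(v.grid_shape)}")
    uf, vf = u.field, v.field
    w = uf.data + vf.data
    if order >= 2:
        w = w + 0.5 * lie_bracket(uf, vf).data
    if order >= 3:
        uuv = lie_bracket(uf, lie_bracket(uf, vf))
        vvu = lie_bracket(vf, lie_bracket(vf, uf))
        w = w + (uuv.data + vvu.data) / 12.0
    return SVF(VectorField(w, uf.spacing))


def _subdivided_fold(acc: SVF, v: SVF, order: int, max_step: float) -> SVF:
    """Fold v into acc by BCH, splitting v so each part stays below max_step voxels."""
    m = max_voxel_magnitude(v)
    n = max(1, int(math.floor(m / max_step)) + 1)
    part = v.scaled(1.0 / n)
    for _ in range(n):
        acc = bch_pair(acc, part, order)
    return acc


def bch_sequence(svfs, order: int = 3, max_step: float = MAX_STEP) -> SVF:
    """Left fold of an ordered SVF list into a single SVF via BCH.

    acc starts as the first element; each subsequent v_j is split into n
    equal parts with max voxelwise |v_j|/n < ``max_step`` and folded in
    n times with ``bch_pair``.
    """
    svfs = list(svfs)
    if not svfs:
        raise ValueError("bch_sequence requires a non-empty list of SVFs")
    shape = tuple(svfs[0].grid_shape)
    for s in svfs[1:]:
        if tuple(s.grid_shape) != shape:
            raise GridMismatchError(
                f"grid shapes differ: {shape} vs {tuple(s.grid_shape)}")
    acc = SVF(VectorField(svfs[0].data.copy(), svfs[0].field.spacing))
    for v in svfs[1:]:
        acc = _subdivided_fold(acc, v, order, max_step)
    return acc
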