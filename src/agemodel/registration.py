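"""Affine pre-alignment, SVF (log-demons) registration, groupwise template.

The pairwise nonrigid step is a log-demons scheme: it is SVF-native, so
every registration result is directly a stationary velocity field.  The
demons force is the classic intensity-difference force with Thirion's
normalization; the update is smoothed with a *fluid* Gaussian, folded
into the current velocity with a second-order BCH step (so the estimate
remains a single SVF), and the velocity is then smoothed with a
*diffusion* Gaussian.  The smoothing deliberately caps the deformation
scale that can be captured: large inter-subject (non-aging) differences
are rejected at this stage by construction.

Directions: ``svf_register(moving, fixed)`` returns v such that
``warp(moving, group_exp(v)) ≈ fixed``.  Every call site in this package
names moving/fixed explicitly.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage, optimize

from .grid import GridMismatchError, ScalarImage, VectorField, warp
from .svf import SVF, bch_pair, group_exp

__all__ = [
    "AffineTransform",
    "RegistrationParams",
    "affine_register",
    "apply_affine",
    "svf_register",
    "build_global_template",
]


@dataclasses.dataclass
class AffineTransform:
    """Affine resampling map in voxel coordinates, taken about the grid center.

    ``apply_affine(moving, A) ≈ fixed`` samples moving at
    m(x) = matrix·(x − c) + c + offset, with c the grid center.
    """

    matrix: np.ndarray
    offset: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.offset = np.asarray(self.offset, dtype=np.float64)
        d = self.offset.shape[0]
        if self.matrix.shape != (d, d):
            raise ValueError(f"matrix shape {self.matrix.shape} does not match offset dim {d}")
        if abs(np.linalg.det(self.matrix)) <= 1e-8:
            raise ValueError("affine matrix is numerically singular")

    @classmethod
    def identity(cls, d: int) -> "AffineTransform":
        return cls(np.eye(d), np.zeros(d))


@dataclasses.dataclass
class RegistrationParams:
    """Tunable knobs of the pairwise registrations.

    levels
        Number of pyramid levels (coarsest is grid/2^(levels−1)).
    iterations
        Demons iterations per level (same budget at every level; early
        stopping on an MSE plateau usually cuts this down).
    fluid_sigma, diffusion_sigma
        Gaussian smoothing (voxels) of the update and of the velocity
        field.  These set the scale below which deformations are
        captured.
    update_rule
        ``"bch"`` (second-order BCH fold, default) or ``"additive"``.
    tol
        Relative MSE-improvement threshold for the plateau early stop.
    """

    levels: int = 3
    iterations: int = 50
    fluid_sigma: float = 2.0
    diffusion_sigma: float = 1.5
    update_rule: str = "bch"
    tol: float = 1e-4
    affine_maxiter: int = 60

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.fluid_sigma < 0 or self.diffusion_sigma < 0:
            raise ValueError("smoothing sigmas must be >= 0")
        if self.update_rule not in ("bch", "additive"):
            raise ValueError(f"unknown update rule {self.update_rule!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "RegistrationParams":
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# pyramids

def _downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    smoothed = ndimage.gaussian_filter(arr, sigma=factor / 2.0)
    target = tuple(max(1, int(round(s / factor))) for s in arr.shape)
    zoom = [t / s for t, s in zip(target, arr.shape)]
    return ndimage.zoom(smoothed, zoom, order=1)


def _upsample_velocity(v: np.ndarray, target_shape) -> np.ndarray:
    """Resample a velocity array to a finer grid, rescaling voxel units."""
    src_shape = v.shape[:-1]
    d = v.shape[-1]
    zoom = [t / s for t, s in zip(target_shape, src_shape)]
    out = np.empty(tuple(target_shape) + (d,))
    for i in range(d):
        out[..., i] = ndimage.zoom(v[..., i], zoom, order=1) * zoom[i]
    return out


# ---------------------------------------------------------------------------
# affine

def apply_affine(moving: ScalarImage, transform: AffineTransform,
                 interp: str = "linear") -> ScalarImage:
    """Resample moving through the affine map (center-relative convention)."""
    d = moving.ndim
    c = (np.asarray(moving.shape, dtype=np.float64) - 1) / 2.0
    # ndimage.affine_transform: output[x] = input[matrix @ x + offset]
    offset = c - transform.matrix @ c + transform.offset
    order = 1 if interp == "linear" else 0
    out = ndimage.affine_transform(
        moving.data, transform.matrix, offset=offset, order=order, mode="nearest")
    return ScalarImage(out, moving.spacing, moving.origin)


def _affine_mse(params, moving_arr, fixed_arr, d):
    matrix = np.eye(d) + params[: d * d].reshape(d, d)
    offset = params[d * d:]
    c = (np.asarray(moving_arr.shape, dtype=np.float64) - 1) / 2.0
    out = ndimage.affine_transform(
        moving_arr, matrix, offset=c - matrix @ c + offset, order=1, mode="nearest")
    return float(np.mean((out - fixed_arr) ** 2))


def affine_register(moving: ScalarImage, fixed: ScalarImage,
                    params: RegistrationParams | None = None) -> AffineTransform:
    """Full-affine alignment minimizing MSE over a multiresolution schedule.

    Powell's derivative-free method on the (d² + d)-parameter full
    affine, coarse-to-fine; deterministic for fixed inputs and params.
    """
    params = params or RegistrationParams()
    if moving.ndim != fixed.ndim:
        raise GridMismatchError(
            f"dimensionality differs: {moving.ndim}D vs {fixed.ndim}D")
    if np.ptp(moving.data) == 0 or np.ptp(fixed.data) == 0:
        raise ValueError("cannot affine-register constant (degenerate) images")
    d = moving.ndim
    x = np.zeros(d * d + d)
    for level in range(params.levels - 1, -1, -1):
        factor = 2**level
        mv = _downsample(moving.data, factor)
        fx = _downsample(fixed.data, factor)
        if mv.shape != fx.shape:
            fx = ndimage.zoom(fx, [a / b for a, b in zip(mv.shape, fx.shape)], order=1)
        # translation lives in voxel units of the current level
        x_level = x.copy()
        x_level[d * d:] /= factor
        res = optimize.minimize(
            _affine_mse, x_level, args=(mv, fx, d), method="Powell",
            options={"maxiter": params.affine_maxiter * (d * d + d), "xtol": 1e-4, "ftol": 1e-8},
        )
        x = res.x.copy()
        x[d * d:] *= factor
    return AffineTransform(np.eye(d) + x[: d * d].reshape(d, d), x[d * d:])


# ---------------------------------------------------------------------------
# log-demons

def _smooth_field(u: np.ndarray, sigma: float) -> np.ndarray:
    if sigma <= 0:
        return u
    out = np.empty_like(u)
    for i in range(u.shape[-1]):
        out[..., i] = ndimage.gaussian_filter(u[..., i], sigma)
    return out


def _demons_level(mv: np.ndarray, fx: np.ndarray, v: np.ndarray,
                  params: RegistrationParams):
    """Run demons iterations at one level; returns (best v, best mse, first mse)."""
    best_v = v
    best_mse = np.inf
    prev_mse = np.inf
    stall = 0
    first_mse = None
    grad_fx = np.gradient(fx)
    for _ in range(params.iterations):
        phi = group_exp(SVF(VectorField(v)))
        warped = warp(ScalarImage(mv), phi).data
        diff = fx - warped
        mse = float(np.mean(diff**2))
        if first_mse is None:
            first_mse = mse
        if mse < best_mse:
            best_mse, best_v = mse, v
        # plateau early stop
        if prev_mse - mse < params.tol * max(prev_mse, 1e-30):
            stall += 1
            if stall >= 3:
                break
        else:
            stall = 0
        prev_mse = mse
        # symmetric (ESM-style) force: mean of warped and fixed gradients.
        # A one-sided force biases expansion vs. contraction, which skews
        # the SVF-norm distances used for reference selection.
        grad = [(gw + gf) * 0.5 for gw, gf in zip(np.gradient(warped), grad_fx)]
        gnorm2 = np.zeros_like(diff)
        for g in grad:
            gnorm2 += g * g
        denom = gnorm2 + diff * diff
        with np.errstate(invalid="ignore", divide="ignore"):
            factor = np.where(denom > 1e-12, diff / denom, 0.0)
        upd = np.stack([factor * g for g in grad], axis=-1)
        upd = _smooth_field(upd, params.fluid_sigma)
        if params.update_rule == "bch":
            v = bch_pair(SVF(VectorField(v)), SVF(VectorField(upd)), order=2).data
        else:
            v = v + upd
        v = _smooth_field(v, params.diffusion_sigma)
    # score the final iterate too
    phi = group_exp(SVF(VectorField(v)))
    mse = float(np.mean((fx - warp(ScalarImage(mv), phi).data) ** 2))
    if mse < best_mse:
        best_mse, best_v = mse, v
    return best_v, best_mse, first_mse


def svf_register(moving: ScalarImage, fixed: ScalarImage,
                 params: RegistrationParams | None = None) -> SVF:
    """Log-demons registration returning a single SVF.

    Returns v with ``warp(moving, group_exp(v)) ≈ fixed``.
    Non-convergence is not an error: the best iterate is returned with
    the initial and final MSE in ``meta``.
    """
    params = params or RegistrationParams()
    if moving.shape != fixed.shape:
        raise GridMismatchError(
            f"grid shapes differ: {moving.shape} vs {fixed.shape}")
    v = None
    pre_mse = None
    final_mse = None
    for level in range(params.levels - 1, -1, -1):
        factor = 2**level
        mv = _downsample(moving.data, factor)
        fx = _downsample(fixed.data, factor)
        if mv.shape != fx.shape:
            fx = ndimage.zoom(fx, [a / b for a, b in zip(mv.shape, fx.shape)], order=1)
        if v is None:
            v = np.zeros(mv.shape + (moving.ndim,))
        else:
            v = _upsample_velocity(v, mv.shape)
        v, mse, first = _demons_level(mv, fx, v, params)
        if level == params.levels - 1:
            pre_mse = first
        final_mse = mse
    out = SVF(VectorField(v, moving.spacing))
    out.meta.update({"final_mse": final_mse, "initial_mse_coarsest": pre_mse,
                     "params": params.to_dict()})
    return out


# ---------------------------------------------------------------------------
# groupwise template

def build_global_template(templates, params: RegistrationParams | None = None,
                          outer_iterations: int = 5):
    """Unbiased iterative groupwise template G from ≥ 2 aligned images.

    G starts as the voxelwise mean; each outer iteration registers every
    T_i to G, averages the warped images, and de-biases the average by
    warping it with exp(−mean v).  Returns (G, final v_i list); the mean
    of the final v_i is small relative to the individual norms
    (unbiasedness).
    """
    params = params or RegistrationParams()
    templates = list(templates)
    if len(templates) < 2:
        raise ValueError("build_global_template needs at least 2 templates")
    shape = templates[0].shape
    for t in templates[1:]:
        if t.shape != shape:
            raise GridMismatchError(f"grid shapes differ: {shape} vs {t.shape}")
    if all(np.array_equal(t.data, templates[0].data) for t in templates[1:]):
        # degenerate but valid: identical inputs
        G = templates[0].copy()
        zero = [SVF.zeros(shape, t.spacing) for t in templates]
        return G, zero
    G = ScalarImage(np.mean([t.data for t in templates], axis=0),
                    templates[0].spacing, templates[0].origin)
    svfs = []
    for _ in range(outer_iterations):
        raw = [svf_register(t, G, params) for t in templates]
        # log-Euclidean de-biasing: subtract the mean SVF from every field
        # so the returned fields are exactly centered at the barycenter
        mean_v = np.mean([v.data for v in raw], axis=0)
        svfs = []
        for v in raw:
            c = SVF(VectorField(v.data - mean_v, G.spacing))
            c.meta.update(v.meta)
            svfs.append(c)
        warped = [warp(t, group_exp(v)) for t, v in zip(templates, svfs)]
        G = ScalarImage(np.mean([w.data for w in warped], axis=0),
                        G.spacing, G.origin)
    return G, svfs
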