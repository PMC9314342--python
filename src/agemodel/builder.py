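"""Core aging-deformation pipeline.

Given age-group templates aligned to a common grid, the aging signal is
extracted in five steps:

1. *Reference selection* — the template whose SVF to the global template
   G has the smallest norm is the reference T_M (the anatomy closest to
   the population average; ties break to the smallest index).
2. *Pairwise SVFs* — consecutive-pair registrations in the forward
   direction (T_M → … → T_N) and backward direction (T_M → … → T_1).
   SVF registration only captures small smooth deformations, which
   rejects large non-aging differences between age groups.
3. *BCH composition* — the pairwise fields are folded into a single SVF
   per direction.  Temporally inconsistent (random) residual
   deformations cancel in the averaging-like BCH sums, leaving the
   consistent aging trend.
4. *Aging rate* — the norm ratio R(j) = ‖composed SVF up to j‖ / ‖full
   composed SVF‖ quantifies how much of the total aging deformation has
   accrued by each age point; a shape-preserving cubic through the R
   knots (plus γ(t_M) = 0) gives the continuous rate curve γ(t).
5. *Parallel transport* — the per-direction SVFs, expressed at T_M, are
   conjugated along half the T_M → G map to live in the global space:
   exp(Π(v)) = exp(v_M/2) ∘ exp(v) ∘ exp(−v_M/2).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import PchipInterpolator

from .grid import GridMismatchError, VectorField, compose, field_norm
from .registration import RegistrationParams, svf_register
from .svf import SVF, _subdivided_fold, group_exp, group_log

__all__ = [
    "TemplateSequence",
    "AgingDeformation",
    "GammaCurve",
    "select_reference",
    "pairwise_aging_svfs",
    "compose_aging",
    "aging_rate",
    "fit_gamma",
    "transport_to_global",
]


@dataclasses.dataclass
class TemplateSequence:
    """Ordered age-group templates on a common grid with strictly increasing ages."""

    templates: list
    ages: list

    def __post_init__(self):
        self.templates = list(self.templates)
        self.ages = [float(a) for a in self.ages]
        if len(self.templates) != len(self.ages):
            raise ValueError("templates and ages must have equal length")
        if len(self.templates) < 3:
            raise ValueError("need at least 3 templates to model an aging trend")
        if any(b <= a for a, b in zip(self.ages, self.ages[1:])):
            raise ValueError("ages must be strictly increasing")
        shape = self.templates[0].shape
        for t in self.templates[1:]:
            if t.shape != shape:
                raise GridMismatchError(f"grid shapes differ: {shape} vs {t.shape}")

    def __len__(self):
        return len(self.templates)


@dataclasses.dataclass
class AgingDeformation:
    """Composed aging SVFs with their intermediates, per direction.

    ``intermediates_f[j]`` is the single-SVF parameterization of the
    deformation from T_M to T_{M+1+j} (0-based j); likewise backward.
    ``v_f``/``v_b`` are the final composed fields (zero SVFs when the
    reference sits at the corresponding end of the sequence).
    """

    v_f: SVF
    v_b: SVF
    intermediates_f: list
    intermediates_b: list
    M: int = None
    t_M: float = None


def select_reference(v_norms) -> int:
    """Index of the template with the smallest SVF norm to G (0-based).

    Ties break to the smallest index.
    """
    norms = list(v_norms)
    if not norms:
        raise ValueError("select_reference requires a non-empty list of norms")
    return int(np.argmin(norms))


def pairwise_aging_svfs(seq: TemplateSequence, M: int,
                        params: RegistrationParams | None = None):
    """Consecutive-pair SVFs in both directions from the reference (0-based M).

    Forward entry j registers moving T_{M+j} to fixed T_{M+j+1}
    (j = 0 … N−M−2); backward entry j registers moving T_{M−j} to fixed
    T_{M−j−1} (j = 0 … M−1).  Each SVF is tagged with its pair and
    direction.
    """
    N = len(seq)
    if not 0 <= M < N:
        raise ValueError(f"reference index {M} out of range for {N} templates")
    forward, backward = [], []
    for j in range(N - 1 - M):
        v = svf_register(seq.templates[M + j], seq.templates[M + j + 1], params)
        v.meta.update({"pair": (M + j, M + j + 1), "direction": "forward"})
        forward.append(v)
    for j in range(M):
        v = svf_register(seq.templates[M - j], seq.templates[M - j - 1], params)
        v.meta.update({"pair": (M - j, M - j - 1), "direction": "backward"})
        backward.append(v)
    return forward, backward


def _compose_direction(svfs, grid_shape, spacing, order):
    intermediates = []
    acc = None
    for v in svfs:
        if acc is None:
            acc = SVF(VectorField(v.data.copy(), spacing))
        else:
            acc = _subdivided_fold(acc, v, order, 0.5)
        intermediates.append(acc)
    if acc is None:
        acc = SVF.zeros(grid_shape, spacing)
    return acc, intermediates


def compose_aging(forward, backward, order: int = 3) -> AgingDeformation:
    """Fold the pairwise SVF lists into one SVF per direction via BCH.

    ``intermediates_*[j]`` is the running composition of the first j+1
    pairwise fields; the last intermediate is the final composed SVF.
    Empty direction lists yield zero SVFs.
    """
    if not forward and not backward:
        raise ValueError("compose_aging needs at least one pairwise SVF")
    ref = (forward or backward)[0]
    shape = tuple(ref.grid_shape)
    spacing = ref.field.spacing
    for v in list(forward) + list(backward):
        if tuple(v.grid_shape) != shape:
            raise GridMismatchError(
                f"grid shapes differ: {shape} vs {tuple(v.grid_shape)}")
    v_f, inter_f = _compose_direction(forward, shape, spacing, order)
    v_b, inter_b = _compose_direction(backward, shape, spacing, order)
    return AgingDeformation(v_f=v_f, v_b=v_b,
                            intermediates_f=inter_f, intermediates_b=inter_b)


def aging_rate(deform: AgingDeformation):
    """Norm-ratio quantification R of the accrued aging deformation.

    R(j) = ‖composed SVF up to j‖ / ‖final composed SVF‖ per direction;
    the final entry of each non-empty list is exactly 1.
    """
    out = []
    for inter, total in ((deform.intermediates_f, deform.v_f),
                         (deform.intermediates_b, deform.v_b)):
        if not inter:
            out.append([])
            continue
        denom = field_norm(total)
        if denom == 0.0:
            raise ValueError(
                "degenerate aging signal: composed SVF has zero norm")
        out.append([field_norm(v) / denom for v in inter])
    R_f, R_b = out
    return R_f, R_b


class GammaCurve:
    """Continuous aging-rate curve γ(t) through the R knots.

    A shape-preserving piecewise cubic (PCHIP) through
    {(t_M, 0)} ∪ {(t_{M+j}, R_f(j))} ∪ {(t_{M−j}, R_b(j))}; monotone
    knot runs stay monotone (no overshoot below 0 near t_M).  Outside
    [t_1, t_N] the curve continues linearly with the boundary slope.
    """

    def __init__(self, knot_ages, knot_values, t_M):
        ages = np.asarray(knot_ages, dtype=np.float64)
        vals = np.asarray(knot_values, dtype=np.float64)
        if ages.shape != vals.shape or ages.ndim != 1:
            raise ValueError("knot ages and values must be matching 1D arrays")
        if len(ages) < 2:
            raise ValueError("need at least 2 knots to fit a curve")
        if len(np.unique(ages)) != len(ages):
            raise ValueError("duplicate knot ages")
        order = np.argsort(ages)
        self.knot_ages = ages[order]
        self.knot_values = vals[order]
        self.t_M = float(t_M)
        self.age_range = (float(self.knot_ages[0]), float(self.knot_ages[-1]))
        self._pchip = PchipInterpolator(self.knot_ages, self.knot_values,
                                        extrapolate=False)
        deriv = self._pchip.derivative()
        self.end_slopes = (float(deriv(self.knot_ages[0])),
                           float(deriv(self.knot_ages[-1])))

    @property
    def coefficients(self) -> np.ndarray:
        """Piecewise-cubic coefficient array (scipy PPoly layout)."""
        return self._pchip.c

    def __call__(self, t):
        t = np.asarray(t, dtype=np.float64)
        lo, hi = self.age_range
        inside = self._pchip(np.clip(t, lo, hi))
        below = self.knot_values[0] + self.end_slopes[0] * (t - lo)
        above = self.knot_values[-1] + self.end_slopes[1] * (t - hi)
        out = np.where(t < lo, below, np.where(t > hi, above, inside))
        return float(out) if out.ndim == 0 else out

    def to_dict(self) -> dict:
        return {
            "knot_ages": self.knot_ages.tolist(),
            "knot_values": self.knot_values.tolist(),
            "t_M": self.t_M,
            "age_range": list(self.age_range),
            "end_slopes": list(self.end_slopes),
            "coefficients": self.coefficients.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GammaCurve":
        return cls(d["knot_ages"], d["knot_values"], d["t_M"])

    def __eq__(self, other):
        return (isinstance(other, GammaCurve)
                and np.array_equal(self.knot_ages, other.knot_ages)
                and np.array_equal(self.knot_values, other.knot_values)
                and self.t_M == other.t_M)


def fit_gamma(ages, R_f, R_b, t_M) -> GammaCurve:
    """Fit γ(t) through the aging-rate knots.

    ``ages`` is the full template age list; ``t_M`` must be one of its
    entries (the reference age).  Forward knots sit at the ages after
    t_M, backward knots at the ages before it, plus the anchor
    (t_M, 0): the deformation with respect to the reference is zero at
    the reference itself.
    """
    ages = [float(a) for a in ages]
    if len(set(ages)) != len(ages):
        raise ValueError("duplicate ages")
    try:
        M = ages.index(float(t_M))
    except ValueError:
        raise ValueError(f"t_M={t_M} is not one of the template ages") from None
    n_f, n_b = len(ages) - 1 - M, M
    if len(R_f) != n_f or len(R_b) != n_b:
        raise ValueError(
            f"R lists ({len(R_f)} forward, {len(R_b)} backward) do not match "
            f"the age layout around t_M ({n_f} forward, {n_b} backward)")
    if not R_f and not R_b:
        raise ValueError("no aging-rate knots on either side of the reference")
    knot_ages = [float(t_M)]
    knot_vals = [0.0]
    knot_ages += [ages[M + 1 + j] for j in range(n_f)]
    knot_vals += [float(r) for r in R_f]
    knot_ages += [ages[M - 1 - j] for j in range(n_b)]
    knot_vals += [float(r) for r in R_b]
    return GammaCurve(knot_ages, knot_vals, t_M)


def transport_to_global(v: SVF, v_M: SVF, log_iters: int = 40,
                        log_tol: float = 1e-3) -> SVF:
    """Parallel transport of v from the reference space to the global space.

    Conjugation along half the reference-to-global map:
    Π(v) = log(exp(v_M/2) ∘ exp(v) ∘ exp(−v_M/2)).  A zero v_M returns v
    unchanged up to the log-map tolerance.
    """
    if tuple(v.grid_shape) != tuple(v_M.grid_shape):
        raise GridMismatchError(
            f"grid shapes differ: {tuple(v.grid_shape)} vs {tuple(v_M.grid_shape)}")
    if not v_M.data.any():
        out = SVF(VectorField(v.data.copy(), v.field.spacing))
        out.meta["transport"] = "identity (v_M = 0)"
        return out
    half = v_M.scaled(0.5)
    disp = compose(group_exp(half),
                   compose(group_exp(v), group_exp(half.scaled(-1.0))))
    out = group_log(disp, iters=log_iters, tol=log_tol)
    out.meta["transport"] = "conjugation by exp(v_M/2)"
    return out
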