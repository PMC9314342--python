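"""Evaluation metrics and the synthetic-experiment validation report."""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from .grid import GridMismatchError, interior, jacobian_determinant
from .svf import group_exp

__all__ = ["mse", "ssim", "dice", "topology_report", "validate_model",
           "summarize_report"]

#: SSIM configuration (conventional Gaussian-window formulation).
SSIM_CONFIG = {"gaussian_weights": True, "sigma": 1.5,
               "use_sample_covariance": False, "K1": 0.01, "K2": 0.03}


def _arrays(a, b):
    aa = np.asarray(a) if isinstance(a, np.ndarray) else np.asarray(a.data)
    bb = np.asarray(b) if isinstance(b, np.ndarray) else np.asarray(b.data)
    if aa.shape != bb.shape:
        raise GridMismatchError(f"shapes differ: {aa.shape} vs {bb.shape}")
    return aa, bb


def mse(a, b) -> float:
    """Mean squared intensity error."""
    aa, bb = _arrays(a, b)
    return float(np.mean((aa - bb) ** 2))


def ssim(a, b, data_range: float = None) -> float:
    """Structural similarity index with a Gaussian window (σ = 1.5)."""
    aa, bb = _arrays(a, b)
    if data_range is None:
        data_range = float(max(aa.max() - aa.min(), bb.max() - bb.min(), 1e-12))
    return float(structural_similarity(aa, bb, data_range=data_range, **SSIM_CONFIG))


def dice(labels_a, labels_b, label) -> float:
    """Dice overlap of one label between two label images."""
    aa, bb = _arrays(labels_a, labels_b)
    ma, mb = aa == label, bb == label
    denom = ma.sum() + mb.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(ma, mb).sum() / denom)


def topology_report(disp) -> dict:
    """Min interior Jacobian determinant and the fraction of non-positive voxels."""
    det = interior(jacobian_determinant(disp))
    return {"min_interior_jacobian": float(det.min()),
            "fraction_nonpositive": float(np.mean(det <= 0))}


def validate_model(model, cohort, extrapolate_below: float = 10.0,
                   extrapolate_above: float = 15.0, age_step: float = 1.0) -> dict:
    """Score an aging model against the synthetic cohort's proxy ground truth.

    Reports, per timepoint, SSIM and MSE between the model-generated
    template and the aging deformation applied directly to the base
    phantom; the γ-symmetry score max_δ |γ(t_M+δ) − γ(t_M−δ)|; and a
    topology sweep (min interior Jacobian of the applied deformation)
    over a dense age grid extended beyond both data endpoints.
    """
    from .model import generate_template  # local import to avoid a cycle

    ages = cohort.ages
    t1, tN = model.age_range
    if not (min(ages) >= t1 - 1e-9 and max(ages) <= tN + 1e-9):
        raise ValueError(
            f"cohort ages {ages} fall outside the model age range [{t1}, {tN}]")

    per_tp = []
    for age, truth in zip(ages, cohort.truths):
        gen = generate_template(model, age)
        per_tp.append({"age": age,
                       "ssim": ssim(gen, truth, data_range=1.0),
                       "mse": mse(gen, truth)})

    span = min(tN - model.t_M, model.t_M - t1)
    deltas = np.arange(0.0, span + 1e-9, 0.25)
    gamma_sym = float(np.max(np.abs(
        model.gamma(model.t_M + deltas) - model.gamma(model.t_M - deltas))))

    sweep_ages = np.arange(t1 - extrapolate_below, tN + extrapolate_above + 1e-9,
                           age_step)
    min_jac = np.inf
    worst_age = None
    for t in sweep_ages:
        g = float(model.gamma(t))
        v = model.pi_vf if t >= model.t_M else model.pi_vb
        rep = topology_report(group_exp(v.scaled(g)))
        if rep["min_interior_jacobian"] < min_jac:
            min_jac = rep["min_interior_jacobian"]
            worst_age = float(t)

    report = {
        "config": cohort.config.to_dict(),
        "reference_age": model.t_M,
        "reference_index": int(ages.index(model.t_M)) if model.t_M in ages else None,
        "per_timepoint": per_tp,
        "gamma_symmetry_score": gamma_sym,
        "gamma_knots": model.gamma.to_dict(),
        "topology": {
            "age_sweep": [float(sweep_ages[0]), float(sweep_ages[-1])],
            "min_interior_jacobian": float(min_jac),
            "worst_age": worst_age,
        },
    }
    return report


def summarize_report(report: dict) -> str:
    """Human-readable one-screen summary of a validation report."""
    lines = ["aging-model validation report",
             f"  reference age t_M = {report['reference_age']}"]
    for row in report["per_timepoint"]:
        lines.append(
            f"  age {row['age']:6.1f}:  SSIM = {row['ssim']:.4f}   MSE = {row['mse']:.5f}")
    lines.append(f"  gamma symmetry score = {report['gamma_symmetry_score']:.4f}")
    topo = report["topology"]
    lines.append(
        f"  min interior Jacobian over ages [{topo['age_sweep'][0]:.0f}, "
        f"{topo['age_sweep'][1]:.0f}] = {topo['min_interior_jacobian']:.4f} "
        f"(worst at age {topo['worst_age']:.0f})")
    return "\n".join(lines)
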