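"""The assembled aging model: build, generate, map subjects, serialize.

The model has three components: the global structural template G, the
aging-rate curve γ(t), and the transported forward/backward aging SVFs
Π(v_f), Π(v_b).  An age-specific template is

    T(t) = warp(G, exp(γ(t)·Π(v_f)))   for t ≥ t_M,
    T(t) = warp(G, exp(γ(t)·Π(v_b)))   for t ≤ t_M,

where ``warp`` is this package's pullback-style resampling (see
``agemodel.grid``); the sign works out so that T(t_N) reproduces the
oldest template's anatomy.  γ(t_M) = 0, so T(t_M) is G bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import warnings

import numpy as np
import yaml

from .builder import (
    GammaCurve,
    TemplateSequence,
    compose_aging,
    fit_gamma,
    pairwise_aging_svfs,
    select_reference,
    transport_to_global,
)
from .grid import ScalarImage, compose, field_norm, warp
from .io import load_image, load_vector_field, save_image, save_vector_field
from .registration import (
    RegistrationParams,
    affine_register,
    apply_affine,
    build_global_template,
    svf_register,
)
from .svf import SVF, group_exp

__all__ = ["AgingModel", "build_model", "generate_template",
           "map_subject_to_global", "save_model", "load_model"]

MODEL_FORMAT_VERSION = "1.0"

#: Affines whose largest induced displacement over the grid is below this
#: (voxels) are snapped to the identity: re-alignment below a quarter voxel
#: is meaningless while the resampling blur it causes is not.
AFFINE_SNAP_TOL = 0.25


def _max_affine_displacement(aff, shape) -> float:
    """Largest |m(x) − x| over the grid corners (m is the affine map)."""
    c = (np.asarray(shape, dtype=np.float64) - 1) / 2.0
    corners = np.array(np.meshgrid(*[(0, s - 1) for s in shape])).reshape(len(shape), -1).T
    disp = (corners - c) @ (aff.matrix - np.eye(len(shape))).T + aff.offset
    return float(np.sqrt((disp**2).sum(axis=1)).max())


@dataclasses.dataclass
class AgingModel:
    """The three-component aging model plus age metadata and provenance."""

    G: ScalarImage
    pi_vf: SVF
    pi_vb: SVF
    gamma: GammaCurve
    t_M: float
    age_range: tuple
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        shapes = {tuple(self.G.shape), tuple(self.pi_vf.grid_shape),
                  tuple(self.pi_vb.grid_shape)}
        if len(shapes) != 1:
            raise ValueError(f"model component grids differ: {shapes}")
        if self.gamma.t_M != self.t_M:
            raise ValueError("gamma.t_M does not match the model t_M")
        self.age_range = (float(self.age_range[0]), float(self.age_range[1]))


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the pipeline stage named."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"stage '{name}': {exc}") from exc
            return False
    return _Ctx()


class _StageError(RuntimeError):
    pass


def build_model(seq: TemplateSequence, params: RegistrationParams | None = None,
                outer_iterations: int = 5, bch_order: int = 3) -> AgingModel:
    """Run the whole pipeline on an age-ordered template sequence.

    Affine pre-alignment → groupwise global template G (with the SVFs
    v_i mapping each template to G) → reference selection by smallest
    ‖v_i‖ → pairwise forward/backward SVFs → BCH composition → aging
    rate and γ(t) fit → parallel transport of both composed SVFs along
    v_M.  Deterministic for fixed inputs and params.
    """
    params = params or RegistrationParams()
    ages = list(seq.ages)

    with _stage("affine pre-alignment"):
        mean = ScalarImage(np.mean([t.data for t in seq.templates], axis=0),
                           seq.templates[0].spacing)
        aligned = []
        affines = []
        for t in seq.templates:
            aff = affine_register(t, mean, params)
            if _max_affine_displacement(aff, t.shape) < AFFINE_SNAP_TOL:
                aff = type(aff).identity(t.ndim)
                aligned.append(t.copy())
            else:
                aligned.append(apply_affine(t, aff))
            affines.append(aff)

    with _stage("global template construction"):
        G, v_list = build_global_template(aligned, params,
                                          outer_iterations=outer_iterations)

    with _stage("reference selection"):
        norms = [field_norm(v) for v in v_list]
        M = select_reference(norms)
        t_M = ages[M]

    with _stage("pairwise aging SVFs"):
        aligned_seq = TemplateSequence(aligned, ages)
        forward, backward = pairwise_aging_svfs(aligned_seq, M, params)

    with _stage("BCH composition"):
        deform = compose_aging(forward, backward, order=bch_order)
        deform.M, deform.t_M = M, t_M

    with _stage("aging rate + gamma fit"):
        def _side_rates(inter, total):
            if not inter:
                return []
            denom = field_norm(total)
            if denom == 0.0:
                # no aging signal on this side (e.g. identical templates):
                # the deformation is zero, so gamma only needs to be
                # well-defined — use the uniform ramp of evenly accruing change
                return [(j + 1) / len(inter) for j in range(len(inter))]
            return [field_norm(v) / denom for v in inter]

        R_f = _side_rates(deform.intermediates_f, deform.v_f)
        R_b = _side_rates(deform.intermediates_b, deform.v_b)
        gamma = fit_gamma(ages, R_f, R_b, t_M)

    with _stage("parallel transport"):
        v_M = v_list[M]
        pi_vf = transport_to_global(deform.v_f, v_M)
        pi_vb = transport_to_global(deform.v_b, v_M)

    provenance = {
        "ages": ages,
        "reference_index": M,
        "svf_norms_to_G": norms,
        "R_forward": R_f,
        "R_backward": R_b,
        "params": params.to_dict(),
        "outer_iterations": outer_iterations,
        "bch_order": bch_order,
        "template_checksums": [
            hashlib.sha256(t.data.tobytes()).hexdigest()[:16] for t in seq.templates],
    }
    return AgingModel(G=G, pi_vf=pi_vf, pi_vb=pi_vb, gamma=gamma, t_M=t_M,
                      age_range=(ages[0], ages[-1]), provenance=provenance)


def generate_template(model: AgingModel, t: float) -> ScalarImage:
    """Age-specific template at time t (years); extrapolation allowed.

    t ≥ t_M flows along the forward transported SVF, t ≤ t_M along the
    backward one, each scaled by γ(t).  γ(t_M) = 0 returns G bit-exact.
    """
    t = float(t)
    if not np.isfinite(t):
        raise ValueError("age must be finite")
    lo, hi = model.age_range
    if t < lo or t > hi:
        warnings.warn(
            f"age {t} is outside the fitted range [{lo}, {hi}]; extrapolating "
            "with the boundary slope of gamma", stacklevel=2)
    g = float(model.gamma(t))
    v = model.pi_vf if t >= model.t_M else model.pi_vb
    return warp(model.G, group_exp(v.scaled(g)))


def map_subject_to_global(model: AgingModel, subject: ScalarImage, age: float,
                          params: RegistrationParams | None = None):
    """Map a subject scan at a known age into the global template space.

    One affine alignment to the age-matched generated template, then a
    single pairwise SVF registration (w); the composite map chains the
    inverse of the age-specific aging deformation after exp(w), so the
    subject is resampled straight into G-space.  Returns (image in
    G-space, composite DisplacementField).
    """
    params = params or RegistrationParams()
    if subject.ndim != model.G.ndim:
        raise ValueError(
            f"subject dimensionality {subject.ndim}D does not match model {model.G.ndim}D")
    age_template = generate_template(model, age)
    aff = affine_register(subject, age_template, params)
    subject_aligned = apply_affine(subject, aff)
    w = svf_register(subject_aligned, age_template, params)
    g = float(model.gamma(age))
    v = model.pi_vf if age >= model.t_M else model.pi_vb
    # inverse of the age-specific deformation = exp(−γ·Π(v)), exact in the
    # one-parameter subgroup.  Warps act by pullback, so the left compose
    # argument is applied to the image first: exp(w) takes the subject to the
    # age template, then exp(−γ·Π(v)) takes the age template to G.
    to_G = group_exp(v.scaled(-g))
    composite = compose(group_exp(w), to_G)
    return warp(subject_aligned, composite), composite


# ---------------------------------------------------------------------------
# serialization

_COMPONENTS = {"G": "G.nii", "pi_vf": "pi_vf.nii", "pi_vb": "pi_vb.nii",
               "model": "model.json", "params": "params.yaml"}


def save_model(model: AgingModel, directory) -> None:
    """Write the model to a directory: NIfTI arrays + JSON/YAML metadata.

    Output is byte-reproducible: saving the same model twice produces
    identical files.
    """
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_image(model.G, directory / _COMPONENTS["G"])
    save_vector_field(model.pi_vf.field, directory / _COMPONENTS["pi_vf"])
    save_vector_field(model.pi_vb.field, directory / _COMPONENTS["pi_vb"])
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "t_M": model.t_M,
        "age_range": list(model.age_range),
        "gamma": model.gamma.to_dict(),
        "provenance": model.provenance,
    }
    (directory / _COMPONENTS["model"]).write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")
    params = model.provenance.get("params", {})
    (directory / _COMPONENTS["params"]).write_text(
        yaml.safe_dump(params, sort_keys=True))


def load_model(directory) -> AgingModel:
    """Load a model saved by :func:`save_model`.

    Missing components are reported by name; an unknown format version
    is an explicit error.
    """
    directory = pathlib.Path(directory)
    missing = [name for name, fname in _COMPONENTS.items()
               if name != "params" and not (directory / fname).exists()
               and not (directory / (fname + ".gz")).exists()]
    if missing:
        raise FileNotFoundError(
            f"model directory {directory} is missing component(s): {', '.join(missing)}")

    meta = json.loads((directory / _COMPONENTS["model"]).read_text())
    version = meta.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {version!r} "
            f"(this build reads {MODEL_FORMAT_VERSION!r})")

    def _find(fname):
        p = directory / fname
        return p if p.exists() else directory / (fname + ".gz")

    G = load_image(_find(_COMPONENTS["G"]))
    pi_vf = SVF(load_vector_field(_find(_COMPONENTS["pi_vf"])))
    pi_vb = SVF(load_vector_field(_find(_COMPONENTS["pi_vb"])))
    gamma = GammaCurve.from_dict(meta["gamma"])
    return AgingModel(G=G, pi_vf=pi_vf, pi_vb=pi_vb, gamma=gamma,
                      t_M=float(meta["t_M"]),
                      age_range=tuple(meta["age_range"]),
                      provenance=meta.get("provenance", {}))
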