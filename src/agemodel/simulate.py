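"""Synthetic longitudinal phantom cohort.

Emulates a cross-sectional aging study with fully known ground truth: a
cohort of randomly deformed Shepp–Logan phantoms is replicated at
several "ages", and a shared smooth aging deformation of increasing
degree is applied at each age.  Per-age templates built from the cohort
then feed the aging-model pipeline, and the model's generated templates
can be compared against the aging deformation applied directly to the
base phantom (the proxy ground truth).

What this emulates: inter-subject anatomical variability (random
Gaussian-bump displacement fields per subject) and a slow, spatially
smooth, monotonic aging trend (one bump field scaled by an increasing
magnitude schedule).  What it does not: realistic brain anatomy, MRI
noise/bias fields, or atrophy biophysics.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.data import shepp_logan_phantom
from skimage.transform import resize

from .grid import (
    DisplacementField,
    ScalarImage,
    VectorField,
    interior,
    jacobian_determinant,
    warp,
)
from .registration import RegistrationParams, build_global_template
from .svf import SVF, group_exp, max_voxel_magnitude

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "shepp_logan",
    "random_bump_displacement",
    "smooth_random_svf",
    "simulate_cohort",
]


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions of the synthetic longitudinal experiment.

    Defaults: a 128×128 grid, 50 subjects at 5 time points; subject
    variability as 8 Gaussian bumps of radius 10 voxels with amplitude
    σ = 2 voxels; aging magnitudes rising uniformly from 0.5 to 2.5
    voxels; nominal ages 30–70 years; master seed 7.
    """

    grid_shape: tuple = (128, 128)
    n_subjects: int = 50
    n_timepoints: int = 5
    n_bump_sites: int = 8
    site_radius: float = 10.0
    sigma_subject: float = 2.0
    aging_magnitudes: tuple = (0.5, 1.0, 1.5, 2.0, 2.5)
    ages: tuple = (30.0, 40.0, 50.0, 60.0, 70.0)
    seed: int = 7
    template_outer_iterations: int = 2
    registration: RegistrationParams = None

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        self.aging_magnitudes = tuple(float(m) for m in self.aging_magnitudes)
        self.ages = tuple(float(a) for a in self.ages)
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if len(self.aging_magnitudes) != self.n_timepoints:
            raise ValueError("need one aging magnitude per timepoint")
        if len(self.ages) != self.n_timepoints:
            raise ValueError("need one age per timepoint")
        if any(b <= a for a, b in
               zip(self.aging_magnitudes, self.aging_magnitudes[1:])):
            raise ValueError("aging magnitudes must be strictly increasing")
        if self.registration is None:
            self.registration = RegistrationParams()
        elif isinstance(self.registration, dict):
            self.registration = RegistrationParams.from_dict(self.registration)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["registration"] = self.registration.to_dict()
        return d


@dataclasses.dataclass
class SyntheticCohort:
    """Everything the synthetic experiment produced, ground truth included."""

    config: SimulationConfig
    base: ScalarImage
    subject_fields: list          # per-subject DisplacementField
    aging_svfs: list              # per-timepoint truth SVF (scaled pattern)
    aging_fields: list            # per-timepoint truth DisplacementField
    templates: list               # per-timepoint ScalarImage (groupwise built)
    truths: list                  # per-timepoint proxy ground-truth ScalarImage

    @property
    def ages(self):
        return list(self.config.ages)


def shepp_logan(shape) -> ScalarImage:
    """The standard 2D Shepp–Logan ellipse phantom, intensities in [0, 1]."""
    shape = tuple(shape)
    if len(shape) != 2:
        raise ValueError("the phantom validation runs in 2D; expected a 2D shape")
    img = shepp_logan_phantom()
    img = resize(img, shape, order=1, anti_aliasing=True)
    return ScalarImage(np.clip(img, 0.0, 1.0))


def _bump_field(shape, sites, amplitudes, radius):
    """Sum of Gaussian-windowed displacement bumps (window σ = radius/2)."""
    d = len(shape)
    u = np.zeros(tuple(shape) + (d,))
    coords = np.indices(shape, dtype=np.float64)
    sigma_w = radius / 2.0
    for site, amp in zip(sites, amplitudes):
        r2 = np.zeros(shape)
        for ax in range(d):
            r2 += (coords[ax] - site[ax]) ** 2
        window = np.exp(-0.5 * r2 / sigma_w**2)
        for ax in range(d):
            u[..., ax] += amp[ax] * window
    return u


def random_bump_displacement(grid_shape, n_sites, radius, sigma, seed,
                             max_attempts: int = 12) -> DisplacementField:
    """Smooth random field: compact Gaussian bumps at seeded locations.

    Site locations are uniform over the grid (with a margin of one
    radius); per-site displacement amplitudes along each axis are drawn
    from N(0, σ²).  If the field folds (min interior Jacobian ≤ 0.1),
    amplitudes are rescaled by 0.8 until it does not.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    grid_shape = tuple(grid_shape)
    d = len(grid_shape)
    rng = np.random.default_rng(seed)
    if sigma == 0:
        return DisplacementField(np.zeros(grid_shape + (d,)), diffeomorphic=True)
    margin = min(radius, min(grid_shape) / 4.0)
    sites = np.column_stack([
        rng.uniform(margin, s - 1 - margin, size=n_sites) for s in grid_shape])
    amplitudes = rng.normal(0.0, sigma, size=(n_sites, d))
    for attempt in range(max_attempts):
        u = _bump_field(grid_shape, sites, amplitudes, radius)
        field = DisplacementField(u)
        if interior(jacobian_determinant(field)).min() > 0.1:
            field.diffeomorphic = True
            return field
        amplitudes = amplitudes * 0.8
    raise ValueError(
        f"sigma={sigma} too large: field still folds after {max_attempts} rescalings")


def smooth_random_svf(grid_shape, max_magnitude, sigma=4.0, seed=0) -> SVF:
    """Gaussian-smoothed white noise rescaled to a given max voxel magnitude.

    A generic smooth test field, used by the oracle suites.
    """
    grid_shape = tuple(grid_shape)
    d = len(grid_shape)
    rng = np.random.default_rng(seed)
    u = rng.normal(size=grid_shape + (d,))
    for i in range(d):
        u[..., i] = ndimage.gaussian_filter(u[..., i], sigma)
    m = max_voxel_magnitude(VectorField(u))
    if m > 0 and max_magnitude > 0:
        u *= max_magnitude / m
    else:
        u[:] = 0.0
    return SVF(VectorField(u))


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Run the full synthetic longitudinal experiment.

    Each subject k gets a random bump field s_k; the subject image is
    the base phantom warped by s_k.  One shared aging bump pattern â
    (normalized to unit max magnitude) is scaled by the per-timepoint
    magnitude schedule; the image of subject k at timepoint τ is the
    subject image warped by exp(m_τ·â).  A per-timepoint template is
    built from the cohort images with the groupwise builder, and the
    proxy ground truth at τ is the base phantom warped by exp(m_τ·â).
    """
    config = config or SimulationConfig()
    base = shepp_logan(config.grid_shape)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_subjects + 1)
    aging_seed, subject_seeds = seeds[0], seeds[1:]

    pattern = random_bump_displacement(
        config.grid_shape, config.n_bump_sites, config.site_radius,
        sigma=1.0, seed=aging_seed)
    unit = pattern.data / max(max_voxel_magnitude(pattern), 1e-12)

    aging_svfs, aging_fields, truths = [], [], []
    for m in config.aging_magnitudes:
        v = SVF(VectorField(unit * m))
        phi = group_exp(v)
        aging_svfs.append(v)
        aging_fields.append(phi)
        truths.append(warp(base, phi))

    subject_fields = [
        random_bump_displacement(
            config.grid_shape, config.n_bump_sites, config.site_radius,
            config.sigma_subject, seed=s)
        for s in subject_seeds
    ]
    subject_images = [warp(base, s) for s in subject_fields]

    templates = []
    for phi in aging_fields:
        cohort_images = [warp(img, phi) for img in subject_images]
        G_tau, _ = build_global_template(
            cohort_images, config.registration,
            outer_iterations=config.template_outer_iterations)
        templates.append(G_tau)

    return SyntheticCohort(
        config=config, base=base, subject_fields=subject_fields,
        aging_svfs=aging_svfs, aging_fields=aging_fields,
        templates=templates, truths=truths)
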