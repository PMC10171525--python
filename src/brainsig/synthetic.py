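"""Synthetic cohorts with known ground truth.

The generator emulates the inputs to the signature pipeline: a smooth
template gray-matter density field; per-subject GM volumes equal to the
template plus a planted spatial effect scaled by a latent trait plus
spatially smoothed noise; and an outcome score linearly loaded on the
latent trait with demographic effects and noise.  An ``outcome_sign`` of
-1 emulates inverse-scored instruments (everyday-cognition style, where
higher scores mean worse function), producing negative brain-outcome
t-values in the planted regions.

The latent trait is standard normal by default; all randomness flows from
one seeded generator and the seed is recorded in every output.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import BinaryMask, CohortTable, Volume

__all__ = [
    "EffectSpec",
    "GenerativeConfig",
    "make_template",
    "simulate_cohort",
    "split_discovery_validation",
    "SimulatedCohort",
]


@dataclasses.dataclass
class EffectSpec:
    """A planted effect region: an axis-aligned box or a sphere.

    ``effect_size`` is in GM-density units per unit latent trait and may be
    zero (a null region, excluded from the ground-truth mask).
    """

    kind: str = "box"  # "box" or "sphere"
    center: tuple[int, int, int] = (0, 0, 0)
    extent: tuple[int, int, int] | int = 4  # half-widths (box) or radius (sphere)
    effect_size: float = 0.0

    def indicator(self, shape: tuple[int, int, int]) -> np.ndarray:
        idx = np.indices(shape)
        c = np.asarray(self.center)
        if np.any(c < 0) or np.any(c >= np.asarray(shape)):
            raise ValueError(f"effect region center {self.center} outside grid {shape}")
        if self.kind == "box":
            half = np.broadcast_to(np.asarray(self.extent), (3,))
            ind = np.all(np.abs(idx - c[:, None, None, None]) <= half[:, None, None, None], axis=0)
        elif self.kind == "sphere":
            r = float(np.asarray(self.extent).ravel()[0])
            ind = np.sum((idx - c[:, None, None, None]) ** 2, axis=0) <= r**2
        else:
            raise ValueError(f"unknown region kind {self.kind!r}")
        return ind


@dataclasses.dataclass
class GenerativeConfig:
    """Parameters of the synthetic cohort generator.

    Defaults target an elderly memory-study profile: ages uniform on
    [55, 90] years, education uniform on [8, 20] years, outcome scores on a
    roughly z-scored scale (SD near 1).  ``noise_sd`` is the per-voxel
    standard deviation of the smoothed imaging noise (the smoothed field is
    rescaled so this SD holds after smoothing).
    """

    n_subjects: int = 400
    shape: tuple[int, int, int] = (24, 24, 24)
    effects: Sequence[EffectSpec] = ()
    latent_sd: float = 1.0
    noise_sd: float = 0.06
    noise_smooth_sigma: float = 1.0
    outcome_loading: float = 0.6
    outcome_sign: int = 1
    gamma_age: float = -0.03
    gamma_education: float = 0.04
    outcome_noise_sd: float = 0.5
    outcome_name: str = "memory"
    diagnosis_quantiles: tuple[float, float] = (1 / 3, 2 / 3)
    min_density: float = 0.5
    seed: int = 0
    #: template seed; fix it to draw several cohorts in the same template
    #: space (shared grid and ground truth), else derived from ``seed``
    template_seed: int | None = None


@dataclasses.dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_cohort`."""

    cohort: CohortTable
    volumes: dict[str, Volume]
    truth_mask: BinaryMask
    template: Volume
    config: GenerativeConfig


def make_template(shape: tuple[int, int, int], seed: int) -> Volume:
    """A smooth positive GM-density field, deterministic given seed.

    The field has baseline density near 1 with gentle spatial structure
    (range roughly 0.6-1.4), standing in for a registered template GM map.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or min(shape) < 8:
        raise ValueError(f"template extents must be >= 8 per axis, got {shape}")
    rng = np.random.default_rng(seed)
    field = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=3.0, mode="nearest")
    span = field.max() - field.min()
    if span > 0:
        field = (field - field.min()) / span  # -> [0, 1]
    data = 0.6 + 0.8 * field
    return Volume(data, space_tag=f"synthetic-template-seed{seed}")


def _smoothed_noise(rng: np.random.Generator, shape, sigma: float, sd: float) -> np.ndarray:
    """White noise smoothed by a Gaussian kernel, rescaled to SD ``sd``.

    Rescaling uses the kernel's L2 norm (smoothing an impulse), so the
    marginal voxel SD is ``sd`` regardless of the smoothing width.
    """
    noise = rng.standard_normal(shape)
    if sigma <= 0:
        return sd * noise
    smoothed = ndimage.gaussian_filter(noise, sigma=sigma, mode="wrap")
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    kernel = ndimage.gaussian_filter(impulse, sigma=sigma, mode="wrap")
    scale = np.sqrt(np.sum(kernel**2))
    return sd * smoothed / scale


def simulate_cohort(cfg: GenerativeConfig) -> SimulatedCohort:
    """Generate a cohort with planted brain-outcome effects.

    Subject ``i`` receives a volume ``template + sum_r effect_size_r *
    latent_i`` within each region ``r`` plus smoothed noise, and an outcome
    ``outcome_sign * loading * latent_i + gamma_age*age_i +
    gamma_education*edu_i + eps_i``.  Diagnosis categories (CN, MCI,
    Dementia) are tertiles of outcome severity by default.
    """
    if cfg.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    for name in ("latent_sd", "noise_sd", "outcome_noise_sd", "noise_smooth_sigma"):
        if getattr(cfg, name) < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(cfg.seed)
    tseed = int(rng.integers(2**31))
    if cfg.template_seed is not None:
        tseed = cfg.template_seed
    template = make_template(cfg.shape, seed=tseed)

    effect_field = np.zeros(cfg.shape)
    truth = np.zeros(cfg.shape, dtype=bool)
    for spec in cfg.effects:
        ind = spec.indicator(cfg.shape)
        effect_field += spec.effect_size * ind
        if spec.effect_size != 0:
            truth |= ind

    n = cfg.n_subjects
    latent = cfg.latent_sd * rng.standard_normal(n)
    age = rng.uniform(55.0, 90.0, n)
    gender = rng.integers(0, 2, n).astype(float)
    education = rng.uniform(8.0, 20.0, n)
    eps = cfg.outcome_noise_sd * rng.standard_normal(n)
    outcome = (
        cfg.outcome_sign * cfg.outcome_loading * latent
        + cfg.gamma_age * age
        + cfg.gamma_education * education
        + eps
    )

    # severity: larger = worse, independent of scoring direction
    severity = -cfg.outcome_sign * outcome
    cuts = np.quantile(severity, cfg.diagnosis_quantiles)
    diagnosis = np.where(severity <= cuts[0], "CN", np.where(severity <= cuts[1], "MCI", "Dementia"))

    ids = [f"sub-{i:04d}" for i in range(n)]
    volumes: dict[str, Volume] = {}
    for i, sid in enumerate(ids):
        noise = _smoothed_noise(rng, cfg.shape, cfg.noise_smooth_sigma, cfg.noise_sd)
        volumes[sid] = template.like(template.data + effect_field * latent[i] + noise)

    table = pd.DataFrame(
        {
            "subject_id": ids,
            "age": age,
            "gender": gender,
            "education": education,
            cfg.outcome_name: outcome,
            "diagnosis": diagnosis,
            "latent": latent,
            "seed": cfg.seed,
        }
    )
    cohort = CohortTable(table, outcomes=(cfg.outcome_name,))
    truth_mask = BinaryMask(truth, template.voxel_size, template.space_tag)
    return SimulatedCohort(cohort, volumes, truth_mask, template, cfg)


def split_discovery_validation(
    cohort: CohortTable, fraction: float, seed: int
) -> tuple[CohortTable, CohortTable]:
    """Disjoint discovery/validation partition, reproducible given seed."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(cohort)
    n_disc = int(round(fraction * n))
    if n_disc == 0 or n_disc == n:
        raise ValueError(f"fraction {fraction} yields an empty side for n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    ids = cohort.subject_ids
    disc_ids, val_ids = ids[perm[:n_disc]], ids[perm[n_disc:]]
    return cohort.subset(disc_ids), cohort.subset(val_ids)
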