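"""Nonparametric cluster-size inference.

Suprathreshold voxels of a t-map are grouped into connected components and
a component is retained only if its size reaches the empirical 95th
percentile (inclusive) of the maximal-cluster-size distribution obtained by
permutation.  Permutations follow the Freedman-Lane scheme: residuals of
the outcome under the nuisance-only model (age, gender, education) are
shuffled and added back to the nuisance fit, preserving covariate structure.
A raw outcome shuffle is available for comparison.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from . import glm
from .volumes import BinaryMask, CohortTable, Volume

__all__ = [
    "ClusterSet",
    "NullClusterDistribution",
    "DiscoveryConfig",
    "SignatureMaskSet",
    "label_clusters",
    "permutation_null",
    "significant_mask",
    "discover_signature_masks",
    "fwer_calibration",
]

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclasses.dataclass
class ClusterSet:
    """Connected suprathreshold components, largest first.

    ``clusters`` holds flat (raveled) voxel indices per component; ordering
    is deterministic: size descending, ties broken by smallest linear index.
    """

    clusters: list[np.ndarray]
    shape: tuple[int, int, int]
    t_thresh: float
    connectivity: int

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    @property
    def max_size(self) -> int:
        return max(self.sizes, default=0)


@dataclasses.dataclass
class NullClusterDistribution:
    """Per-permutation maximal suprathreshold cluster sizes."""

    max_sizes: np.ndarray
    n_perm: int
    t_thresh: float
    seed: int | None

    def threshold(self, alpha: float = 0.05) -> int:
        """Smallest size s with at least (1-alpha)*n_perm null values <= s."""
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        s = np.sort(self.max_sizes)
        k = math.ceil((1 - alpha) * len(s))
        return int(s[k - 1])


@dataclasses.dataclass
class SignatureMaskSet:
    """Significant-cluster masks at each t-level (the TsROI masks)."""

    masks: dict[float, BinaryMask]
    provenance: dict = dataclasses.field(default_factory=dict)

    @property
    def t_levels(self) -> tuple[float, ...]:
        return tuple(sorted(self.masks))

    def mask_at(self, t: float) -> BinaryMask:
        return self.masks[t]


@dataclasses.dataclass
class DiscoveryConfig:
    """Settings for one discovery run (per subset)."""

    t_levels: tuple[float, ...] = (3.0, 5.0, 7.0)
    n_perm: int = 2000
    direction: str = "positive"
    connectivity: int = 26
    alpha: float = 0.05
    scheme: str = "freedman-lane"  # or "raw"
    seed: int = 0


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    return ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])


def label_clusters(mask: BinaryMask, connectivity: int = 26) -> ClusterSet:
    """Connected-component decomposition of a binary mask."""
    labels, n = ndimage.label(mask.data, structure=_structure(connectivity))
    flat = labels.ravel()
    comps: list[np.ndarray] = []
    if n:
        order = np.argsort(flat, kind="stable")
        sorted_labels = flat[order]
        bounds = np.searchsorted(sorted_labels, np.arange(1, n + 2))
        comps = [np.sort(order[bounds[i] : bounds[i + 1]]) for i in range(n)]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return ClusterSet(comps, mask.shape, t_thresh=np.nan, connectivity=connectivity)


def _max_cluster_size(binary: np.ndarray, structure: np.ndarray) -> int:
    labels, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return 0
    return int(np.bincount(labels.ravel())[1:].max())


def _make_permutations(
    n: int, n_perm: int, seed: int | None, method: str, include_identity: bool
) -> np.ndarray:
    """(n_perm, n) array of row permutations."""
    if method == "exhaustive":
        if n > 9:
            raise ValueError("exhaustive enumeration is limited to n <= 9")
        return np.array(list(itertools.permutations(range(n))))
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=np.intp)
    start = 0
    if include_identity:
        perms[0] = np.arange(n)
        start = 1
    if method == "draw":
        for i in range(start, n_perm):
            perms[i] = rng.permutation(n)
    elif method == "unique":
        if n <= 20 and n_perm > math.factorial(n):
            raise ValueError(f"cannot draw {n_perm} distinct permutations of {n} items")
        seen = {tuple(perms[0])} if include_identity else set()
        i = start
        while i < n_perm:
            p = rng.permutation(n)
            key = tuple(p)
            if key not in seen:
                seen.add(key)
                perms[i] = p
                i += 1
    else:
        raise ValueError(f"unknown permutation method {method!r}")
    return perms


@dataclasses.dataclass
class _PreparedDesign:
    """Residualized quantities reused across permutations and t-levels."""

    Z: np.ndarray
    Gres: np.ndarray
    gg: np.ndarray
    yres: np.ndarray
    yhat: np.ndarray
    e: np.ndarray
    y: np.ndarray
    df: int
    mask: BinaryMask


def _prepare(
    cohort: CohortTable,
    volumes,
    mask: BinaryMask,
    outcome: str,
    covariates: Sequence[str] = glm.COVARIATES,
) -> _PreparedDesign:
    sub = cohort.complete_cases(outcome)
    Z = glm.nuisance_design(sub, covariates)
    n, p = len(sub), Z.shape[1] + 1
    if n <= p + 1:
        raise ValueError(f"n={n} too small for {p} predictors")
    G = glm.masked_matrix(volumes, mask, ids=sub.subject_ids)
    y = sub.table[outcome].to_numpy(dtype=float)
    Gres = glm.residualize(G, Z)
    gg = np.sum(Gres**2, axis=0)
    gg[np.ptp(G, axis=0) == 0] = 0.0
    yres = glm.residualize(y, Z)
    # under Freedman-Lane the shuffled unit is the nuisance-model residual
    return _PreparedDesign(Z, Gres, gg, yres, yhat=y - yres, e=yres, y=y, df=n - p, mask=mask)


def _null_from_prepared(
    prep: _PreparedDesign,
    t_thresh: float,
    direction: str,
    n_perm: int,
    seed: int | None,
    connectivity: int,
    scheme: str,
    method: str = "draw",
    include_identity: bool = True,
    chunk: int = 256,
) -> NullClusterDistribution:
    n = prep.Z.shape[0]
    perms = _make_permutations(n, n_perm, seed, method, include_identity)
    n_perm = len(perms)
    structure = _structure(connectivity)
    shape = prep.mask.shape
    inmask = prep.mask.data.ravel().nonzero()[0]

    max_sizes = np.empty(n_perm, dtype=int)
    for lo in range(0, n_perm, chunk):
        block = perms[lo : lo + chunk]
        if scheme == "freedman-lane":
            # y* = Zg + Pe; residualizing y* on Z leaves residualize(Pe, Z)
            Ystar = prep.e[block.T]  # (n, B) permuted residuals
            Yres = glm.residualize(Ystar, prep.Z)
        elif scheme == "raw":
            Yres = glm.residualize(prep.y[block.T], prep.Z)
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        T = glm.tvals_from_residuals(Yres, prep.Gres, prep.gg, prep.df)  # (V, B)
        with np.errstate(invalid="ignore"):
            if direction == "positive":
                sup = T >= t_thresh
            elif direction == "negative":
                sup = T <= -t_thresh
            elif direction == "absolute":
                sup = np.abs(T) >= t_thresh
            else:
                raise ValueError(f"unknown direction {direction!r}")
        for b in range(sup.shape[1]):
            binary = np.zeros(shape, dtype=bool).ravel()
            binary[inmask] = sup[:, b]
            max_sizes[lo + b] = _max_cluster_size(binary.reshape(shape), structure)
    return NullClusterDistribution(max_sizes, n_perm, t_thresh, seed)


def permutation_null(
    cohort: CohortTable,
    volumes: Mapping[str, Volume] | Sequence[Volume],
    mask: BinaryMask,
    outcome: str,
    t_thresh: float,
    direction: str = "positive",
    n_perm: int = 2000,
    seed: int | None = 0,
    connectivity: int = 26,
    scheme: str = "freedman-lane",
    method: str = "draw",
    include_identity: bool = True,
    covariates: Sequence[str] = glm.COVARIATES,
) -> NullClusterDistribution:
    """Maximal-cluster-size null distribution under permutation.

    By default the first permutation is the identity, so the observed
    statistic is a member of its own null (the usual convention that keeps
    the test exact).  ``method='unique'`` draws distinct permutations;
    ``method='exhaustive'`` enumerates all n! (small n only).
    """
    prep = _prepare(cohort, volumes, mask, outcome, covariates)
    return _null_from_prepared(
        prep, t_thresh, direction, n_perm, seed, connectivity, scheme, method, include_identity
    )


def significant_mask(
    observed: ClusterSet, null: NullClusterDistribution, alpha: float = 0.05
) -> BinaryMask:
    """Union of observed clusters at or above the null's (1-alpha) quantile."""
    if not math.isnan(observed.t_thresh) and not math.isnan(null.t_thresh):
        if observed.t_thresh != null.t_thresh:
            raise ValueError(
                f"t-threshold mismatch: observed {observed.t_thresh} vs null {null.t_thresh}"
            )
    cut = null.threshold(alpha)
    out = np.zeros(observed.shape, dtype=bool).ravel()
    for comp in observed.clusters:
        if len(comp) >= max(cut, 1):
            out[comp] = True
    return BinaryMask(out.reshape(observed.shape))


def discover_signature_masks(
    cohort: CohortTable,
    volumes: Mapping[str, Volume] | Sequence[Volume],
    mask: BinaryMask,
    outcome: str,
    config: DiscoveryConfig | None = None,
) -> SignatureMaskSet:
    """One discovery run: t-map, then per t-level a permutation-calibrated
    significant-cluster mask (TsROI)."""
    cfg = config or DiscoveryConfig()
    prep = _prepare(cohort, volumes, mask, outcome)
    t_obs = glm.tvals_from_residuals(prep.yres, prep.Gres, prep.gg, prep.df)
    ss = np.random.SeedSequence(cfg.seed)
    level_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(len(cfg.t_levels))]

    masks: dict[float, BinaryMask] = {}
    shape = mask.shape
    inmask = mask.data.ravel().nonzero()[0]
    for t_level, lseed in zip(cfg.t_levels, level_seeds):
        with np.errstate(invalid="ignore"):
            if cfg.direction == "positive":
                sup = t_obs >= t_level
            elif cfg.direction == "negative":
                sup = t_obs <= -t_level
            else:
                sup = np.abs(t_obs) >= t_level
        binary = np.zeros(shape, dtype=bool).ravel()
        binary[inmask] = sup
        obs_mask = mask.like_mask(binary.reshape(shape))
        observed = label_clusters(obs_mask, cfg.connectivity)
        observed.t_thresh = t_level
        null = _null_from_prepared(
            prep, t_level, cfg.direction, cfg.n_perm, lseed, cfg.connectivity, cfg.scheme
        )
        sig = significant_mask(observed, null, cfg.alpha)
        masks[t_level] = mask.like_mask(sig.data)
    prov = {
        "outcome": outcome,
        "n_subjects": prep.Z.shape[0],
        "t_levels": list(cfg.t_levels),
        "n_perm": cfg.n_perm,
        "direction": cfg.direction,
        "connectivity": cfg.connectivity,
        "alpha": cfg.alpha,
        "scheme": cfg.scheme,
        "seed": cfg.seed,
    }
    return SignatureMaskSet(masks, prov)


def fwer_calibration(
    n_datasets: int = 200,
    shape: tuple[int, int, int] = (16, 16, 16),
    n_subjects: int = 60,
    t_thresh: float = 3.0,
    n_perm: int = 500,
    alpha: float = 0.05,
    direction: str = "positive",
    connectivity: int = 26,
    seed: int = 0,
) -> float:
    """Empirical family-wise error rate under a no-effect generative model.

    Simulates independent null cohorts (smoothed imaging noise, outcome
    driven only by demographics and noise), runs the full threshold +
    permutation retention procedure on each, and returns the fraction of
    datasets in which any cluster is retained.
    """
    from . import synthetic
    from .volumes import make_analysis_mask

    ss = np.random.SeedSequence(seed)
    hits = 0
    for child in ss.spawn(n_datasets):
        dseed = int(child.generate_state(1)[0] % 2**31)
        cfg = synthetic.GenerativeConfig(
            n_subjects=n_subjects, shape=shape, effects=(), outcome_loading=0.0, seed=dseed
        )
        sim = synthetic.simulate_cohort(cfg)
        mask = make_analysis_mask(sim.template, cfg.min_density)
        prep = _prepare(sim.cohort, sim.volumes, mask, cfg.outcome_name)
        t_obs = glm.tvals_from_residuals(prep.yres, prep.Gres, prep.gg, prep.df)
        binary = np.zeros(shape, dtype=bool).ravel()
        with np.errstate(invalid="ignore"):
            binary[mask.data.ravel().nonzero()[0]] = t_obs >= t_thresh
        observed = label_clusters(mask.like_mask(binary.reshape(shape)), connectivity)
        null = _null_from_prepared(
            prep, t_thresh, direction, n_perm, dseed + 1, connectivity, "freedman-lane"
        )
        sig = significant_mask(observed, null, alpha)
        hits += int(sig.data.any())
    return hits / n_datasets
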