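"""Random-subset discovery and consensus signature masks.

Discovery is repeated over many randomly chosen subsets of the discovery
cohort (default 40 subsets of size 400, each drawn uniformly without
replacement within itself; subsets are mutually independent, so pairwise
overlaps follow the hypergeometric expectation size^2/N).  Per t-level the
subset TsROI masks are summed into an overlap frequency map, and the
consensus mask keeps voxels present in at least a fraction (default 70%,
inclusive via ceiling) of the subsets.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

from .clusters import DiscoveryConfig, SignatureMaskSet, discover_signature_masks
from .volumes import BinaryMask, CohortTable, Volume, check_aligned

__all__ = [
    "FrequencyMap",
    "ConsensusConfig",
    "ConsensusResult",
    "sample_subsets",
    "frequency_map",
    "consensus_mask",
    "run_consensus_discovery",
]


@dataclasses.dataclass
class FrequencyMap:
    """Voxelwise count of subset TsROI masks containing each voxel."""

    counts: Volume
    k: int
    t_thresh: float

    def fraction(self) -> Volume:
        return self.counts.like(self.counts.data / self.k)


@dataclasses.dataclass
class ConsensusConfig:
    """Consensus-discovery settings (defaults: 40 subsets of 400, 70%)."""

    k_subsets: int = 40
    subset_size: int = 400
    consensus_fraction: float = 0.70
    discovery: DiscoveryConfig = dataclasses.field(default_factory=DiscoveryConfig)
    seed: int = 0


@dataclasses.dataclass
class ConsensusResult:
    """Consensus masks plus the per-level frequency maps and subset masks."""

    mask_set: SignatureMaskSet
    frequency_maps: dict[float, FrequencyMap]
    subset_ids: list[np.ndarray]
    provenance: dict


def sample_subsets(
    ids: Sequence, k_subsets: int, subset_size: int, seed: int | None = 0
) -> list[np.ndarray]:
    """Draw ``k_subsets`` uniform subsets of ``subset_size`` ids.

    Sampling is without replacement within each subset; subsets are drawn
    independently of one another, so they generally overlap.
    """
    ids = np.asarray(ids)
    if subset_size > len(ids):
        raise ValueError(f"subset_size {subset_size} exceeds pool of {len(ids)} ids")
    if k_subsets < 1:
        raise ValueError("k_subsets must be >= 1")
    rng = np.random.default_rng(seed)
    return [rng.choice(ids, size=subset_size, replace=False) for _ in range(k_subsets)]


def mean_pairwise_intersection(subsets: Sequence[np.ndarray]) -> float:
    """Mean intersection size over all subset pairs."""
    sets = [set(s.tolist()) for s in subsets]
    sizes = [
        len(sets[i] & sets[j]) for i in range(len(sets)) for j in range(i + 1, len(sets))
    ]
    return float(np.mean(sizes))


def frequency_map(masks: Sequence[BinaryMask], t_thresh: float = np.nan) -> FrequencyMap:
    """Voxelwise sum of aligned mask indicators."""
    if not masks:
        raise ValueError("at least one mask is required")
    check_aligned(*masks)
    counts = np.zeros(masks[0].shape, dtype=int)
    for m in masks:
        counts += m.data
    return FrequencyMap(masks[0].like(counts), k=len(masks), t_thresh=t_thresh)


def consensus_mask(freq: FrequencyMap, threshold_fraction: float = 0.70) -> BinaryMask:
    """Voxels present in at least ceil(fraction * K) of the subset masks."""
    if not 0 < threshold_fraction <= 1:
        raise ValueError("threshold_fraction must be in (0, 1]")
    need = math.ceil(threshold_fraction * freq.k)
    return BinaryMask(
        freq.counts.data >= need, freq.counts.voxel_size, freq.counts.space_tag
    )


def run_consensus_discovery(
    cohort: CohortTable,
    volumes: Mapping[str, Volume] | Sequence[Volume],
    mask: BinaryMask,
    outcome: str,
    config: ConsensusConfig | None = None,
) -> ConsensusResult:
    """Full consensus discovery: subsets -> TsROIs -> frequency -> consensus.

    One master seed spawns a fixed sub-seed per subset, so subsets could be
    recomputed independently (e.g., in parallel) with identical results.
    """
    cfg = config or ConsensusConfig()
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.k_subsets + 1)
    sample_seed = int(children[0].generate_state(1)[0] % 2**31)
    sub = cohort.complete_cases(outcome)
    subset_ids = sample_subsets(sub.subject_ids, cfg.k_subsets, cfg.subset_size, sample_seed)

    per_level: dict[float, list[BinaryMask]] = {t: [] for t in cfg.discovery.t_levels}
    empties = 0
    for child, ids in zip(children[1:], subset_ids):
        dcfg = dataclasses.replace(
            cfg.discovery, seed=int(child.generate_state(1)[0] % 2**31)
        )
        mset = discover_signature_masks(sub.subset(ids), volumes, mask, outcome, dcfg)
        for t, m in mset.masks.items():
            per_level[t].append(m)

    freq_maps: dict[float, FrequencyMap] = {}
    cons: dict[float, BinaryMask] = {}
    for t, level_masks in per_level.items():
        freq_maps[t] = frequency_map(level_masks, t_thresh=t)
        cons[t] = consensus_mask(freq_maps[t], cfg.consensus_fraction)
        if not cons[t].data.any():
            empties += 1
    prov = {
        "outcome": outcome,
        "k_subsets": cfg.k_subsets,
        "subset_size": cfg.subset_size,
        "consensus_fraction": cfg.consensus_fraction,
        "seed": cfg.seed,
        "n_pool": len(sub),
        "empty_consensus_levels": empties,
        "discovery": dataclasses.asdict(cfg.discovery),
    }
    return ConsensusResult(SignatureMaskSet(cons, prov), freq_maps, subset_ids, prov)
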