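"""End-to-end orchestration of the signature workbench.

A :class:`RunConfig` carries every tunable of the discovery-validation
pipeline; defaults match the production-scale protocol (40 discovery
subsets of 400, t-levels 3/5/7 with 2000 permutations each, 70% consensus,
50 validation subsets of 200, 10,000 bootstrap iterations at the
80/90/95/99% CI levels).  Each stage writes its artifacts plus a
``provenance.json`` recording the full config, its hash, and the master
seed, so a re-run with the same config reproduces every numeric output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import consensus as cns
from . import evaluation, signature, similarity, synthetic
from .clusters import DiscoveryConfig, SignatureMaskSet
from .volumes import (
    CohortTable,
    Volume,
    make_analysis_mask,
    read_cohort,
    read_mask,
    read_volume,
    write_volume,
)

__all__ = ["RunConfig", "run_pipeline"]

STAGES = ("simulate", "discover", "consensus", "fit", "validate", "compare", "similarity")


@dataclasses.dataclass
class RunConfig:
    """Every pipeline parameter, serialized verbatim into provenance."""

    outcome: str = "memory"
    direction: str = "positive"
    # discovery
    k_subsets: int = 40
    subset_size: int = 400
    t_levels: tuple[float, ...] = (3.0, 5.0, 7.0)
    n_perm: int = 2000
    connectivity: int = 26
    consensus_fraction: float = 0.70
    alpha: float = 0.05
    # validation
    val_n_subsets: int = 50
    val_subset_size: int = 200
    n_boot: int = 10000
    ci_levels: tuple[float, ...] = (0.80, 0.90, 0.95, 0.99)
    # synthetic generation (used by the simulate stage)
    n_subjects: int = 800
    shape: tuple[int, int, int] = (24, 24, 24)
    effect_size: float = 0.05
    discovery_fraction: float = 0.5
    min_density: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("t_levels", "ci_levels", "shape"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _provenance(cfg: RunConfig, stage: str, extra: dict | None = None) -> dict:
    return {
        "stage": stage,
        "config": cfg.to_dict(),
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        **(extra or {}),
    }


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def _require(path: Path, what: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing {what}: expected artifact at {path}")
    return path


def _load_volumes(cohort: CohortTable, vol_dir: Path) -> dict[str, Volume]:
    return {
        sid: read_volume(_require(vol_dir / f"{sid}.nii.gz", f"volume for {sid}"))
        for sid in cohort.subject_ids
    }


def _load_mask_set(d: Path, t_levels: Sequence[float]) -> SignatureMaskSet:
    masks = {
        t: read_mask(_require(d / f"consensus_t{t:g}.nii.gz", f"consensus mask t={t:g}"))
        for t in t_levels
    }
    return SignatureMaskSet(masks, {"source": str(d)})


def _stage_simulate(cfg: RunConfig, out: Path) -> None:
    center = tuple(s // 2 for s in cfg.shape)
    effect = synthetic.EffectSpec("box", center, extent=4, effect_size=cfg.effect_size)
    gcfg = synthetic.GenerativeConfig(
        n_subjects=cfg.n_subjects,
        shape=cfg.shape,
        effects=(effect,),
        outcome_name=cfg.outcome,
        min_density=cfg.min_density,
        seed=cfg.seed,
    )
    sim = synthetic.simulate_cohort(gcfg)
    vols = out / "volumes"
    vols.mkdir(parents=True, exist_ok=True)
    for sid, v in sim.volumes.items():
        write_volume(v, vols / f"{sid}.nii.gz")
    write_volume(sim.template, out / "template.nii.gz")
    write_volume(sim.truth_mask, out / "truth_mask.nii.gz")
    disc, val = synthetic.split_discovery_validation(
        sim.cohort, cfg.discovery_fraction, seed=cfg.seed + 1
    )
    sim.cohort.table.to_csv(out / "cohort.csv", index=False)
    disc.table.to_csv(out / "cohort_discovery.csv", index=False)
    val.table.to_csv(out / "cohort_validation.csv", index=False)
    _write_json(
        _provenance(cfg, "simulate", {"generator": dataclasses.asdict(gcfg) | {"effects": "1 box"}}),
        out / "provenance.json",
    )


def _discovery_inputs(cfg: RunConfig, out: Path):
    cohort = read_cohort(_require(out / "cohort_discovery.csv", "discovery cohort table"),
                         outcomes=(cfg.outcome,))
    template = read_volume(_require(out / "template.nii.gz", "template volume"))
    mask = make_analysis_mask(template, cfg.min_density)
    volumes = _load_volumes(cohort, _require(out / "volumes", "volume directory"))
    return cohort, volumes, mask


def _stage_discover(cfg: RunConfig, out: Path) -> None:
    cohort, volumes, mask = _discovery_inputs(cfg, out)
    ccfg = cns.ConsensusConfig(
        k_subsets=cfg.k_subsets,
        subset_size=cfg.subset_size,
        consensus_fraction=cfg.consensus_fraction,
        discovery=DiscoveryConfig(
            t_levels=cfg.t_levels,
            n_perm=cfg.n_perm,
            direction=cfg.direction,
            connectivity=cfg.connectivity,
            alpha=cfg.alpha,
        ),
        seed=cfg.seed,
    )
    res = cns.run_consensus_discovery(cohort, volumes, mask, cfg.outcome, ccfg)
    d = out / "discover"
    d.mkdir(exist_ok=True)
    for t in cfg.t_levels:
        write_volume(res.mask_set.mask_at(t), d / f"consensus_t{t:g}.nii.gz")
        write_volume(res.frequency_maps[t].counts, d / f"frequency_t{t:g}.nii.gz")
    _write_json(_provenance(cfg, "discover", {"discovery": res.provenance}), d / "provenance.json")


def _stage_fit(cfg: RunConfig, out: Path) -> None:
    cohort = read_cohort(_require(out / "cohort_validation.csv", "validation cohort table"),
                         outcomes=(cfg.outcome,))
    volumes = _load_volumes(cohort, _require(out / "volumes", "volume directory"))
    mask_set = _load_mask_set(_require(out / "discover", "discovery artifacts"), cfg.t_levels)
    means = signature.roi_mean_vector(volumes, mask_set, ids=list(cohort.subject_ids))
    model, S = signature.fit_signature_variable(cohort, means, cfg.outcome)
    fits = [
        signature.fit_outcome_model(cohort, [], cfg.outcome, label="demographics"),
        signature.fit_outcome_model(cohort, {"S": S}, cfg.outcome, label="signature"),
    ]
    d = out / "fit"
    d.mkdir(exist_ok=True)
    means.assign(S=S.to_numpy()).to_csv(d / "tsroi_means.csv")
    pd.DataFrame(
        [
            {"model": f.label, "n": f.n, "p": f.p, "r2": f.r2, "adj_r2": f.adj_r2}
            for f in fits
        ]
    ).to_csv(d / "fits.csv", index=False)
    _write_json(
        _provenance(
            cfg,
            "fit",
            {
                "signature_terms": list(model.terms),
                "signature_coefficients": list(model.coefficients),
                "collinear": model.collinear,
            },
        ),
        d / "provenance.json",
    )


def _stage_validate(cfg: RunConfig, out: Path) -> None:
    cohort = read_cohort(_require(out / "cohort_validation.csv", "validation cohort table"),
                         outcomes=(cfg.outcome,))
    volumes = _load_volumes(cohort, _require(out / "volumes", "volume directory"))
    mask_set = _load_mask_set(_require(out / "discover", "discovery artifacts"), cfg.t_levels)
    second = out / "discover_b"
    mask_set_b = _load_mask_set(second, cfg.t_levels) if second.exists() else mask_set
    paired = evaluation.replication_trial(
        cohort,
        volumes,
        mask_set,
        mask_set_b,
        cfg.outcome,
        n_subsets=cfg.val_n_subsets,
        subset_size=min(cfg.val_subset_size, len(cohort)),
        seed=cfg.seed,
    )
    ba = evaluation.bland_altman(paired)
    d = out / "validate"
    d.mkdir(exist_ok=True)
    paired.table.to_csv(d / "paired_fits.csv", index=False)
    _write_json(_provenance(cfg, "validate", {"bland_altman": dataclasses.asdict(ba)}),
                d / "provenance.json")


def _stage_compare(cfg: RunConfig, out: Path) -> None:
    cohort = read_cohort(_require(out / "cohort_validation.csv", "validation cohort table"),
                         outcomes=(cfg.outcome,))
    volumes = _load_volumes(cohort, _require(out / "volumes", "volume directory"))
    mask_set = _load_mask_set(_require(out / "discover", "discovery artifacts"), cfg.t_levels)
    means = signature.roi_mean_vector(volumes, mask_set, ids=list(cohort.subject_ids))
    res = evaluation.bootstrap_r2_difference(
        cohort,
        means,
        cfg.outcome,
        competitor="demographics",
        n_boot=cfg.n_boot,
        levels=cfg.ci_levels,
        seed=cfg.seed,
    )
    d = out / "compare"
    d.mkdir(exist_ok=True)
    _write_json(
        _provenance(
            cfg,
            "compare",
            {
                "competitor": "demographics",
                "point_difference": res.point_difference,
                "intervals": {f"{lv:g}": res.intervals[lv] for lv in res.intervals},
                "superiority": {f"{lv:g}": res.superiority[lv] for lv in res.superiority},
            },
        ),
        d / "provenance.json",
    )


def _stage_similarity(cfg: RunConfig, out: Path) -> None:
    mask_set = _load_mask_set(_require(out / "discover", "discovery artifacts"), cfg.t_levels)
    report: dict = {}
    truth_path = out / "truth_mask.nii.gz"
    if truth_path.exists():
        truth = read_mask(truth_path)
        outer = mask_set.mask_at(mask_set.t_levels[0])
        if outer.data.any() or truth.data.any():
            report["dice_vs_truth"] = similarity.dice(outer, truth)
    second = out / "discover_b"
    if second.exists():
        other = _load_mask_set(second, cfg.t_levels)
        report["dice_between_sets"] = similarity.mask_set_dice(mask_set, other)
        report["eta2_between_sets"] = similarity.mask_set_eta2(mask_set, other)
    d = out / "similarity"
    d.mkdir(exist_ok=True)
    _write_json(_provenance(cfg, "similarity", {"scores": report}), d / "provenance.json")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "discover": _stage_discover,
    "consensus": _stage_discover,  # discovery and consensus run as one unit
    "fit": _stage_fit,
    "validate": _stage_validate,
    "compare": _stage_compare,
    "similarity": _stage_similarity,
}


def run_pipeline(config: RunConfig, stages: Sequence[str], outdir: str | Path) -> Path:
    """Run the requested stages, writing artifacts under ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seen = set()
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
        fn = _STAGE_FUNCS[stage]
        if fn in seen:
            continue
        seen.add(fn)
        fn(config, out)
    return out
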