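"""Replicability and superiority evaluation of signature models.

Three questions are addressed on a validation cohort disjoint from
discovery: (a) do two independently discovered signature models fit the
outcome equally well across many random validation subsets (paired
adjusted-R^2 scatter and Bland-Altman agreement)?  (b) does the signature
model beat competitor models (bootstrap percentile confidence intervals of
the adjusted-R^2 difference at the 80/90/95/99% levels, with superiority
declared when an interval lies entirely above zero)?  (c) does the
signature's slope differ by clinical diagnosis (partial-F interaction
test)?
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import SignatureMaskSet
from .signature import DEMOGRAPHICS, roi_mean_vector
from .volumes import CohortTable, Volume

__all__ = [
    "PairedFitTable",
    "BlandAltmanResult",
    "BootstrapCIResult",
    "replication_trial",
    "bland_altman",
    "bootstrap_r2_difference",
    "diagnosis_interaction",
]


@dataclasses.dataclass
class PairedFitTable:
    """Adjusted R^2 of two signature models over identical subsets."""

    table: pd.DataFrame  # columns: subset, r2_a, r2_b
    subset_size: int
    seed: int

    @property
    def differences(self) -> np.ndarray:
        return (self.table["r2_b"] - self.table["r2_a"]).to_numpy()


@dataclasses.dataclass
class BlandAltmanResult:
    bias: float
    loa_lower: float
    loa_upper: float
    ci_lower: float
    ci_upper: float
    ci_level: float
    n: int
    significant_bias: bool
    degenerate: bool = False


@dataclasses.dataclass
class BootstrapCIResult:
    """Percentile CIs of adjusted R^2_S - adjusted R^2_M per level."""

    intervals: dict[float, tuple[float, float]]
    superiority: dict[float, bool]
    point_difference: float
    n_boot: int
    seed: int
    n_redrawn: int = 0


def _adj_r2(X: np.ndarray, y: np.ndarray) -> float:
    n, k = X.shape
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise np.linalg.LinAlgError("rank-deficient design")
    resid = y - X @ coef
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 0.0 if tss == 0 else 1.0 - float(resid @ resid) / tss
    p = k - 1
    return r2 if p == 0 else 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _signature_adj_r2(means: np.ndarray, demog: np.ndarray, y: np.ndarray) -> float:
    """Refit the signature regression in the given set, then the outcome
    model on [S, demographics]."""
    n = len(y)
    Xs = np.column_stack([np.ones(n), means])
    coef, *_ = np.linalg.lstsq(Xs, y, rcond=None)
    S = Xs @ coef
    X = np.column_stack([np.ones(n), S, demog])
    return _adj_r2(X, y)


def replication_trial(
    validation_cohort: CohortTable,
    volumes: Mapping[str, Volume] | Sequence[Volume],
    model_a_masks: SignatureMaskSet,
    model_b_masks: SignatureMaskSet,
    outcome: str,
    n_subsets: int = 50,
    subset_size: int = 200,
    seed: int = 0,
    discovery_ids: Sequence | None = None,
) -> PairedFitTable:
    """Paired signature fits over random validation subsets.

    Both signature variables are refit within each subset (the signature
    regression, then the outcome model controlling for demographics) and
    their adjusted R^2 recorded.  ``discovery_ids``, when provided, asserts
    the validation cohort is disjoint from discovery.
    """
    sub = validation_cohort.complete_cases(outcome)
    if discovery_ids is not None:
        overlap = set(sub.subject_ids) & set(discovery_ids)
        if overlap:
            raise ValueError(f"validation cohort overlaps discovery ids: {sorted(overlap)[:5]}")
    if subset_size > len(sub):
        raise ValueError(f"subset_size {subset_size} exceeds cohort of {len(sub)}")

    ids = list(sub.subject_ids)
    means_a = roi_mean_vector(volumes, model_a_masks, ids=ids).to_numpy()
    means_b = roi_mean_vector(volumes, model_b_masks, ids=ids).to_numpy()
    demog = sub.table[list(DEMOGRAPHICS)].to_numpy(dtype=float)
    y = sub.table[outcome].to_numpy(dtype=float)

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subsets):
        take = rng.choice(len(ids), size=subset_size, replace=False)
        rows.append(
            {
                "subset": s,
                "r2_a": _signature_adj_r2(means_a[take], demog[take], y[take]),
                "r2_b": _signature_adj_r2(means_b[take], demog[take], y[take]),
            }
        )
    return PairedFitTable(pd.DataFrame(rows), subset_size, seed)


def bland_altman(paired: PairedFitTable | np.ndarray, ci_level: float = 0.95) -> BlandAltmanResult:
    """Agreement of paired fits: bias, 1.96-SD limits, t-based CI of bias."""
    diffs = paired.differences if isinstance(paired, PairedFitTable) else np.asarray(paired, float)
    n = len(diffs)
    if n < 3:
        raise ValueError("Bland-Altman requires at least 3 paired differences")
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    loa = 1.96 * sd
    degenerate = sd == 0
    if degenerate:
        ci_lo = ci_hi = bias
    else:
        half = stats.t.ppf(0.5 + ci_level / 2, n - 1) * sd / np.sqrt(n)
        ci_lo, ci_hi = bias - half, bias + half
    significant = (ci_lo > 0 or ci_hi < 0) and not (degenerate and bias == 0)
    return BlandAltmanResult(
        bias, bias - loa, bias + loa, ci_lo, ci_hi, ci_level, n, bool(significant), degenerate
    )


def bootstrap_r2_difference(
    cohort: CohortTable,
    tsroi_means: pd.DataFrame,
    outcome: str,
    competitor: str = "demographics",
    competitor_means: pd.DataFrame | None = None,
    drop_covariates: Sequence[str] = (),
    n_boot: int = 10000,
    levels: Sequence[float] = (0.80, 0.90, 0.95, 0.99),
    seed: int = 0,
    max_redraws: int = 100,
    method: str = "percentile",
) -> BootstrapCIResult:
    """Bootstrap CIs for adjusted R^2_S - adjusted R^2_M.

    Subjects are resampled with replacement; both models are refit inside
    every resample (the signature regression included) and the difference
    of adjusted R^2 recorded.  ``competitor`` is ``"demographics"``, or a
    column of ``competitor_means`` (single-ROI model), or ``"four_rois"``
    (all columns of ``competitor_means`` jointly).  ``drop_covariates``
    removes demographic covariates from both models.  Rank-deficient
    resamples are redrawn and counted.

    ``method`` selects percentile intervals (default) or ``"bca"``
    (bias-corrected and accelerated, with jackknife acceleration).
    """
    sub = cohort.complete_cases(outcome)
    ids = list(sub.subject_ids)
    covs = [c for c in DEMOGRAPHICS if c not in set(drop_covariates)]
    demog = sub.table[covs].to_numpy(dtype=float)
    y = sub.table[outcome].to_numpy(dtype=float)
    means = tsroi_means.loc[ids].to_numpy()

    if competitor == "demographics":
        comp: np.ndarray | None = None
    elif competitor == "four_rois":
        if competitor_means is None:
            raise ValueError("four_rois competitor requires competitor_means")
        comp = competitor_means.loc[ids].to_numpy()
    elif competitor == "signature":
        comp = None  # self-comparison: difference identically zero
    else:
        if competitor_means is None or competitor not in competitor_means.columns:
            raise ValueError(f"unknown competitor {competitor!r}")
        comp = competitor_means.loc[[*ids]][[competitor]].to_numpy()

    def diff_for(idx: np.ndarray) -> float:
        r2_s = _signature_adj_r2(means[idx], demog[idx], y[idx])
        if competitor == "signature":
            return r2_s - r2_s
        if comp is None:
            Xm = np.column_stack([np.ones(len(idx)), demog[idx]])
        else:
            Xm = np.column_stack([np.ones(len(idx)), comp[idx], demog[idx]])
        return r2_s - _adj_r2(Xm, y[idx])

    n = len(ids)
    point = diff_for(np.arange(n))
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    redrawn = 0
    for b in range(n_boot):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            try:
                diffs[b] = diff_for(idx)
                break
            except np.linalg.LinAlgError:
                redrawn += 1
        else:
            raise RuntimeError("could not draw a full-rank bootstrap resample")

    if method == "percentile":
        def bounds(lv: float) -> tuple[float, float]:
            lo, hi = np.percentile(diffs, [50 * (1 - lv), 50 * (1 + lv)])
            return float(lo), float(hi)
    elif method == "bca":
        # bias correction from the bootstrap distribution, acceleration
        # from the jackknife of the leave-one-out differences
        z0 = stats.norm.ppf(np.clip(np.mean(diffs < point), 1e-6, 1 - 1e-6))
        jack = np.array([diff_for(np.delete(np.arange(n), i)) for i in range(n)])
        dev = jack.mean() - jack
        denom = 6.0 * (np.sum(dev**2) ** 1.5)
        acc = np.sum(dev**3) / denom if denom > 0 else 0.0

        def bounds(lv: float) -> tuple[float, float]:
            out = []
            for z in (stats.norm.ppf((1 - lv) / 2), stats.norm.ppf((1 + lv) / 2)):
                adj = stats.norm.cdf(z0 + (z0 + z) / (1 - acc * (z0 + z)))
                out.append(float(np.percentile(diffs, 100 * adj)))
            return out[0], out[1]
    else:
        raise ValueError(f"unknown CI method {method!r}")

    intervals: dict[float, tuple[float, float]] = {}
    superiority: dict[float, bool] = {}
    for lv in levels:
        lo, hi = bounds(lv)
        intervals[lv] = (lo, hi)
        superiority[lv] = bool(lo > 0)
    return BootstrapCIResult(intervals, superiority, point, n_boot, seed, redrawn)


@dataclasses.dataclass
class InteractionReport:
    """Partial-F tests for diagnosis main effect and S-by-diagnosis
    interaction in the signature outcome model."""

    p_signature: float
    p_diagnosis: float
    p_interaction: float
    f_diagnosis: float
    f_interaction: float
    levels: tuple[str, ...]
    n: int


def _block_f(X_full: np.ndarray, X_reduced: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    def rss(X):
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ coef
        return float(r @ r)
    rss_f, rss_r = rss(X_full), rss(X_reduced)
    df_num = X_full.shape[1] - X_reduced.shape[1]
    df_den = len(y) - X_full.shape[1]
    if df_num <= 0 or df_den <= 0:
        raise ValueError("invalid nested models for partial F")
    f = ((rss_r - rss_f) / df_num) / (rss_f / df_den)
    return f, float(stats.f.sf(f, df_num, df_den))


def diagnosis_interaction(
    cohort: CohortTable, S: pd.Series | np.ndarray, outcome: str
) -> InteractionReport:
    """Outcome ~ demographics + S + diagnosis + S:diagnosis.

    Diagnosis is dummy-coded; block significance uses partial F-tests
    (main effect tested in the model without interactions, interaction
    tested in the full model).
    """
    sub = cohort.complete_cases(outcome)
    if "diagnosis" not in sub.table.columns:
        raise ValueError("cohort has no diagnosis column")
    diag = sub.table["diagnosis"].astype(str)
    levels = tuple(sorted(diag.unique()))
    if len(levels) < 2:
        raise ValueError(f"diagnosis needs >= 2 levels, found {levels}")
    if isinstance(S, pd.Series) and not isinstance(S.index, pd.RangeIndex):
        S = S.loc[sub.subject_ids]
    s = np.asarray(S, dtype=float)
    n = len(sub)
    demog = sub.table[list(DEMOGRAPHICS)].to_numpy(dtype=float)
    dummies = np.column_stack([(diag == lv).to_numpy(float) for lv in levels[1:]])
    inter = dummies * s[:, None]
    y = sub.table[outcome].to_numpy(dtype=float)

    base = np.column_stack([np.ones(n), demog])
    with_s = np.column_stack([base, s])
    main = np.column_stack([with_s, dummies])
    full = np.column_stack([main, inter])

    f_sig, p_sig = _block_f(with_s, base, y)
    f_diag, p_diag = _block_f(main, with_s, y)
    f_int, p_int = _block_f(full, main, y)
    return InteractionReport(p_sig, p_diag, p_int, f_diag, f_int, levels, n)
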