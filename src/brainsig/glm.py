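"""Mass-univariate voxelwise regression.

At every analysis-mask voxel, the outcome is regressed on [intercept, GM
density at that voxel, age, gender, education] by ordinary least squares
and the t-statistic of the GM coefficient is recorded.  The vectorized
implementation uses the Frisch-Waugh-Lovell partialling identity: both the
outcome and each voxel's GM column are residualized against the nuisance
design, after which the GM t-value equals the simple-regression t of the
residuals with the full model's residual degrees of freedom.  This is
algebraically identical to a per-voxel full-design solve.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from .volumes import BinaryMask, CohortTable, Volume, check_aligned

__all__ = ["TMap", "voxelwise_tmap", "signed_threshold", "masked_matrix"]

COVARIATES = ("age", "gender", "education")


@dataclasses.dataclass
class TMap:
    """t-statistics of the GM coefficient on the analysis mask.

    Values are NaN outside the mask and at voxels with zero GM variance
    across subjects (undefined, not an error).
    """

    tvals: Volume
    mask: BinaryMask
    df: int
    outcome_name: str
    n_subjects: int

    @property
    def masked(self) -> np.ndarray:
        """1D t-values over mask voxels (NaN where undefined)."""
        return self.tvals.data[self.mask.data]


def masked_matrix(
    volumes: Mapping[str, Volume] | Sequence[Volume],
    mask: BinaryMask,
    ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Stack per-subject GM values into an (n_subjects, n_voxels) matrix.

    ``ids`` fixes the row order when ``volumes`` is a mapping; all volumes
    must be aligned with the mask.
    """
    if isinstance(volumes, Mapping):
        if ids is None:
            ids = list(volumes)
        vols = [volumes[i] for i in ids]
    else:
        vols = list(volumes)
    check_aligned(mask, *vols)
    flat = mask.data.ravel()
    return np.stack([v.data.ravel()[flat] for v in vols]).astype(np.float64)


def nuisance_design(cohort: CohortTable, covariates: Sequence[str] = COVARIATES) -> np.ndarray:
    """[intercept | covariates] design; errors on rank deficiency."""
    Z = np.column_stack(
        [np.ones(len(cohort))] + [cohort.table[c].to_numpy(dtype=float) for c in covariates]
    )
    for j, c in enumerate(covariates, start=1):
        if np.ptp(Z[:, j]) == 0:
            raise ValueError(f"rank-deficient design: covariate {c!r} is constant")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError(f"rank-deficient design over covariates {tuple(covariates)}")
    return Z


def residualize(A: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Residuals of each column of A after OLS on Z."""
    coef, *_ = np.linalg.lstsq(Z, A, rcond=None)
    return A - Z @ coef


def tvals_from_residuals(
    Yres: np.ndarray, Gres: np.ndarray, gg: np.ndarray, df: int
) -> np.ndarray:
    """GM t-statistics for one or more residualized outcome vectors.

    ``Yres``: (n,) or (n, B) residualized outcomes; ``Gres``: (n, V)
    residualized GM; ``gg``: per-voxel sum of squares of Gres.  Returns
    (V,) or (V, B).  Voxels with ``gg == 0`` come back NaN.
    """
    single = Yres.ndim == 1
    Y = Yres[:, None] if single else Yres
    num = Gres.T @ Y  # (V, B)
    with np.errstate(divide="ignore", invalid="ignore"):
        yss = np.sum(Y**2, axis=0)  # (B,)
        rss = yss[None, :] - num**2 / gg[:, None]
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df
        t = num / np.sqrt(sigma2 * gg[:, None])
    t[gg == 0, :] = np.nan
    return t[:, 0] if single else t


def voxelwise_tmap(
    cohort: CohortTable,
    volumes: Mapping[str, Volume] | Sequence[Volume],
    mask: BinaryMask,
    outcome: str,
    covariates: Sequence[str] = COVARIATES,
) -> TMap:
    """OLS t-map of the GM-density coefficient, controlling for covariates."""
    sub = cohort.complete_cases(outcome)
    n = len(sub)
    Z = nuisance_design(sub, covariates)
    p = Z.shape[1] + 1  # + GM column
    if n < 10 or n <= p + 2:
        raise ValueError(f"n={n} too small for {p} predictors")
    G = masked_matrix(volumes, mask, ids=sub.subject_ids)
    y = sub.table[outcome].to_numpy(dtype=float)

    Gres = residualize(G, Z)
    gg = np.sum(Gres**2, axis=0)
    # exact zero variance, not numerical residue of the projection
    gg[np.ptp(G, axis=0) == 0] = 0.0
    yres = residualize(y, Z)
    df = n - p
    t = tvals_from_residuals(yres, Gres, gg, df)

    tdata = np.full(mask.shape, np.nan)
    tdata[mask.data] = t
    return TMap(mask.like(tdata), mask, df, outcome, n)


def signed_threshold(tmap: TMap, t_thresh: float, direction: str = "positive") -> BinaryMask:
    """Suprathreshold mask of a t-map.

    ``direction``: "positive" keeps t >= thresh, "negative" keeps
    t <= -thresh, "absolute" keeps |t| >= thresh.  NaN voxels never pass.
    """
    if t_thresh <= 0:
        raise ValueError("t_thresh must be > 0")
    t = tmap.tvals.data
    with np.errstate(invalid="ignore"):
        if direction == "positive":
            sel = t >= t_thresh
        elif direction == "negative":
            sel = t <= -t_thresh
        elif direction == "absolute":
            sel = np.abs(t) >= t_thresh
        else:
            raise ValueError(f"unknown direction {direction!r}")
    sel &= tmap.mask.data
    return tmap.mask.like_mask(sel)
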