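"""Signature variable construction and outcome model fitting.

The signature variable S for a subject is the fitted value from an OLS
regression of the outcome on the mean GM density within the three
consensus TsROI masks (t = 3, 5, 7):

    Y = b0 + b1*TsROI1 + b2*TsROI2 + b3*TsROI3,   S = Y_hat.

Model fit is summarized by adjusted R^2 = 1 - (1-R^2)(n-1)/(n-p-1).
Competitor models share the demographic covariates (age, gender,
education) and swap the brain term: none (demographics only), a single
atlas-ROI mean, four atlas-ROI means jointly ("FourROIs"), or S.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clusters import SignatureMaskSet
from .glm import masked_matrix
from .volumes import BinaryMask, CohortTable, Volume

__all__ = [
    "SignatureModel",
    "FitResult",
    "roi_mean_vector",
    "fit_signature_variable",
    "fit_outcome_model",
    "atlas_roi_means",
]

DEMOGRAPHICS = ("age", "gender", "education")


@dataclasses.dataclass
class SignatureModel:
    """Coefficients of the signature regression (intercept first)."""

    coefficients: np.ndarray
    terms: tuple[str, ...]
    outcome_name: str
    fitting_set: str = ""
    collinear: bool = False

    def predict(self, means: pd.DataFrame) -> pd.Series:
        X = np.column_stack([np.ones(len(means))] + [means[t].to_numpy() for t in self.terms])
        return pd.Series(X @ self.coefficients, index=means.index, name="S")


@dataclasses.dataclass
class FitResult:
    """An OLS fit summary: coefficients, R^2, and adjusted R^2."""

    label: str
    coefficients: np.ndarray
    predictor_names: tuple[str, ...]
    n: int
    p: int  # predictors excluding intercept
    r2: float
    adj_r2: float
    df_resid: int


def _ols(X: np.ndarray, y: np.ndarray, names: Sequence[str], label: str = "") -> FitResult:
    """Plain OLS with an explicit rank check naming offending columns."""
    n, k = X.shape
    if n <= k:
        raise ValueError(f"n={n} too small for {k} parameters in model {label!r}")
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        culprits = [
            names[j] for j in range(1, k) if np.ptp(X[:, j]) == 0
        ] or list(names[1:])
        raise ValueError(f"rank-deficient design in model {label!r}: columns {culprits}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = np.sum((y - y.mean()) ** 2)
    rss = float(resid @ resid)
    r2 = 0.0 if tss == 0 else 1.0 - rss / tss
    p = k - 1
    adj = r2 if p == 0 else 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return FitResult(label, coef, tuple(names), n, p, r2, adj, n - k)


def roi_mean_vector(
    volumes: Mapping[str, Volume] | Sequence[Volume],
    masks: SignatureMaskSet,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-subject mean GM density within each non-empty TsROI mask.

    Columns are named ``tsroi_t{level}``; empty masks are skipped with a
    warning (all empty is an error).
    """
    if isinstance(volumes, Mapping) and ids is None:
        ids = list(volumes)
    cols: dict[str, np.ndarray] = {}
    for t in masks.t_levels:
        m = masks.mask_at(t)
        if not m.data.any():
            warnings.warn(f"consensus mask at t={t:g} is empty; term dropped")
            continue
        G = masked_matrix(volumes, m, ids=ids)
        cols[f"tsroi_t{t:g}"] = G.mean(axis=1)
    if not cols:
        raise ValueError("all consensus masks are empty; no signature terms")
    index = pd.Index(ids, name="subject_id") if ids is not None else None
    return pd.DataFrame(cols, index=index)


def fit_signature_variable(
    cohort: CohortTable,
    tsroi_means: pd.DataFrame,
    outcome: str,
    condition_bound: float = 1e10,
    fitting_set: str = "",
) -> tuple[SignatureModel, pd.Series]:
    """Fit the signature regression and return the signature variable S.

    S is the vector of fitted values in the fitting set.  Collinear mask
    means (design condition number above ``condition_bound``) fall back to
    a pseudo-inverse solve and are flagged on the returned model.
    """
    sub = cohort.complete_cases(outcome)
    means = tsroi_means.loc[sub.subject_ids]
    terms = tuple(means.columns)
    y = sub.table[outcome].to_numpy(dtype=float)
    if len(sub) <= len(terms) + 1:
        raise ValueError(f"n={len(sub)} too small for {len(terms)} signature terms")
    X = np.column_stack([np.ones(len(sub))] + [means[t].to_numpy() for t in terms])
    collinear = np.linalg.cond(X) > condition_bound
    if collinear:
        warnings.warn(
            "signature design is ill-conditioned; using pseudo-inverse solve"
        )
        coef = np.linalg.pinv(X) @ y
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    model = SignatureModel(coef, terms, outcome, fitting_set, collinear)
    S = pd.Series(X @ coef, index=pd.Index(sub.subject_ids, name="subject_id"), name="S")
    return model, S


def fit_outcome_model(
    cohort: CohortTable,
    predictors: Mapping[str, np.ndarray | pd.Series] | Sequence[str],
    outcome: str,
    label: str = "",
    include_demographics: bool = True,
) -> FitResult:
    """OLS of the outcome on named predictors (plus demographics).

    ``predictors`` is either a list of cohort-table column names or a
    mapping of name -> per-subject values indexed like the cohort's
    subject ids.  Demographics-only is ``predictors=[]``.
    """
    sub = cohort.complete_cases(outcome)
    names: list[str] = ["intercept"]
    cols: list[np.ndarray] = [np.ones(len(sub))]
    if isinstance(predictors, Mapping):
        items = predictors.items()
    else:
        items = [(name, sub.table[name]) for name in predictors]
    for name, vals in items:
        if isinstance(vals, pd.Series) and not isinstance(vals.index, pd.RangeIndex):
            vals = vals.loc[sub.subject_ids]
        v = np.asarray(vals, dtype=float)
        if len(v) != len(sub):
            raise ValueError(f"predictor {name!r} has {len(v)} values for n={len(sub)}")
        names.append(name)
        cols.append(v)
    if include_demographics:
        for c in DEMOGRAPHICS:
            names.append(c)
            cols.append(sub.table[c].to_numpy(dtype=float))
    y = sub.table[outcome].to_numpy(dtype=float)
    return _ols(np.column_stack(cols), y, names, label or "+".join(names[1:]) or "intercept")


def atlas_roi_means(
    volumes: Mapping[str, Volume] | Sequence[Volume],
    atlas: Volume,
    labels: Sequence[int],
    label_names: Sequence[str] | None = None,
    ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean GM density per atlas-labeled region per subject."""
    if isinstance(volumes, Mapping) and ids is None:
        ids = list(volumes)
    names = list(label_names) if label_names else [f"roi_{int(l)}" for l in labels]
    cols: dict[str, np.ndarray] = {}
    for lab, name in zip(labels, names):
        region = atlas.data == lab
        if not region.any():
            raise ValueError(f"label {lab} absent from atlas")
        m = BinaryMask(region, atlas.voxel_size, atlas.space_tag)
        cols[name] = masked_matrix(volumes, m, ids=ids).mean(axis=1)
    index = pd.Index(ids, name="subject_id") if ids is not None else None
    return pd.DataFrame(cols, index=index)
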