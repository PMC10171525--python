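"""Volumes, masks, and cohort tables.

All voxelwise computation in this package runs on a single common grid
(the template grid).  A :class:`Volume` couples a 3D scalar array with its
voxel dimensions and a free-text space tag; two volumes participate in a
multi-volume operation only if they are *aligned* (same shape, voxel sizes,
and space tag).  Voxel coordinates are 0-based grid indices throughout; no
world-coordinate resampling is performed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "BinaryMask",
    "CohortTable",
    "AlignmentError",
    "read_volume",
    "write_volume",
    "read_cohort",
    "make_analysis_mask",
]

#: Covariates required for every outcome analysis (gender coded 0/1,
#: reference = male; education in years, continuous).
REQUIRED_COVARIATES = ("age", "gender", "education")


class AlignmentError(ValueError):
    """Two volumes do not share a grid (shape, voxel size, or space tag)."""


@dataclasses.dataclass
class Volume:
    """A 3D scalar grid with voxel dimensions in mm and a template tag."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    space_tag: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate grid shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def aligned_with(self, other: "Volume") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, rtol=1e-5)
            and self.space_tag == other.space_tag
        )

    def like(self, data: np.ndarray) -> "Volume":
        """New Volume on this grid with different data."""
        return Volume(data, self.voxel_size, self.space_tag)


class BinaryMask(Volume):
    """A boolean Volume: signature masks, consensus masks, analysis mask."""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.dtype != bool:
            uniq = np.unique(self.data)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask values must be in {0, 1}")
            self.data = self.data.astype(bool)
        super().__post_init__()

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def like_mask(self, data: np.ndarray) -> "BinaryMask":
        return BinaryMask(data, self.voxel_size, self.space_tag)


def check_aligned(*volumes: Volume) -> None:
    """Raise :class:`AlignmentError` unless all volumes share a grid."""
    ref = volumes[0]
    for v in volumes[1:]:
        if not ref.aligned_with(v):
            raise AlignmentError(
                f"volumes not aligned: {ref.shape}/{ref.voxel_size}/{ref.space_tag!r}"
                f" vs {v.shape}/{v.voxel_size}/{v.space_tag!r}"
            )


def read_volume(path: str | Path) -> Volume:
    """Read a 3D NIfTI-1 image.

    4D inputs with a singleton last axis are squeezed; any other
    dimensionality is rejected.  The space tag is taken from the header
    description field.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
    except Exception as exc:  # nibabel raises several unrelated types
        raise ValueError(f"cannot read NIfTI volume from {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D image in {path}, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    descrip = ""
    try:
        descrip = img.header["descrip"].tobytes().split(b"\x00")[0].decode("ascii", "ignore")
    except Exception:
        pass
    return Volume(data, tuple(float(z) for z in zooms), descrip)


def write_volume(v: Volume, path: str | Path) -> None:
    """Write a Volume (or BinaryMask, stored as uint8) as NIfTI-1."""
    path = Path(path)
    data = v.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif data.dtype in (np.int64, np.uint64):  # NIfTI-1 has no 64-bit int
        data = data.astype(np.int32)
    affine = np.diag(list(v.voxel_size) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(v.voxel_size)
    img.header["descrip"] = v.space_tag.encode("ascii", "ignore")[:79]
    try:
        nib.save(img, str(path))
    except Exception as exc:
        raise OSError(f"cannot write volume to {path}: {exc}") from exc


def read_mask(path: str | Path) -> BinaryMask:
    v = read_volume(path)
    return BinaryMask(v.data != 0, v.voxel_size, v.space_tag)


@dataclasses.dataclass
class CohortTable:
    """Per-subject demographics, outcomes, diagnosis, and volume references.

    ``table`` is indexed 0..n-1 with a unique ``subject_id`` column; the
    demographic covariates of :data:`REQUIRED_COVARIATES` are always present
    and complete.  Outcome columns may contain NaN — analyses drop incomplete
    rows per outcome (complete-case) via :meth:`complete_cases`.
    """

    table: pd.DataFrame
    outcomes: tuple[str, ...] = ()
    n_excluded: int = 0

    def __len__(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> np.ndarray:
        return self.table["subject_id"].to_numpy()

    def complete_cases(self, outcome: str) -> "CohortTable":
        """Rows with the named outcome and all covariates present."""
        if outcome not in self.table.columns:
            raise KeyError(f"outcome column {outcome!r} not in cohort table")
        cols = ["subject_id", *REQUIRED_COVARIATES, outcome]
        keep = self.table[cols].notna().all(axis=1)
        sub = self.table.loc[keep].reset_index(drop=True)
        return CohortTable(sub, self.outcomes, int((~keep).sum()))

    def subset(self, ids: Sequence) -> "CohortTable":
        """Rows for the given subject ids, in table order."""
        ids = set(ids)
        keep = self.table["subject_id"].isin(ids)
        return CohortTable(self.table.loc[keep].reset_index(drop=True), self.outcomes)


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    outcomes: Sequence[str] = ("memory",),
) -> CohortTable:
    """Read a cohort CSV (comma-delimited, header row).

    ``schema`` maps canonical names (subject_id, age, gender, education,
    diagnosis, volume_path, and each outcome) to the file's column names.
    Rows missing any required covariate are excluded and counted; outcome
    missingness is handled per analysis.
    """
    path = Path(path)
    df = pd.read_csv(path)
    schema = dict(schema or {})
    rename = {v: k for k, v in schema.items() if v in df.columns}
    df = df.rename(columns=rename)

    required = ["subject_id", *REQUIRED_COVARIATES]
    missing = [c for c in required + list(outcomes) if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table {path} lacks mapped column(s): {missing}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id in {path}: {dups[:5]}")

    df["subject_id"] = df["subject_id"].astype(str)
    for col in REQUIRED_COVARIATES + tuple(outcomes):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    complete = df[list(REQUIRED_COVARIATES)].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    df = df.loc[complete].reset_index(drop=True)
    return CohortTable(df, tuple(outcomes), n_excluded)


def make_analysis_mask(template_gm: Volume, min_density: float) -> BinaryMask:
    """Voxels of the template with GM density above ``min_density``.

    All downstream voxelwise operations iterate only over this mask.
    """
    if min_density < 0:
        raise ValueError("min_density must be >= 0")
    mask = template_gm.data > min_density
    if not mask.any():
        raise ValueError("no analysis voxels: template has no density above threshold")
    return BinaryMask(mask, template_gm.voxel_size, template_gm.space_tag)
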