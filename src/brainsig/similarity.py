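"""Spatial agreement between signature mask sets.

Two scores are provided.  Dice measures binary-mask overlap; by default the
standard convention 2|A∩B|/(|A|+|B|) is used, with the union-denominator
variant 2|A∩B|/|A∪B| available as mode "union".  Eta-squared compares two
scalar maps voxelwise,

    eta2 = 1 - sum_i[(a_i-m_i)^2 + (b_i-m_i)^2] / sum_i[(a_i-M)^2 + (b_i-M)^2],

with m_i the voxel-pair mean and M the grand mean over both maps; it is 1
for identical maps and is sensitive to both local and global magnitude
differences.  Mask *sets* are compared through a coded volume that assigns
each voxel the highest t-level whose mask contains it (0/3/5/7), so the
score reflects correspondence of t-value locations.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .clusters import SignatureMaskSet
from .volumes import BinaryMask, Volume, check_aligned

__all__ = [
    "dice",
    "eta2",
    "coded_volume",
    "mask_set_dice",
    "mask_set_eta2",
    "atlas_overlap_table",
]


def dice(m1: BinaryMask, m2: BinaryMask, mode: str = "standard") -> float:
    """Dice overlap of two aligned binary masks (error if both empty)."""
    check_aligned(m1, m2)
    a, b = m1.data, m2.data
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        raise ValueError("Dice undefined: both masks are empty")
    inter = int((a & b).sum())
    if mode == "standard":
        return 2.0 * inter / (na + nb)
    if mode == "union":
        return 2.0 * inter / int((a | b).sum())
    raise ValueError(f"unknown Dice mode {mode!r}")


def eta2(v1: Volume, v2: Volume, mask: BinaryMask | None = None) -> float:
    """Voxelwise eta-squared agreement of two aligned scalar maps."""
    if mask is not None:
        check_aligned(v1, v2, mask)
        a = v1.data[mask.data].astype(float)
        b = v2.data[mask.data].astype(float)
        if a.size == 0:
            raise ValueError("eta2 undefined: empty mask")
    else:
        check_aligned(v1, v2)
        a, b = v1.data.ravel().astype(float), v2.data.ravel().astype(float)
    m = (a + b) / 2.0
    grand = m.mean()
    denom = np.sum((a - grand) ** 2 + (b - grand) ** 2)
    if denom == 0:
        raise ValueError("eta2 undefined: zero total variance across both images")
    num = np.sum((a - m) ** 2 + (b - m) ** 2)
    return float(1.0 - num / denom)


def coded_volume(masks: SignatureMaskSet) -> Volume:
    """Volume coding each voxel by the highest t-level containing it (else 0)."""
    levels = masks.t_levels
    ref = masks.mask_at(levels[0])
    code = np.zeros(ref.shape)
    for t in levels:  # ascending: higher levels overwrite
        code[masks.mask_at(t).data] = t
    return Volume(code, ref.voxel_size, ref.space_tag)


def mask_set_dice(a: SignatureMaskSet, b: SignatureMaskSet, mode: str = "standard") -> float:
    """Dice of the outermost (lowest-t, t >= 3 style) masks of two sets."""
    return dice(a.mask_at(a.t_levels[0]), b.mask_at(b.t_levels[0]), mode)


def mask_set_eta2(a: SignatureMaskSet, b: SignatureMaskSet, mask: BinaryMask | None = None) -> float:
    """Eta-squared of the t-level-coded volumes of two mask sets."""
    return eta2(coded_volume(a), coded_volume(b), mask)


def atlas_overlap_table(
    mask: BinaryMask,
    atlas: Volume,
    labels: Sequence[int],
    label_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Fraction of each atlas region covered by the mask, sorted descending.

    Empty regions get NaN and a ``defined`` flag of False.
    """
    check_aligned(mask, atlas)
    names = list(label_names) if label_names else [f"roi_{int(l)}" for l in labels]
    rows = []
    for lab, name in zip(labels, names):
        region = atlas.data == lab
        size = int(region.sum())
        if size == 0:
            rows.append({"region": name, "label": lab, "overlap": np.nan, "defined": False})
        else:
            covered = int((region & mask.data).sum())
            rows.append(
                {"region": name, "label": lab, "overlap": covered / size, "defined": True}
            )
    df = pd.DataFrame(rows).sort_values("overlap", ascending=False, na_position="last")
    return df.reset_index(drop=True)
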