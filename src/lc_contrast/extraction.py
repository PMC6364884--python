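"""Median signal extraction from ROIs.

The contrast statistics are built from the median intensity within each ROI
(nucleus, plus1, plus2, pontine tegmentum), extracted per hemisphere.  The
median is deliberately preferred to the mean: it is robust to the handful of
partial-volume or noise-corrupted voxels a small brainstem ROI inevitably
contains.

Also provides the within-mask variability ratio, median / IQR of the voxel
intensities inside a mask, a unitless figure of how sharply a nucleus stands
out against its own internal spread.  Quartiles use linear interpolation
between order statistics throughout the package.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .images import BinaryMask, GridMismatchError, VolumeImage
from .rois import RoiSet, split_hemispheres

__all__ = ["extract_median", "within_mask_variability", "extract_roi_medians",
           "MEDIANS_COLUMNS"]

MEDIANS_COLUMNS = ["subject", "sequence", "hemisphere", "roi", "n_voxels", "median"]


def extract_median(volume: VolumeImage, mask: BinaryMask) -> float:
    """Median intensity over the mask voxels.

    Even voxel counts use the midpoint of the two central order statistics.
    Raises on an empty mask or non-finite intensities inside the mask.
    """
    if not volume.same_grid(mask):
        raise GridMismatchError("volume and mask are not on the same grid")
    values = volume.data[mask.data]
    if values.size == 0:
        raise ValueError("cannot take the median of an empty mask")
    n_bad = int(np.count_nonzero(~np.isfinite(values)))
    if n_bad:
        raise ValueError(f"{n_bad} non-finite voxel value(s) inside the mask")
    return float(np.median(values))


def within_mask_variability(volume: VolumeImage, mask: BinaryMask) -> float:
    """Median / within-mask IQR of the intensities inside a mask.

    Returns NaN (with no exception) when the IQR is zero — a flat ROI has no
    defined variability ratio and must not silently become infinite.
    Requires at least 4 voxels so the quartiles are meaningful.
    """
    if not volume.same_grid(mask):
        raise GridMismatchError("volume and mask are not on the same grid")
    values = volume.data[mask.data]
    if values.size < 4:
        raise ValueError(f"need >= 4 voxels for a variability ratio, got {values.size}")
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    if iqr == 0:
        return math.nan
    return float(med / iqr)


def extract_roi_medians(volumes: dict[str, VolumeImage], rois: RoiSet,
                        subject_id: str) -> pd.DataFrame:
    """Per-sequence, per-hemisphere ROI medians for one subject.

    The nucleus and ring ROIs are split at the midline and extracted per
    hemisphere.  The pontine-tegmentum box is a single central reference
    spanning the midline; its median is computed over the whole box and
    recorded identically for both hemispheres.

    Returns a long-format table with columns ``subject, sequence, hemisphere,
    roi, n_voxels, median``.
    """
    split: dict[str, dict[str, BinaryMask]] = {}
    for name, mask in (("lc", rois.lc), ("plus1", rois.plus1), ("plus2", rois.plus2)):
        left, right = split_hemispheres(mask, rois.midline_index)
        split[name] = {"left": left, "right": right}
    rows = []
    for seq_name, vol in volumes.items():
        for roi_name, sides in split.items():
            for hemi, m in sides.items():
                rows.append({
                    "subject": subject_id, "sequence": seq_name,
                    "hemisphere": hemi, "roi": roi_name,
                    "n_voxels": m.n_voxels,
                    "median": extract_median(vol, m),
                })
        pt_median = extract_median(vol, rois.pt)
        for hemi in ("left", "right"):
            rows.append({
                "subject": subject_id, "sequence": seq_name,
                "hemisphere": hemi, "roi": "pt",
                "n_voxels": rois.pt.n_voxels, "median": pt_median,
            })
    return pd.DataFrame(rows, columns=MEDIANS_COLUMNS)
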