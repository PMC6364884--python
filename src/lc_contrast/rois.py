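"""Analysis ROI construction on voxel grids.

Builds the regions the contrast statistics are computed over:

* a conjunction nucleus mask — voxels identified by at least ``min_votes`` of
  the rater segmentations (the study convention is 3 of 4);
* ``plus1`` and ``plus2`` ring control regions obtained by in-plane 2D box
  dilation of the nucleus mask (3x3 and 5x5 Chebyshev neighbourhoods), with
  the ventricle excluded so no control voxel lies in CSF;
* a square pontine-tegmentum reference box placed at an explicit landmark on
  every axial slice that contains nucleus voxels;
* a hemisphere split along a midline column.

Rings never cross axial slices: the box kernel is two-dimensional, matching
the slab-wise geometry of the underlying acquisitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import BinaryMask, GridMismatchError

__all__ = ["RoiSet", "build_conjunction_mask", "expand_ring", "place_pt_roi",
           "split_hemispheres", "build_roi_set", "EmptyMaskError"]

log = logging.getLogger(__name__)


class EmptyMaskError(ValueError):
    """Raised when an operation requires a non-empty mask."""


_BOX3 = np.ones((3, 3, 1), dtype=bool)
_BOX5 = np.ones((5, 5, 1), dtype=bool)


@dataclass(frozen=True)
class RoiSet:
    """The full set of analysis ROIs on one subject's grid.

    Invariants (checked at construction): the nucleus mask, the two rings and
    the pt box are pairwise disjoint, and none of them intersects the
    ventricle.
    """

    lc: BinaryMask
    plus1: BinaryMask
    plus2: BinaryMask
    pt: BinaryMask
    ventricle: BinaryMask
    midline_index: int

    def __post_init__(self) -> None:
        lc, p1, p2 = self.lc.data, self.plus1.data, self.plus2.data
        if (lc & p1).any() or ((lc | p1) & p2).any():
            raise ValueError("nucleus and ring masks overlap")
        vent = self.ventricle.data
        for name, m in (("lc", lc), ("plus1", p1), ("plus2", p2)):
            if (m & vent).any():
                raise ValueError(f"{name} mask intersects the ventricle")
        if (self.pt.data & (lc | p1 | p2)).any():
            raise ValueError("pt ROI overlaps the nucleus or its rings")

    def as_dict(self) -> dict[str, BinaryMask]:
        return {"lc": self.lc, "plus1": self.plus1, "plus2": self.plus2,
                "pt": self.pt}


def build_conjunction_mask(rater_masks: list[BinaryMask],
                           min_votes: int) -> BinaryMask:
    """Voxelwise vote threshold across repeated segmentations.

    A voxel is retained iff it is marked in at least ``min_votes`` of the
    input masks.
    """
    if not rater_masks:
        raise ValueError("need at least one rater mask")
    if not (1 <= min_votes <= len(rater_masks)):
        raise ValueError(
            f"min_votes must lie in [1, {len(rater_masks)}], got {min_votes}")
    first = rater_masks[0]
    for m in rater_masks[1:]:
        if not first.same_grid(m):
            raise GridMismatchError("rater masks are not on a common grid")
    votes = np.sum([m.data for m in rater_masks], axis=0)
    out = votes >= min_votes
    if not out.any():
        log.warning("conjunction mask is empty at min_votes=%d", min_votes)
    return BinaryMask(out, first.voxel_size_mm, role="LC")


def expand_ring(lc: BinaryMask, ring: int,
                exclusion: BinaryMask | None = None) -> BinaryMask:
    """Ring control region at in-plane Chebyshev distance ``ring`` (1 or 2).

    ``ring=1``: per-slice 3x3 box dilation of the nucleus mask minus the mask
    itself; ``ring=2``: 5x5 dilation minus the 3x3 dilation.  Voxels of the
    ``exclusion`` mask (the ventricle) are removed from the result.  No
    expansion across slices.
    """
    if not lc.data.any():
        raise EmptyMaskError("empty LC mask")
    if ring not in (1, 2):
        raise ValueError(f"ring must be 1 or 2, got {ring}")
    if exclusion is not None and not lc.same_grid(exclusion):
        raise GridMismatchError("exclusion mask grid differs from LC grid")
    dil3 = ndimage.binary_dilation(lc.data, structure=_BOX3)
    if ring == 1:
        out = dil3 & ~lc.data
    else:
        dil5 = ndimage.binary_dilation(lc.data, structure=_BOX5)
        out = dil5 & ~dil3
    if exclusion is not None:
        out &= ~exclusion.data
    return BinaryMask(out, lc.voxel_size_mm, role=f"plus{ring}")


def place_pt_roi(center: tuple[int, int], size_mm: float, lc: BinaryMask,
                 voxel_size_mm: tuple[float, float, float],
                 forbid: BinaryMask | None = None) -> BinaryMask:
    """Square reference box at an explicit in-plane landmark.

    A square of edge ``round(size_mm / in-plane voxel size)`` voxels centred
    at ``center`` is placed on every axial slice that contains at least one
    nucleus voxel; other slices stay empty.  Overlap with ``forbid`` (the
    nucleus plus its rings) is an error, as is a box exceeding the grid.
    """
    if not lc.data.any():
        raise EmptyMaskError("empty LC mask")
    nx, ny, nz = lc.shape
    cx, cy = center
    if not (0 <= cx < nx and 0 <= cy < ny):
        raise ValueError(f"pt centre {center} outside grid {lc.shape[:2]}")
    edge = int(round(size_mm / voxel_size_mm[0]))
    x0, y0 = cx - edge // 2, cy - edge // 2
    if x0 < 0 or y0 < 0 or x0 + edge > nx or y0 + edge > ny:
        raise ValueError("pt square exceeds grid bounds")
    lc_slices = np.where(lc.data.any(axis=(0, 1)))[0]
    out = np.zeros(lc.shape, dtype=bool)
    for z in lc_slices:
        out[x0:x0 + edge, y0:y0 + edge, z] = True
    if forbid is not None and (out & forbid.data).any():
        raise ValueError("pt ROI overlaps the nucleus or its ring regions")
    return BinaryMask(out, voxel_size_mm, role="pt")


def split_hemispheres(mask: BinaryMask,
                      midline_index: int) -> tuple[BinaryMask, BinaryMask]:
    """Partition a mask into left/right hemispheres at a midline column.

    Voxels exactly on the midline column belong to neither hemisphere; their
    count is logged.  Raises if either hemisphere ends up empty.
    """
    nx = mask.shape[0]
    if not (0 <= midline_index < nx):
        raise ValueError(f"midline index {midline_index} outside grid")
    left = np.zeros_like(mask.data)
    right = np.zeros_like(mask.data)
    left[:midline_index] = mask.data[:midline_index]
    right[midline_index + 1:] = mask.data[midline_index + 1:]
    n_mid = int(mask.data[midline_index].sum())
    if n_mid:
        log.info("dropped %d voxels on the midline column", n_mid)
    for name, h in (("left", left), ("right", right)):
        if not h.any():
            raise EmptyMaskError(f"{name} hemisphere is empty")
    return (BinaryMask(left, mask.voxel_size_mm, role=f"{mask.role}_left"),
            BinaryMask(right, mask.voxel_size_mm, role=f"{mask.role}_right"))


def build_roi_set(rater_masks: list[BinaryMask], ventricle: BinaryMask,
                  pt_center: tuple[int, int], midline_index: int,
                  min_votes: int = 3, pt_size_mm: float = 4.0) -> RoiSet:
    """Construct the full ROI set from rater masks and a ventricle mask."""
    lc = build_conjunction_mask(rater_masks, min_votes)
    if not lc.same_grid(ventricle):
        raise GridMismatchError("ventricle mask grid differs from rater grid")
    lc = BinaryMask(lc.data & ~ventricle.data, lc.voxel_size_mm, role="LC")
    if not lc.data.any():
        raise EmptyMaskError("conjunction mask empty after ventricle exclusion")
    plus1 = expand_ring(lc, 1, exclusion=ventricle)
    plus2 = expand_ring(lc, 2, exclusion=ventricle)
    forbid = BinaryMask(lc.data | plus1.data | plus2.data, lc.voxel_size_mm)
    pt = place_pt_roi(pt_center, pt_size_mm, lc, lc.voxel_size_mm, forbid=forbid)
    return RoiSet(lc=lc, plus1=plus1, plus2=plus2, pt=pt,
                  ventricle=ventricle, midline_index=midline_index)
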