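"""Relative-contrast statistics for nucleus-versus-reference comparisons.

Three contrast definitions are computed per subject, sequence and hemisphere,
each a percent signal difference of the nucleus median against a reference
median::

    contrast1  = (LC - plus1) / plus1 * 100     (directly adjacent ring)
    contrast2  = (LC - plus2) / plus2 * 100     (ring two voxels away)
    contrast_pt = (LC - PT) / PT * 100          (pontine tegmentum box)

Hemisphere values are averaged per subject; left/right consistency is
summarised by a Pearson correlation across subjects; outliers are flagged by
Tukey fences at three times the interquartile range, independently per
sequence and contrast definition.  Contrasts of hypointense sequences can be
sign-inverted once (guarded against double inversion) so all screened
sequences are compared on a common positive scale.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["contrast_ratio", "compute_contrasts", "average_hemispheres",
           "lr_correlation", "invert_sign", "reject_outliers", "flag_outliers",
           "summarize", "CONTRAST_NAMES"]

log = logging.getLogger(__name__)

CONTRAST_NAMES = ("contrast1", "contrast2", "contrast_pt")
_REFERENCE_ROI = {"contrast1": "plus1", "contrast2": "plus2", "contrast_pt": "pt"}


def contrast_ratio(lc_median: float, ref_median: float) -> float:
    """Percent relative contrast ``(lc - ref) / ref * 100``."""
    if ref_median == 0:
        raise ValueError("degenerate reference: reference median is zero")
    return (lc_median - ref_median) / ref_median * 100.0


def compute_contrasts(medians: pd.DataFrame) -> pd.DataFrame:
    """Per-hemisphere contrast values from a long ROI-medians table.

    Expects the columns emitted by
    :func:`lc_contrast.extraction.extract_roi_medians`; returns a long table
    ``subject, sequence, contrast, hemisphere, value``.
    """
    wide = medians.pivot_table(index=["subject", "sequence", "hemisphere"],
                               columns="roi", values="median")
    rows = []
    for (subject, sequence, hemi), r in wide.iterrows():
        for cname, ref in _REFERENCE_ROI.items():
            rows.append({
                "subject": subject, "sequence": sequence, "contrast": cname,
                "hemisphere": hemi,
                "value": contrast_ratio(r["lc"], r[ref]),
            })
    return pd.DataFrame(rows)


def average_hemispheres(hemi_values: pd.DataFrame) -> pd.DataFrame:
    """Average the hemisphere contrasts per subject, sequence and definition.

    The averaged value is the arithmetic mean of the hemisphere values that
    are present; records built from a single hemisphere are flagged through
    ``n_hemispheres``.  Rows with both hemispheres missing keep a missing
    average.
    """
    piv = hemi_values.pivot_table(index=["subject", "sequence", "contrast"],
                                  columns="hemisphere", values="value",
                                  dropna=False)
    for hemi in ("left", "right"):
        if hemi not in piv.columns:
            piv[hemi] = np.nan
    out = piv.reset_index().rename_axis(columns=None)
    both = out[["left", "right"]]
    out["n_hemispheres"] = both.notna().sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        out["avg"] = np.nanmean(both.to_numpy(), axis=1)
    out["sign_inverted"] = False
    n_single = int((out["n_hemispheres"] == 1).sum())
    if n_single:
        log.info("%d record(s) built from a single hemisphere", n_single)
    return out[["subject", "sequence", "contrast", "left", "right", "avg",
                "n_hemispheres", "sign_inverted"]]


def lr_correlation(left: np.ndarray, right: np.ndarray) -> float:
    """Pearson correlation between paired left/right contrast values.

    Returns NaN (never a fabricated value) when fewer than 3 complete pairs
    remain or either side is constant.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right must be paired vectors of equal length")
    ok = np.isfinite(left) & np.isfinite(right)
    left, right = left[ok], right[ok]
    if left.size < 3 or np.ptp(left) == 0 or np.ptp(right) == 0:
        return math.nan
    return float(stats.pearsonr(left, right).statistic)


def invert_sign(records: pd.DataFrame, sequence_names: list[str]) -> pd.DataFrame:
    """Multiply all contrasts of the named sequences by -1, once.

    Used to put hypointense-nucleus sequences on the same footing as the
    hyperintense ones before cross-sequence comparison.  Inverting a sequence
    twice, or naming an absent sequence, raises.
    """
    out = records.copy()
    present = set(out["sequence"])
    for name in sequence_names:
        if name not in present:
            raise KeyError(f"sequence {name!r} not present in records")
        sel = out["sequence"] == name
        if out.loc[sel, "sign_inverted"].any():
            raise ValueError(f"sequence {name!r} is already sign-inverted")
        for col in ("left", "right", "avg"):
            out.loc[sel, col] = -out.loc[sel, col]
        out.loc[sel, "sign_inverted"] = True
    return out


def reject_outliers(values: np.ndarray, k: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
    """Tukey-fence outlier flags at ``k`` times the IQR beyond the quartiles.

    Values outside ``[Q1 - k*IQR, Q3 + k*IQR]`` are flagged; quartiles use
    linear interpolation.  A zero IQR disables rejection (logged).  Missing
    values are neither flagged nor used for the fences.

    Returns ``(kept_values, flags)`` where ``flags`` aligns with the input.
    """
    values = np.asarray(values, dtype=float)
    finite = values[np.isfinite(values)]
    if finite.size < 4:
        raise ValueError(f"need >= 4 values for outlier fences, got {finite.size}")
    q1, q3 = np.percentile(finite, [25, 75])
    iqr = q3 - q1
    flags = np.zeros(values.shape, dtype=bool)
    if iqr == 0:
        log.warning("IQR is zero; outlier rejection skipped")
    else:
        with np.errstate(invalid="ignore"):
            flags = (values < q1 - k * iqr) | (values > q3 + k * iqr)
        flags &= np.isfinite(values)
    kept = values[np.isfinite(values) & ~flags]
    return kept, flags


def flag_outliers(records: pd.DataFrame, k: float = 3.0,
                  on: str = "avg") -> pd.DataFrame:
    """Apply outlier rejection independently per sequence x contrast.

    By default the fences are computed on the hemisphere-averaged values;
    ``on`` may name a hemisphere column instead to reject per hemisphere.
    Adds a boolean ``outlier`` column.
    """
    out = records.copy()
    out["outlier"] = False
    for (seq, cname), grp in out.groupby(["sequence", "contrast"], sort=False):
        _, flags = reject_outliers(grp[on].to_numpy(), k=k)
        out.loc[grp.index, "outlier"] = flags
    return out


def summarize(records: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary per sequence and contrast definition.

    For each sequence x contrast: the number of subjects surviving outlier
    rejection, the mean of their (hemisphere-averaged, median-based) contrast
    values, the across-subject IQR, and the left/right Pearson correlation.
    Outlier-flagged records are excluded from every statistic.
    """
    if "outlier" not in records.columns:
        records = records.assign(outlier=False)
    rows = []
    for (seq, cname), grp in records.groupby(["sequence", "contrast"], sort=False):
        keep = grp[~grp["outlier"] & grp["avg"].notna()]
        vals = keep["avg"].to_numpy()
        if vals.size == 0:
            raise ValueError(f"no surviving records for {seq}/{cname}")
        q1, q3 = np.percentile(vals, [25, 75]) if vals.size > 1 else (vals[0], vals[0])
        rows.append({
            "sequence": seq, "contrast": cname, "n": int(vals.size),
            "avg_median": float(np.mean(vals)),
            "iqr": float(q3 - q1),
            "cor_lr": lr_correlation(keep["left"].to_numpy(),
                                     keep["right"].to_numpy()),
        })
    return pd.DataFrame(rows)
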