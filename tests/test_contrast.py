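"""Contrast statistics: ratios, averaging, outliers, inversion, summaries."""

import math

import numpy as np
import pandas as pd
import pytest

from lc_contrast.contrast import (average_hemispheres, compute_contrasts,
                                  contrast_ratio, flag_outliers, invert_sign,
                                  lr_correlation, reject_outliers, summarize)
from lc_contrast.extraction import extract_roi_medians
from lc_contrast.phantom import (LcGeometry, PhantomSpec, SequenceSpec,
                                 generate_cohort, generate_phantom)
from lc_contrast.rois import build_roi_set

from _oracles import pearson_oracle


def _records(values_by_seq, contrast="contrast1"):
    rows = []
    for seq, vals in values_by_seq.items():
        for i, v in enumerate(vals):
            rows.append({"subject": f"s{i:02d}", "sequence": seq,
                         "contrast": contrast, "left": v, "right": v,
                         "avg": v, "n_hemispheres": 2, "sign_inverted": False})
    return pd.DataFrame(rows)


class TestContrastRatio:
    @pytest.mark.parametrize("lc,ref,expected", [
        (100.0, 100.0, 0.0),
        (110.0, 100.0, 10.0),
        (99.8, 100.0, pytest.approx(-0.2)),  # hypointense nuclei are legal
    ])
    def test_forced_arithmetic(self, lc, ref, expected):
        assert contrast_ratio(lc, ref) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="degenerate reference"):
            contrast_ratio(5.0, 0.0)


class TestAverageHemispheres:
    def _hemi(self, left, right):
        rows = []
        for hemi, val in (("left", left), ("right", right)):
            if val is not None:
                rows.append({"subject": "s", "sequence": "q",
                             "contrast": "contrast1", "hemisphere": hemi,
                             "value": val})
        return pd.DataFrame(rows)

    def test_mean_of_both(self):
        out = average_hemispheres(self._hemi(4.0, 6.0))
        assert out.loc[0, "avg"] == 5.0
        assert out.loc[0, "n_hemispheres"] == 2

    def test_single_hemisphere_flagged(self):
        out = average_hemispheres(self._hemi(4.0, None))
        assert out.loc[0, "avg"] == 4.0
        assert out.loc[0, "n_hemispheres"] == 1

    def test_equal_bilateral_phantom_average_is_truth(self, noiseless_cohort):
        spec = noiseless_cohort.spec
        sub = noiseless_cohort.subjects[0]
        rois = build_roi_set(sub.rater_masks, sub.ventricle_mask, sub.pt_center,
                             spec.midline_index)
        med = extract_roi_medians(sub.volumes, rois, sub.subject_id)
        rec = average_hemispheres(compute_contrasts(med))
        assert (rec["avg"] == 10.0).all()
        assert (rec["left"] == rec["right"]).all()


class TestLrCorrelation:
    def test_identical_sides(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert lr_correlation(x, x) == pytest.approx(1.0)

    def test_opposite_sides(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert lr_correlation(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula_oracle(self, rng):
        x = rng.normal(size=20)
        y = 0.4 * x + rng.normal(size=20)
        assert lr_correlation(x, y) == pytest.approx(pearson_oracle(x, y),
                                                     abs=1e-12)

    def test_degenerate_cases_are_missing_not_fabricated(self):
        assert math.isnan(lr_correlation([1.0, 2.0], [1.0, 2.0]))  # n < 3
        assert math.isnan(lr_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))

    def test_pairs_with_missing_values_dropped(self):
        x = np.array([1.0, 2.0, 3.0, np.nan, 5.0])
        y = np.array([1.1, 2.2, 2.9, 4.0, np.nan])
        assert lr_correlation(x, y) == pytest.approx(
            pearson_oracle(x[:3], y[:3]))


class TestInvertSign:
    def test_inversion_flips_all_columns(self):
        rec = _records({"mag": [-0.36, -0.5, -0.2, -0.4]})
        out = invert_sign(rec, ["mag"])
        assert (out["avg"] == [0.36, 0.5, 0.2, 0.4]).all()
        assert out["sign_inverted"].all()

    def test_double_inversion_guarded(self):
        rec = invert_sign(_records({"mag": [-1.0, -2.0, -1.5, -1.2]}), ["mag"])
        with pytest.raises(ValueError, match="already"):
            invert_sign(rec, ["mag"])

    def test_absent_sequence_rejected(self):
        with pytest.raises(KeyError):
            invert_sign(_records({"a": [1.0, 2.0, 1.0, 2.0]}), ["missing"])


class TestRejectOutliers:
    def test_flags_value_far_outside_fences(self, rng):
        vals = np.concatenate([rng.uniform(4, 6, 11), [60.0]])
        q1, q3 = np.percentile(vals, [25, 75])
        assert 60.0 > q3 + 3 * (q3 - q1)  # fence oracle agrees
        kept, flags = reject_outliers(vals, k=3)
        assert flags.sum() == 1 and flags[-1]
        assert 60.0 not in kept

    def test_identical_values_none_flagged(self):
        _, flags = reject_outliers(np.full(6, 5.0))
        assert not flags.any()

    def test_idempotent_on_converged_sample(self, rng):
        vals = np.concatenate([rng.normal(5, 0.5, 11), [60.0]])
        kept, flags = reject_outliers(vals, k=3)
        kept2, flags2 = reject_outliers(kept, k=3)
        assert not flags2.any()

    def test_missing_values_ignored(self):
        vals = np.array([5.0, 5.1, 4.9, 5.2, np.nan, 60.0])
        kept, flags = reject_outliers(vals, k=3)
        assert not flags[4] and flags[5]
        assert len(kept) == 4

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            reject_outliers(np.array([1.0, 2.0, 3.0]))

    def test_applied_per_sequence_and_contrast(self, rng):
        rec = pd.concat([
            _records({"a": list(rng.uniform(4, 6, 11)) + [60.0]}, "contrast1"),
            _records({"a": list(rng.uniform(4, 6, 12))}, "contrast2"),
        ], ignore_index=True)
        out = flag_outliers(rec, k=3)
        by = out.groupby("contrast")["outlier"].sum()
        assert by["contrast1"] == 1 and by["contrast2"] == 0


class TestSummarize:
    def test_single_subject_degenerates_gracefully(self):
        rec = _records({"a": [5.0]})
        rec["outlier"] = False
        row = summarize(rec).iloc[0]
        assert row["n"] == 1 and row["iqr"] == 0.0
        assert math.isnan(row["cor_lr"])

    def test_noiseless_constant_cohort(self, noiseless_cohort):
        spec = noiseless_cohort.spec
        frames = []
        for sub in noiseless_cohort.subjects:
            rois = build_roi_set(sub.rater_masks, sub.ventricle_mask,
                                 sub.pt_center, spec.midline_index)
            frames.append(extract_roi_medians(sub.volumes, rois, sub.subject_id))
        rec = average_hemispheres(compute_contrasts(pd.concat(frames)))
        rec["outlier"] = False
        summary = summarize(rec)
        assert (summary["avg_median"] == 10.0).all()
        assert (summary["iqr"] == 0.0).all()

    def test_outliers_excluded_from_all_statistics(self, rng):
        vals = list(rng.uniform(4, 6, 11)) + [60.0]
        rec = flag_outliers(_records({"a": vals}), k=3)
        row = summarize(rec).iloc[0]
        assert row["n"] == 11
        assert row["avg_median"] == pytest.approx(np.mean(vals[:11]))

    def test_matches_independent_summary_oracle(self, noisy_cohort):
        spec = noisy_cohort.spec
        frames = []
        for sub in noisy_cohort.subjects:
            rois = build_roi_set(sub.rater_masks, sub.ventricle_mask,
                                 sub.pt_center, spec.midline_index)
            frames.append(extract_roi_medians(sub.volumes, rois, sub.subject_id))
        rec = flag_outliers(average_hemispheres(
            compute_contrasts(pd.concat(frames))))
        summary = summarize(rec).set_index(["sequence", "contrast"])
        for (seq, cname), grp in rec.groupby(["sequence", "contrast"]):
            keep = grp[~grp["outlier"]]
            vals = keep["avg"].to_numpy()
            row = summary.loc[(seq, cname)]
            assert row["avg_median"] == pytest.approx(vals.mean())
            q1, q3 = np.percentile(vals, [25, 75])
            assert row["iqr"] == pytest.approx(q3 - q1)
            assert row["cor_lr"] == pytest.approx(
                pearson_oracle(keep["left"], keep["right"]), abs=1e-12)


def test_scale_invariance_offset_sensitivity():
    """Multiplying a volume by k leaves contrasts unchanged; adding a constant
    shifts them — the reason ratios need no intensity normalisation."""
    spec = PhantomSpec(sequence_specs=(SequenceSpec("s", 10.0),),
                       n_subjects=1, rater_jitter=0.0, seed=2)
    sub = generate_phantom(spec, 0)
    rois = build_roi_set(sub.rater_masks, sub.ventricle_mask, sub.pt_center,
                         spec.midline_index)
    base = average_hemispheres(compute_contrasts(
        extract_roi_medians(sub.volumes, rois, "s")))["avg"]

    from lc_contrast.images import VolumeImage
    scaled = {k: VolumeImage(v.data * 3.0, v.voxel_size_mm)
              for k, v in sub.volumes.items()}
    shifted = {k: VolumeImage(v.data + 500.0, v.voxel_size_mm)
               for k, v in sub.volumes.items()}
    got_scaled = average_hemispheres(compute_contrasts(
        extract_roi_medians(scaled, rois, "s")))["avg"]
    got_shifted = average_hemispheres(compute_contrasts(
        extract_roi_medians(shifted, rois, "s")))["avg"]
    np.testing.assert_allclose(got_scaled, base, rtol=1e-12)
    assert (np.abs(got_shifted - base) > 1.0).all()


def test_partial_volume_contamination_orders_the_contrasts():
    """With boundary partial volume on, the adjacent ring is contaminated by
    the nucleus, so the two-voxel ring yields at least as much contrast."""
    spec = PhantomSpec(sequence_specs=(SequenceSpec("s", 10.0),),
                       n_subjects=1, rater_jitter=0.0, partial_volume=True,
                       lc_geometry=LcGeometry(radius_mm=1.4), seed=4)
    sub = generate_phantom(spec, 0)
    rois = build_roi_set(sub.rater_masks, sub.ventricle_mask, sub.pt_center,
                         spec.midline_index)
    rec = average_hemispheres(compute_contrasts(
        extract_roi_medians(sub.volumes, rois, "s"))).set_index("contrast")
    assert rec.loc["contrast2", "avg"] >= rec.loc["contrast1", "avg"]
    assert rec.loc["contrast2", "avg"] > rec.loc["contrast1", "avg"] + 0.5


def test_recovery_bias_shrinks_with_noise():
    """Mean absolute recovery error decreases monotonically over a sigma grid."""
    errors = []
    for sigma in (0.08, 0.02, 0.0):
        spec = PhantomSpec(
            sequence_specs=(SequenceSpec("s", 5.0, noise_sigma=sigma),),
            n_subjects=6, rater_jitter=0.0, seed=31)
        frames = []
        for sub in generate_cohort(spec).subjects:
            rois = build_roi_set(sub.rater_masks, sub.ventricle_mask,
                                 sub.pt_center, spec.midline_index)
            frames.append(extract_roi_medians(sub.volumes, rois, sub.subject_id))
        rec = average_hemispheres(compute_contrasts(pd.concat(frames)))
        c1 = rec[rec["contrast"] == "contrast1"]["avg"]
        errors.append(abs(c1.mean() - 5.0))
    assert errors[0] > errors[2]
    assert errors[1] >= errors[2]
    assert errors[2] == 0.0
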