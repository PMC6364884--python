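"""End-to-end orchestration: cohort -> ROIs -> medians -> contrasts -> evidence.

The pipeline runs either on a synthetic phantom cohort (generated in memory
from a :class:`~lc_contrast.phantom.PhantomSpec`) or on a directory of
co-registered NIfTI volumes and rater masks laid out as written by
:func:`lc_contrast.phantom.write_cohort`.  All tabular outputs are TSV with a
provenance header block (config hash, seed, package version); identical
config + seed yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bayes import (BayesConfig, jzs_one_sample_bf, jzs_paired_bf,
                    mixed_model_bf, screen_sequences)
from .contrast import (CONTRAST_NAMES, average_hemispheres, compute_contrasts,
                       flag_outliers, invert_sign, summarize)
from .extraction import extract_roi_medians
from .images import load_mask, load_volume
from .phantom import PhantomSpec, SyntheticSubject, generate_cohort
from .rois import build_roi_set

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage and offending subject/sequence."""


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one input mode is active: ``synthetic`` (a PhantomSpec) or
    ``nifti-dir`` (a cohort directory with a ``manifest.tsv``).
    """

    mode: str = "synthetic"
    phantom: PhantomSpec | None = None
    input_dir: str | None = None
    pt_center: tuple[int, int] | None = None     # nifti-dir mode
    midline_index: int | None = None             # nifti-dir mode
    min_votes: int = 3
    pt_size_mm: float = 4.0
    outlier_k: float = 3.0
    outlier_on: str = "avg"
    invert_sequences: list[str] | None = None    # None: auto (negative mean)
    bayes: BayesConfig = field(default_factory=BayesConfig)
    out_dir: str = "lc_contrast_run"
    seed: int = 0
    log_level: str = "INFO"
    write_nifti: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "nifti-dir"):
            raise ValueError("mode must be 'synthetic' or 'nifti-dir'")
        if self.mode == "synthetic" and self.phantom is None:
            raise ValueError("synthetic mode requires a phantom spec")
        if self.mode == "nifti-dir":
            if self.input_dir is None:
                raise ValueError("nifti-dir mode requires input_dir")
            if self.pt_center is None or self.midline_index is None:
                raise ValueError("nifti-dir mode requires pt_center and midline_index")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if d.get("phantom") is not None:
            d["phantom"] = PhantomSpec.from_yaml(yaml.safe_dump(d["phantom"]))
        if d.get("bayes") is not None:
            b = dict(d["bayes"])
            if "evidence_bounds" in b:
                b["evidence_bounds"] = tuple(b["evidence_bounds"])
            d["bayes"] = BayesConfig(**b)
        if d.get("pt_center") is not None:
            d["pt_center"] = tuple(d["pt_center"])
        return cls(**d)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration.

        Output location and logging verbosity are excluded: runs that differ
        only in where they write are the same analysis.
        """
        d = self.to_dict()
        for key in ("out_dir", "log_level", "write_nifti"):
            d.pop(key, None)
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _load_nifti_cohort(config: RunConfig) -> list[SyntheticSubject]:
    """Ingest a cohort directory laid out like ``phantom.write_cohort``."""
    root = Path(config.input_dir)
    manifest = root / "manifest.tsv"
    if not manifest.exists():
        raise PipelineError(f"ingest: manifest not found: {manifest}")
    table = pd.read_csv(manifest, sep="\t")
    subjects = []
    for sub_id, grp in table.groupby("subject", sort=True):
        sdir = root / str(sub_id)
        volumes = {}
        truths = {}
        for _, row in grp.iterrows():
            p = root / row["path"]
            if not p.exists():
                raise PipelineError(f"ingest: missing volume file: {p}")
            volumes[row["sequence"]] = load_volume(p)
            truths[row["sequence"]] = float(row.get("true_contrast_percent", np.nan))
        raters = sorted(sdir.glob("lc_rater*.nii.gz"))
        if not raters:
            raise PipelineError(f"ingest: no rater masks found under {sdir}")
        vent_path = sdir / "ventricle_mask.nii.gz"
        if not vent_path.exists():
            raise PipelineError(f"ingest: missing mask file: {vent_path}")
        subjects.append(SyntheticSubject(
            subject_id=str(sub_id),
            volumes=volumes,
            true_mask=None,  # unknown for acquired data
            rater_masks=[load_mask(p, role="rater") for p in raters],
            ventricle_mask=load_mask(vent_path, role="ventricle"),
            pt_mask=None,
            pt_center=tuple(config.pt_center),
            true_contrasts=truths,
        ))
    return subjects


def _header_lines(config: RunConfig) -> str:
    return (f"# lc-contrast v{__version__}\n"
            f"# config_hash = {config.config_hash()}\n"
            f"# seed = {config.seed}\n")


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(config))
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g", na_rep="NA")


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the run report (also written to disk).

    Stages: cohort acquisition, ROI construction, median extraction, contrast
    statistics with outlier rejection, one-sample evidence per sequence and
    contrast, screening at BF10 > threshold, sign inversion of hypointense
    screened sequences, the mixed-model interaction Bayes factor, and
    post-hoc pairwise comparisons.
    """
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(fh)
    report: dict = {"seed": config.seed, "config_hash": config.config_hash(),
                    "version": __version__, "stages": {}}
    timings: dict[str, float] = {}

    def stage_done(name: str, **info) -> None:
        timings[name] = round(time.monotonic() - t0, 3)
        report["stages"][name] = info
        log.info("stage %s done: %s", name, info)

    # -- cohort -------------------------------------------------------------
    if config.mode == "synthetic":
        spec = dataclasses.replace(config.phantom, seed=config.seed)
        cohort = generate_cohort(spec)
        subjects = cohort.subjects
        midline = spec.midline_index
        manifest_rows = [
            {"subject": s.subject_id, "sequence": name,
             "true_contrast_percent": s.true_contrasts[name]}
            for s in subjects for name in s.volumes]
        _write_tsv(pd.DataFrame(manifest_rows), out / "cohort_manifest.tsv", config)
        if config.write_nifti:
            from .phantom import write_cohort
            write_cohort(cohort, out / "cohort")
    else:
        subjects = _load_nifti_cohort(config)
        midline = config.midline_index
    stage_done("cohort", subjects_in=len(subjects))

    # -- ROIs and medians ---------------------------------------------------
    medians_frames = []
    for sub in subjects:
        try:
            rois = build_roi_set(sub.rater_masks, sub.ventricle_mask,
                                 sub.pt_center, midline,
                                 min_votes=config.min_votes,
                                 pt_size_mm=config.pt_size_mm)
        except Exception as exc:
            raise PipelineError(f"rois: subject {sub.subject_id}: {exc}") from exc
        if config.write_nifti:
            from .images import save_mask
            rdir = out / "rois" / sub.subject_id
            rdir.mkdir(parents=True, exist_ok=True)
            for name, m in rois.as_dict().items():
                save_mask(m, rdir / f"{name}.nii.gz")
        try:
            medians_frames.append(extract_roi_medians(sub.volumes, rois,
                                                      sub.subject_id))
        except Exception as exc:
            raise PipelineError(f"extract: subject {sub.subject_id}: {exc}") from exc
    medians = pd.concat(medians_frames, ignore_index=True)
    _write_tsv(medians, out / "medians.tsv", config)
    stage_done("extract", rows=len(medians))

    # -- contrasts ----------------------------------------------------------
    hemi = compute_contrasts(medians)
    records = average_hemispheres(hemi)
    records = flag_outliers(records, k=config.outlier_k, on=config.outlier_on)
    n_out = int(records["outlier"].sum())
    _write_tsv(records, out / "contrasts.tsv", config)
    summary = summarize(records)
    _write_tsv(summary, out / "summary.tsv", config)
    stage_done("contrast", records=len(records), outliers_flagged=n_out)

    # -- one-sample evidence and screening -----------------------------------
    bf_rows = []
    for (seq, cname), grp in records.groupby(["sequence", "contrast"], sort=False):
        vals = grp.loc[~grp["outlier"], "avg"].dropna().to_numpy()
        try:
            res = jzs_one_sample_bf(vals, r=config.bayes.prior_scale)
        except Exception as exc:
            raise PipelineError(f"bayes: {seq}/{cname}: {exc}") from exc
        bf_rows.append({"sequence": seq, "contrast": cname, "n": res.n,
                        "bf10": res.bf10, "error": res.error, "label": res.label})
    bf_table = pd.DataFrame(bf_rows)
    _write_tsv(bf_table, out / "one_sample_bf.tsv", config)
    screened = screen_sequences(bf_table, threshold=config.bayes.screening_threshold)
    stage_done("screening", screened=screened)

    # -- sign inversion of hypointense screened sequences --------------------
    if config.invert_sequences is None:
        means = records[~records["outlier"]].groupby("sequence")["avg"].mean()
        to_invert = [s for s in screened if means.get(s, 0.0) < 0]
    else:
        to_invert = list(config.invert_sequences)
    if to_invert:
        records = invert_sign(records, to_invert)
    report["inverted_sequences"] = to_invert

    # -- mixed model and post-hoc pairwise -----------------------------------
    analysis = records[records["sequence"].isin(screened)].copy()
    analysis.loc[analysis["outlier"], "avg"] = np.nan
    mixed = None
    if len(screened) >= 2:
        long = analysis.rename(columns={"contrast": "level", "avg": "value"})
        long = long[["subject", "sequence", "level", "value"]]
        mixed = mixed_model_bf(long, config=config.bayes, seed=config.seed)
        report["mixed_model"] = {"bf10": mixed.bf10, "mc_error": mixed.error,
                                 "label": mixed.label, "n": mixed.n}
        pair_rows = []
        wide = analysis.pivot_table(index=["subject", "contrast"],
                                    columns="sequence", values="avg",
                                    dropna=False)
        for i, a in enumerate(screened):
            for b in screened[i + 1:]:
                for cname in CONTRAST_NAMES:
                    sub = wide.xs(cname, level="contrast")
                    res = jzs_paired_bf(sub[a].to_numpy(), sub[b].to_numpy(),
                                        r=config.bayes.prior_scale)
                    pair_rows.append({"sequence_a": a, "sequence_b": b,
                                      "contrast": cname, "n": res.n,
                                      "bf10": res.bf10, "label": res.label})
        _write_tsv(pd.DataFrame(pair_rows), out / "pairwise_bf.tsv", config)
        stage_done("pairwise", comparisons=len(pair_rows))

    # -- report ---------------------------------------------------------------
    n_subjects = len(subjects)
    report["subjects_in"] = n_subjects
    report["subjects_out"] = n_subjects  # subjects drop per-value, not wholesale
    report["screened_sequences"] = screened
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    log.info("run complete in %.1fs; timings: %s",
             time.monotonic() - t0, timings)
    log.removeHandler(fh)
    fh.close()
    return report
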