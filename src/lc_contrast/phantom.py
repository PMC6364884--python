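"""Synthetic brainstem phantom cohorts.

The phantom emulates the measurement situation of neuromelanin-sensitive
brainstem imaging: two small hyperintense (or hypointense) tubular nuclei sit
bilaterally next to a CSF-filled midline ventricle, embedded in homogeneous
pontine tissue.  Per "sequence" the nuclei carry a true relative contrast of a
few percent against the surrounding tissue; volumes are degraded with Rician
noise (magnitude MRI) and each subject comes with several imperfect rater
segmentations, so that the full downstream analysis — conjunction masks, ring
control regions, median extraction, contrast statistics and Bayes factors —
can be exercised without any acquired data.

Everything is deterministic given the spec's global seed: per-subject,
per-sequence random substreams are derived by seeding
``numpy.random.SeedSequence`` with stable integer tuples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .images import BinaryMask, VolumeImage, save_mask, save_volume

__all__ = [
    "SequenceSpec", "LcGeometry", "VentricleGeometry", "PhantomSpec",
    "SyntheticSubject", "SyntheticCohort",
    "generate_phantom", "simulate_raters", "generate_cohort", "write_cohort",
    "default_sequences",
]

# substream tags so that different random purposes never collide
_TAG_TRUTH = 101
_TAG_NOISE = 102
_TAG_RATER = 103


@dataclass(frozen=True)
class SequenceSpec:
    """One imaging "sequence" of the phantom study.

    Parameters
    ----------
    name:
        Sequence label, e.g. ``"spir_like"``.
    true_contrast1_percent:
        Nominal relative contrast of the nucleus against surrounding tissue,
        in percent; may be negative (hypointense nucleus).
    noise_sigma:
        Rician noise level as a fraction of the baseline intensity.
    between_subject_sd:
        SD (percentage points) of the per-subject true contrast around the
        nominal value.
    intensity_gradient:
        Amplitude of a smooth multiplicative anterior--posterior bias field,
        as a fraction of baseline (0 disables it).
    """

    name: str
    true_contrast1_percent: float
    noise_sigma: float = 0.0
    between_subject_sd: float = 0.0
    intensity_gradient: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError(f"{self.name}: noise_sigma must be >= 0")
        if self.between_subject_sd < 0:
            raise ValueError(f"{self.name}: between_subject_sd must be >= 0")
        if 1.0 + self.true_contrast1_percent / 100.0 <= 0:
            raise ValueError(f"{self.name}: baseline plus contrast must stay positive")


@dataclass(frozen=True)
class LcGeometry:
    """Bilateral tubular nucleus geometry (one tube per hemisphere)."""

    offset_mm: float = 3.5          # tube-centre distance from the midline
    y_mm: float = 22.0              # tube-centre position along the A--P axis
    radius_mm: float = 1.25         # in-plane tube radius
    slices: tuple[int, int] = (3, 9)  # half-open rostrocaudal slice range


@dataclass(frozen=True)
class VentricleGeometry:
    """Midline CSF region: a box straddling the midline on every slice."""

    half_width_mm: float = 1.5
    y_range_mm: tuple[float, float] = (20.0, 26.0)


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a synthetic cohort.

    The defaults draw a 64x64x12 grid at 0.5x0.5x1.0 mm with 1.25 mm-radius
    nuclei — small enough for seconds-scale tests while leaving room for the
    plus-2 ring and a pontine-tegmentum reference box.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 12)
    voxel_size_mm: tuple[float, float, float] = (0.5, 0.5, 1.0)
    baseline_intensity: float = 1000.0
    csf_factor: float = 0.3
    lc_geometry: LcGeometry = field(default_factory=LcGeometry)
    ventricle_geometry: VentricleGeometry = field(default_factory=VentricleGeometry)
    pt_center: tuple[int, int] = (32, 20)
    pt_size_mm: float = 4.0
    sequence_specs: tuple[SequenceSpec, ...] = ()
    n_subjects: int = 12
    rater_jitter: float = 0.1
    n_raters: int = 4
    partial_volume: bool = False
    noise_model: str = "rician"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (0.0 <= self.rater_jitter < 1.0):
            raise ValueError("rater_jitter must lie in [0, 1)")
        if self.n_raters < 1:
            raise ValueError("n_raters must be >= 1")
        if self.baseline_intensity <= 0:
            raise ValueError("baseline_intensity must be positive")
        if self.noise_model not in ("rician", "gaussian"):
            raise ValueError("noise_model must be 'rician' or 'gaussian'")
        object.__setattr__(self, "sequence_specs", tuple(self.sequence_specs))
        self._check_geometry()

    @property
    def midline_index(self) -> int:
        return self.grid_shape[0] // 2

    # -- geometry ----------------------------------------------------------

    def _check_geometry(self) -> None:
        lc = self.lc_fraction_field()
        vent = self.ventricle_mask().data
        pt = self._pt_box_2d()
        lo, hi = self.lc_geometry.slices
        if not (0 <= lo < hi <= self.grid_shape[2]):
            raise ValueError("lc slice range outside grid")
        lc_any = lc > 0
        if (lc_any & vent).any():
            raise ValueError("LC tubes overlap the ventricle region")
        pt3 = np.zeros(self.grid_shape, dtype=bool)
        pt3[:, :, lo:hi] = pt[:, :, None]
        if (pt3 & (lc_any | vent)).any():
            raise ValueError("pt region overlaps LC or ventricle")

    def lc_fraction_field(self) -> np.ndarray:
        """In-plane area fraction of each voxel covered by the LC tubes.

        Fractions are computed by 15x15 subvoxel sampling of the tube circles
        (both hemispheres) and broadcast over the tube's slice range.
        """
        nx, ny, nz = self.grid_shape
        dx, dy, _ = self.voxel_size_mm
        g = self.lc_geometry
        mid_mm = self.midline_index * dx  # midline column centre, mm
        centers = [(mid_mm - g.offset_mm, g.y_mm), (mid_mm + g.offset_mm, g.y_mm)]

        sub = (np.arange(15) + 0.5) / 15.0 - 0.5
        ox, oy = np.meshgrid(sub * dx, sub * dy, indexing="ij")
        xs = (np.arange(nx) + 0.0) * dx  # voxel-centre coordinates
        ys = (np.arange(ny) + 0.0) * dy

        frac2d = np.zeros((nx, ny))
        for cx, cy in centers:
            # restrict to a window around the tube for speed
            ix = np.where(np.abs(xs - cx) <= g.radius_mm + dx)[0]
            iy = np.where(np.abs(ys - cy) <= g.radius_mm + dy)[0]
            if len(ix) == 0 or len(iy) == 0:
                raise ValueError("LC tube lies outside the grid")
            for i in ix:
                for j in iy:
                    px = xs[i] + ox
                    py = ys[j] + oy
                    inside = (px - cx) ** 2 + (py - cy) ** 2 <= g.radius_mm ** 2
                    frac2d[i, j] = max(frac2d[i, j], inside.mean())
        lo, hi = g.slices
        frac = np.zeros(self.grid_shape)
        frac[:, :, lo:hi] = frac2d[:, :, None]
        return frac

    def lc_true_mask(self) -> BinaryMask:
        """True nucleus mask: voxels with >= 50% in-plane tube coverage."""
        return BinaryMask(self.lc_fraction_field() >= 0.5, self.voxel_size_mm, role="LC")

    def ventricle_mask(self) -> BinaryMask:
        nx, ny, nz = self.grid_shape
        dx, dy, _ = self.voxel_size_mm
        v = self.ventricle_geometry
        xs = np.arange(nx) * dx
        ys = np.arange(ny) * dy
        mid_mm = self.midline_index * dx
        in_x = np.abs(xs - mid_mm) <= v.half_width_mm
        in_y = (ys >= v.y_range_mm[0]) & (ys <= v.y_range_mm[1])
        m = np.zeros(self.grid_shape, dtype=bool)
        m[np.ix_(np.where(in_x)[0], np.where(in_y)[0], np.arange(nz))] = True
        return BinaryMask(m, self.voxel_size_mm, role="ventricle")

    def _pt_box_2d(self) -> np.ndarray:
        nx, ny, _ = self.grid_shape
        dx = self.voxel_size_mm[0]
        edge = int(round(self.pt_size_mm / dx))
        cx, cy = self.pt_center
        x0, y0 = cx - edge // 2, cy - edge // 2
        if x0 < 0 or y0 < 0 or x0 + edge > nx or y0 + edge > ny:
            raise ValueError("pt box exceeds grid bounds")
        box = np.zeros((nx, ny), dtype=bool)
        box[x0:x0 + edge, y0:y0 + edge] = True
        return box

    def pt_mask(self) -> BinaryMask:
        """Reference box on every slice the nucleus occupies."""
        lo, hi = self.lc_geometry.slices
        m = np.zeros(self.grid_shape, dtype=bool)
        m[:, :, lo:hi] = self._pt_box_2d()[:, :, None]
        return BinaryMask(m, self.voxel_size_mm, role="pt")

    # -- serialisation -----------------------------------------------------

    def to_yaml(self, path: str | Path | None = None) -> str:
        d = asdict(self)
        text = yaml.safe_dump(d, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PhantomSpec":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        d = yaml.safe_load(text)
        if "lc_geometry" in d:
            g = dict(d["lc_geometry"])
            if "slices" in g:
                g["slices"] = tuple(g["slices"])
            d["lc_geometry"] = LcGeometry(**g)
        if "ventricle_geometry" in d:
            g = dict(d["ventricle_geometry"])
            if "y_range_mm" in g:
                g["y_range_mm"] = tuple(g["y_range_mm"])
            d["ventricle_geometry"] = VentricleGeometry(**g)
        if "sequence_specs" in d:
            d["sequence_specs"] = tuple(
                SequenceSpec(**s) for s in d["sequence_specs"])
        for key in ("grid_shape", "voxel_size_mm", "pt_center"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticSubject:
    """All per-subject phantom data, born co-registered on one grid."""

    subject_id: str
    volumes: dict[str, VolumeImage]
    true_mask: BinaryMask | None      # unknown for ingested (non-phantom) data
    rater_masks: list[BinaryMask]
    ventricle_mask: BinaryMask
    pt_mask: BinaryMask | None
    pt_center: tuple[int, int]
    true_contrasts: dict[str, float]   # realised per-subject truth, percent


@dataclass
class SyntheticCohort:
    spec: PhantomSpec
    subjects: list[SyntheticSubject]

    @property
    def sequence_names(self) -> list[str]:
        return [s.name for s in self.spec.sequence_specs]


def default_sequences() -> tuple[SequenceSpec, ...]:
    """A cohort emulating the contrast regime of a multi-sequence LC study.

    Nominal contrasts span roughly -0.5% to +6% with between-subject spreads
    of the order seen across such sequences; noise is 2% of baseline.
    """
    return (
        SequenceSpec("tse_3t_like", 4.4, noise_sigma=0.02, between_subject_sd=1.2),
        SequenceSpec("tse_7t_like", 2.9, noise_sigma=0.02, between_subject_sd=2.4),
        SequenceSpec("t2star_mag_like", -0.5, noise_sigma=0.02, between_subject_sd=0.15),
        SequenceSpec("spir_like", 5.6, noise_sigma=0.02, between_subject_sd=1.9),
        SequenceSpec("wb_t1_like", 1.3, noise_sigma=0.02, between_subject_sd=2.1),
    )


def _rng(spec_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, *key]))


def _apply_noise(clean: np.ndarray, sigma_abs: float, model: str,
                 rng: np.random.Generator) -> np.ndarray:
    if sigma_abs == 0:
        return clean.copy()
    if model == "rician":
        # magnitude of (signal + complex Gaussian noise)
        re = clean + rng.normal(0.0, sigma_abs, clean.shape)
        im = rng.normal(0.0, sigma_abs, clean.shape)
        return np.hypot(re, im)
    return clean + rng.normal(0.0, sigma_abs, clean.shape)


def generate_phantom(spec: PhantomSpec, subject_index: int) -> SyntheticSubject:
    """Generate one subject's volumes, truth and rater masks.

    Deterministic given ``(spec.seed, subject_index)``.  Nucleus voxels carry
    an expected intensity of ``baseline * (1 + c/100)`` where ``c`` is the
    subject's realised true contrast for the sequence; surrounding tissue sits
    at baseline and the ventricle at ``baseline * csf_factor``.  With
    ``partial_volume`` enabled, intensities at the tube boundary are area
    weighted so that voxels just outside the true mask remain contaminated.
    """
    if not (0 <= subject_index < spec.n_subjects):
        raise ValueError(f"subject_index {subject_index} outside cohort of {spec.n_subjects}")
    if not spec.sequence_specs:
        raise ValueError("PhantomSpec has no sequences")

    frac = spec.lc_fraction_field()
    true_mask = BinaryMask(frac >= 0.5, spec.voxel_size_mm, role="LC")
    vent = spec.ventricle_mask()
    ptm = spec.pt_mask()

    ny = spec.grid_shape[1]
    ramp = (np.arange(ny) - (ny - 1) / 2.0) / ((ny - 1) / 2.0)  # -1..1, A--P

    volumes: dict[str, VolumeImage] = {}
    truths: dict[str, float] = {}
    for j, seq in enumerate(spec.sequence_specs):
        truth_rng = _rng(spec.seed, subject_index, j, _TAG_TRUTH)
        c = seq.true_contrast1_percent
        if seq.between_subject_sd > 0:
            c = float(truth_rng.normal(c, seq.between_subject_sd))
        weight = frac if spec.partial_volume else true_mask.data.astype(float)
        clean = spec.baseline_intensity * (1.0 + (c / 100.0) * weight)
        clean[vent.data] = spec.baseline_intensity * spec.csf_factor
        if seq.intensity_gradient:
            clean = clean * (1.0 + seq.intensity_gradient * ramp)[None, :, None]
        noise_rng = _rng(spec.seed, subject_index, j, _TAG_NOISE)
        data = _apply_noise(clean, seq.noise_sigma * spec.baseline_intensity,
                            spec.noise_model, noise_rng)
        volumes[seq.name] = VolumeImage(data, spec.voxel_size_mm)
        truths[seq.name] = c

    raters = simulate_raters(true_mask, spec.rater_jitter, spec.n_raters,
                             seed=None,
                             rng=_rng(spec.seed, subject_index, _TAG_RATER))
    return SyntheticSubject(
        subject_id=f"sub-{subject_index + 1:02d}",
        volumes=volumes,
        true_mask=true_mask,
        rater_masks=raters,
        ventricle_mask=vent,
        pt_mask=ptm,
        pt_center=spec.pt_center,
        true_contrasts=truths,
    )


def _boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """In-plane 8-neighbourhood boundary, on both sides of the surface."""
    from scipy import ndimage

    box = np.ones((3, 3, 1), dtype=bool)
    dil = ndimage.binary_dilation(mask, structure=box)
    ero = ndimage.binary_erosion(mask, structure=box)
    return (mask & ~ero) | (~mask & dil)


def simulate_raters(true_mask: BinaryMask, jitter: float, n_raters: int = 4,
                    seed: int | None = None,
                    rng: np.random.Generator | None = None) -> list[BinaryMask]:
    """Simulate imperfect manual segmentations.

    Each rater mask equals the true mask with boundary voxels — voxels having
    at least one in-plane 8-neighbour of the opposite value — independently
    flipped with probability ``jitter``; interior voxels are untouched.
    """
    if n_raters < 1:
        raise ValueError("n_raters must be >= 1")
    if not (0.0 <= jitter < 1.0):
        raise ValueError("jitter must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    boundary = _boundary_voxels(true_mask.data)
    out = []
    for _ in range(n_raters):
        flips = boundary & (rng.random(true_mask.shape) < jitter)
        out.append(BinaryMask(true_mask.data ^ flips, true_mask.voxel_size_mm,
                              role="rater"))
    return out


def generate_cohort(spec: PhantomSpec) -> SyntheticCohort:
    """Generate all subjects of the cohort (deterministic given the spec)."""
    subjects = [generate_phantom(spec, i) for i in range(spec.n_subjects)]
    return SyntheticCohort(spec=spec, subjects=subjects)


def write_cohort(cohort: SyntheticCohort, outdir: str | Path) -> Path:
    """Write the cohort as NIfTI-1 files plus a TSV manifest.

    Returns the manifest path.  Layout: one volume per subject x sequence,
    per-subject rater/ventricle/pt/truth masks (uint8).
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rows = ["subject\tsequence\tpath\ttrue_contrast_percent"]
    for sub in cohort.subjects:
        sdir = out / sub.subject_id
        sdir.mkdir(exist_ok=True)
        for name, vol in sub.volumes.items():
            p = sdir / f"{name}.nii.gz"
            save_volume(vol, p)
            rows.append(f"{sub.subject_id}\t{name}\t{p.relative_to(out)}"
                        f"\t{sub.true_contrasts[name]:.6f}")
        save_mask(sub.true_mask, sdir / "lc_true_mask.nii.gz")
        for k, rm in enumerate(sub.rater_masks):
            save_mask(rm, sdir / f"lc_rater{k + 1}.nii.gz")
        save_mask(sub.ventricle_mask, sdir / "ventricle_mask.nii.gz")
        save_mask(sub.pt_mask, sdir / "pt_mask.nii.gz")
    manifest = out / "manifest.tsv"
    manifest.write_text("\n".join(rows) + "\n")
    return manifest
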