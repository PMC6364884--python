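# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic phantom does and does
not emulate, and the numerical decisions a maintainer would want to know.

## The measurement model

A small nucleus of interest (the locus coeruleus, LC) is quantified on
co-registered 3D volumes by comparing its median intensity with reference
regions. Medians rather than means are used throughout: ROIs of tens of
voxels are dominated by boundary effects, and the median is insensitive to
the handful of partial-volume or noise-corrupted voxels at the rim.

Three references are computed per hemisphere. The `plus1` ring (directly
adjacent voxels) probes the exact border one would draw when segmenting; the
`plus2` ring (two voxels out) probes the same border while being less
contaminated by partial-volume spill-over from the nucleus; the pontine
tegmentum (PT) box is a conventional distant reference that is immune to
LC partial volume but anatomically less homogeneous. Relative contrast is
`(LC − ref)/ref × 100` in percent. Because the statistic is a ratio of
medians from the same volume, it is invariant under any multiplicative
intensity scaling, so no intensity normalization is performed (a test
asserts invariance under scaling and sensitivity to additive offsets, which
is why offsets must not be introduced upstream).

### ROI semantics

* **Conjunction mask**: a voxel belongs to the nucleus iff at least
  `min_votes` (default 3) of the rater segmentations contain it. Vote
  counting is exact and monotone: raising the threshold can only shrink the
  mask.
* **Rings**: the "one voxel away" region is the per-slice 3×3 box dilation
  minus the nucleus; "two voxels away" is the 5×5 dilation minus the 3×3
  dilation. Equivalently, rings are the in-plane Chebyshev-distance-1 and -2
  shells. Two readings of the construction were possible (does `plus2`
  exclude `plus1`, or only the nucleus?); the shell reading was chosen
  because the two rings are used as *distinct* contrast levels — control
  regions at different distances — which requires them to be disjoint.
  Dilation is strictly two-dimensional: slab acquisitions have anisotropic
  slices, and a ring that crossed slices would mix different
  partial-volume regimes.
* **Ventricle exclusion** is enforced when building the rings (not merely
  verified afterwards): CSF voxels next to the nucleus would otherwise enter
  a control region and inflate the contrast. The construction is ambiguous
  in prose descriptions of this workflow; enforcing exclusion is the
  conservative reading and is what the invariants assert.
* **PT box**: a square of edge `round(size_mm / in-plane voxel size)` voxels
  (default 4.0 mm → 8×8 voxels at 0.5 mm) at an explicitly supplied
  landmark, placed on every axial slice that contains nucleus voxels. No
  automatic pons detection is attempted. Overlap with the nucleus or its
  rings is an error, not a warning.
* **Hemispheres** are split at a midline voxel column; voxels exactly on the
  column belong to neither side and are dropped with a logged count, so
  left/right statistics never share voxels. The PT box straddles the
  midline and is deliberately *not* split: it is a single central reference,
  and its median is recorded identically for both hemisphere rows.

### Contrast statistics

Hemisphere values are averaged per subject (no a-priori hemisphere
hypothesis); a record built from a single hemisphere is flagged rather than
dropped. Outliers are flagged by Tukey fences at `k = 3` times the IQR
beyond the quartiles — the standard reading of a "3× interquartile range"
criterion — computed independently per sequence × contrast definition, on
the hemisphere-averaged values (a switch allows per-hemisphere rejection
instead; averaging first matches the order of operations the summary
statistics assume). Quartiles use linear interpolation between order
statistics everywhere (outlier fences, across-subject IQR, within-mask
variability), fixed because every IQR-derived quantity depends on the
convention. An outlier-flagged value is excluded from every downstream
summary, Bayes factor and pairwise comparison; missing values propagate as
missing, never as zeros. Left/right consistency is a plain Pearson
correlation across subjects; with fewer than 3 complete pairs or zero
variance it is reported as missing rather than fabricated.

Hypointense sequences (nucleus darker than surround) can be sign-inverted
(×−1) so all sequences are compared on a common positive scale; the
operation records a flag and refuses to run twice or on unknown sequence
names.

## Bayesian evidence

### JZS t-tests

The one-sample Bayes factor uses the default JZS setup: under H1 the
standardized effect δ carries a Cauchy(0, r) prior with r = 0.707;
equivalently δ|g ~ N(0, g) with g ~ InverseGamma(1/2, r²/2). BF₁₀ is the
ratio of the marginal likelihood of the observed t statistic under H1 to its
value at δ = 0, computed by adaptive quadrature of the likelihood ratio
against the mixing density. Numerically, g is substituted as g = r²·s with
s ~ InverseGamma(1/2, 1/2) and the s-axis compactified to (0, 1); without
that substitution the prior's mass concentrates in an O(r²) spike and the
quadrature silently misses it for small r (the r → 0 limit, BF → 1, is a
regression test). The quadrature error estimate is attached to every result.
The paired test is the one-sample test on within-subject differences after
listwise exclusion of incomplete pairs, and reports the reduced n.

Tests validate the implementation against an independently coded oracle
that takes a different route entirely — marginalising the noncentral-t
likelihood over the Cauchy prior — with agreement to ~10⁻¹³ relative over a
(t, n) grid.

Evidence labels follow the conventional Jeffreys-style ladder (boundaries
1/100, 1/30, 1/10, 1/3, 1, 3, 10, 30, 100). The ladder leaves boundary
membership open; here a BF exactly on a boundary falls in the
weaker-evidence interval, and BF₁₀ = 1 is "No evidence". Screening for
cross-sequence comparison requires BF₁₀ strictly greater than 10 for **all
three** contrast definitions.

### Mixed-model interaction Bayes factor

To ask whether contrast depends on the interplay of sequence and reference
distance, the package compares the linear mixed model
`sequence + level + sequence:level + subject` against
`sequence + level + subject` under default g-priors on standardized
effects. Effects are grouped in batches; batch b has θ_b | g_b ~
N(0, σ²g_b I) with g_b ~ InverseGamma(1/2, r_b²/2), r = 0.5 for
fixed-effect batches and r = 1 for the subject batch (the conventional
"default prior scales"), with Jeffreys priors on the grand mean and σ².
Factor design matrices use orthonormal sum-to-zero contrasts, the
interaction design is the column-wise product of the projected main-effect
designs, and conditional on g the marginal likelihood has the closed form

    BF(g) = |G|^(−1/2) |X'X + G⁻¹|^(−1/2) (1 − b'M⁻¹b / y'y)^(−(N−1)/2)

with centred X and y. The g's are integrated by Monte-Carlo (default 10⁵
draws, g = r²/χ²₁, fixed seed), vectorised over draws with batched Cholesky
factorizations; the MC standard error of the resulting BF is reported so
that decisions near a threshold can be recognized as unstable. The test
suite cross-checks the MC estimate on a tiny 2×2 design against an oracle
that integrates the *observation-space* covariance Σ = I + Σ_b g_b X_b X_bᵀ
on tensor-product Gauss–Legendre grids — a derivation sharing no code path
with the implementation. An empty design cell raises an error naming the
cell; the model assumes balanced or missing-at-random data.

## The synthetic phantom

The generator emulates the geometry and statistics the analysis assumes: a
64×64×12 grid at 0.5×0.5×1.0 mm; two tubular nuclei of radius 1.25 mm
(≈2–3 voxels in-plane, the "small nucleus" regime) offset ±3.5 mm from the
midline over slices 3–8; a CSF-like midline ventricle box adjacent to the
tubes (so ring construction genuinely needs the exclusion); a PT landmark
anterior to the ventricle; and per-sequence true contrasts. Per subject and
sequence, the true contrast is drawn around the nominal value with a
between-subject SD, tissue is set to `baseline × (1 + c/100)` inside the
nucleus, and Rician noise is applied as |signal + complex Gaussian| (a
Gaussian flag exists for unit tests). Rater masks equal the truth with
boundary voxels — those with an opposite-valued in-plane 8-neighbour —
independently flipped with probability `rater_jitter` (default 0.1; no
quantitative inter-rater figure was available to calibrate against, so this
is a free parameter, not an estimate of any particular raters).

The default cohort (`default_sequences()`) spans nominal contrasts from
−0.5% to +5.6% with between-subject spreads of 0.15–2.4 percentage points
and 2% Rician noise — the regime in which some sequences clearly pass a
BF₁₀ > 10 screen and others clearly fail, which is the structure the
evidence workflow must resolve.

Randomness is fully reproducible: every purpose (truth draw, noise field,
rater flips) derives its own `SeedSequence` from stable integer tuples
`(seed, subject, sequence, tag)`, so cohorts are bitwise identical across
runs and stable under partial regeneration.

**Partial volume** is opt-in (`partial_volume=True`): boundary voxels then
carry area-weighted intensities computed by 15×15 sub-voxel sampling of the
tube circles. It is off by default because the defaults define an exactness
contract — a noiseless cohort must reproduce its configured contrast to
machine precision through the entire chain, which pins down the sign
conventions and the median semantics. With partial volume on and a tube
radius of ~1.4 mm, the majority of `plus1` voxels are contaminated while
`plus2` stays clean, reproducing the expected ordering contrast2 ≥
contrast1 (measured 10.0 vs 8.8 at 10% truth); that configuration is the
contamination fixture in the tests.

What the phantom does **not** emulate: k-space acquisition, B0/B1
inhomogeneity beyond an optional smooth bias ramp, geometric distortion,
registration error (volumes are born aligned — corresponding to a
native-space analysis), anatomical texture inside the nucleus or pons, and
rostrocaudal truncation of slab coverage. Passing tests therefore certify
the analysis logic and its statistical calibration, not robustness to
registration or acquisition artifacts.

Rician noise at high SNR inflates the background mean by ≈ σ²/(2μ) — 0.02%
of baseline at the default σ = 2% — which biases both nucleus and reference
medians nearly equally; the recovery tolerance (±1 percentage point on the
cohort mean) absorbs it comfortably (observed worst-case ≈ 0.3 pp over 100
seeds).

## Problem sizes and calibration figures

The simulation studies in the test suite use sizes chosen to give stable
pass/fail margins at seconds-to-minutes scale: 100 seeds × 12 subjects for
noisy recovery and screening; 1000 null replicates at n = 12 for the
calibration of the one-sample workflow; 100 replicates each of additive and
interacting 3×3×12 designs (8000 MC draws per marginal) for the
mixed-model discrimination, with the crossed interaction pattern
`outer((−1,0,1),(−1,0,1))` scaled to one noise-SD per extreme cell.

One calibration fact is worth recording: under the null at n = 12 and
r = 0.707, the probability that BF₁₀ < 1/3 is an analytic constant ≈ 0.43
(BF₁₀(t) < 1/3 iff |t| < ≈0.56, and 2·F_t11(0.56) − 1 ≈ 0.43). Moderate
support for H0 is therefore the *plurality*, not the majority, outcome at
this sample size; a majority would require larger n. The test suite asserts
the spurious-evidence rate (BF₁₀ > 10 under the null < 2%; observed ≈1%).

## Pipeline and provenance

`run_pipeline` sequences the stages (cohort → ROIs → medians → contrasts →
one-sample BFs → screening → inversion → mixed model → pairwise BFs) and
aborts on the first stage error, naming the stage and subject. Every TSV
carries a header block with package version, a hash of the
analysis-relevant configuration (output paths and verbosity excluded), and
the seed; floats are written with a fixed `%.12g` format so identical
config + seed yields byte-identical tables. Hypointense screened sequences
are auto-inverted before cross-sequence comparison unless an explicit list
is configured. Per-stage wall-clock timings go to the run log only and are
never part of compared outputs.
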