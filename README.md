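# lc-contrast

Quantifying how strongly a small brainstem nucleus — the locus coeruleus
(LC) — stands out from its surroundings on co-registered structural MRI, and
deciding, with Bayes factors, which pulse sequences deliver detectable
contrast.

The LC is a thin, bilateral, neuromelanin-rich nucleus beside the fourth
ventricle, a few millimetres across. Visualizing it is a borderline problem:
the relevant signal differences are a few percent, ROIs hold tens of voxels,
and the choice of reference region changes the answer. This package
implements the full quantification chain for that setting:

* **ROI construction** — a conjunction mask keeping voxels marked by at
  least 3 of 4 rater segmentations; ring control regions one and two voxels
  away from the nucleus (in-plane 2D box kernel, so rings never cross axial
  slices) with the ventricle excluded; and a ~4×4 mm pontine-tegmentum (PT)
  reference box on every slice the nucleus occupies.
* **Signal extraction** — per-hemisphere median intensity in each ROI, plus
  a median/IQR within-mask variability ratio.
* **Contrast statistics** — three relative contrasts per subject, sequence
  and hemisphere,

  ```
  contrast1  = (LC − LCplus1) / LCplus1 × 100
  contrast2  = (LC − LCplus2) / LCplus2 × 100
  contrast_pt = (LC − PT) / PT × 100
  ```

  hemisphere averaging, left/right Pearson consistency, Tukey-fence outlier
  rejection at 3×IQR, and one-time sign inversion for hypointense sequences.
* **Bayesian evidence** — JZS one-sample and paired t-test Bayes factors
  (Cauchy(0, 0.707) prior on the standardized effect, computed by
  quadrature, not delegated), a Jeffreys-style evidence ladder, screening of
  sequences at BF₁₀ > 10 on all three contrasts, and a default-g-prior
  mixed-model Bayes factor for the sequence × contrast-level interaction
  with subjects as a random factor.
* **A synthetic phantom cohort** — bilateral hyper-/hypointense tubes beside
  a CSF-like ventricle, Rician noise, imperfect rater masks — so the entire
  chain is testable end-to-end with known ground truth and no acquired data.

## Worked example

Run the full pipeline on the built-in five-sequence phantom cohort
(12 subjects, 2% Rician noise, true contrasts from −0.5% to +5.6%):

```python
from lc_contrast import PhantomSpec, RunConfig, default_sequences, run_pipeline

config = RunConfig(
    phantom=PhantomSpec(sequence_specs=default_sequences(), n_subjects=12),
    seed=1, out_dir="demo_run")
report = run_pipeline(config)
print(report["screened_sequences"])
```

```
['spir_like', 'tse_3t_like', 'tse_7t_like']
```

`demo_run/summary.tsv` then holds the cohort summary; for the strongest
sequence (true contrast 5.6%, between-subject SD 1.9):

```
 sequence    contrast  n  avg_median      iqr   cor_lr
spir_like   contrast1 12    6.142486 1.986470 0.960055
spir_like   contrast2 12    6.247451 1.989849 0.948841
spir_like contrast_pt 12    6.243507 2.050049 0.985193
```

`n` is the number of subjects surviving outlier rejection, `avg_median` the
cohort mean of the per-subject (median-based, hemisphere-averaged) contrast
in percent, `iqr` its across-subject spread, and `cor_lr` the left/right
Pearson correlation. The three sequences with clearly positive true contrast
pass screening; the near-zero ones do not. `one_sample_bf.tsv` and
`pairwise_bf.tsv` hold the per-sequence and pairwise Bayes factors with
evidence labels, and `report.json` the run provenance (seed, config hash,
mixed-model BF with its Monte-Carlo standard error).

The same stages are available from the shell:

```
lc-contrast simulate --seed 1 --out cohort/
lc-contrast run --config run.yaml --seed 1
```

## Scope

The package assumes co-registered inputs on a shared voxel grid (the
phantom generator emits aligned volumes by construction). Image
registration, acquisition protocols, DICOM conversion and manual
segmentation GUIs are out of scope. See `docs/methods.md` for the model,
its assumptions, and the numerical choices.
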