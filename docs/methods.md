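# Methods

## Correction model

`refnorm` assumes observed GC-MS peak intensities factorize multiplicatively:

```
x[i,m] = c[i,m] · w_i · b[m, batch(i)] · d(run_i) · s[m]^{1(run_i > t_col)} · ε[i,m]
```

* `c[i,m]` — true concentration of metabolite *m* in sample *i*, per mg of
  dry tissue;
* `w_i` — sample dry weight (mg);
* `b[m,batch]` — analyte-specific multiplicative batch factor, constant
  within a batch;
* `d(run)` — smooth run-order sensitivity drift (column bleed/fouling);
* `s[m]` — analyte-specific step factor applied after a column replacement
  at run `t_col`;
* `ε[i,m]` — multiplicative measurement noise with mean 1.

The internal-standard channel is `IS_i = IS₀ · d(run_i) · ε_i^{IS}`: it
shares the run-level drift but **not** the analyte-specific factors — this
is the reason IS normalization alone cannot remove batch effects, and the
premise the reference-ratio method works around.

Dividing by `IS_i · w_i` removes dry weight and run-level drift. Dividing
by the batch-matched reference injection (same pooled material in every
batch, so `c[ref,m]` is one fixed vector) removes `b[m,batch]` and `s[m]`
for every test/reference pair on the same side of a column change. In the
noise-free limit the chain returns exactly `c[i,m]/c[ref,m]`; this exact
cancellation is a unit-tested invariant (relative error ≤ 1e-12 on the
simulator with noise and drift at zero).

### Reference assignment

Each test sample maps to the reference injection(s) of its own batch
nearest in **run-order index** (no timestamps are assumed). An exact tie —
which occurs for the sample equidistant from the mid-batch and end-of-batch
injections — keeps both references and divides by the *mean of their
intensities*, treating the two injections as replicate measurements of one
reference level (dividing by the mean, not averaging the two ratios). A
zero or missing reference value makes the affected cell missing and flags
it (`made-missing-by-zero-reference`); the alternative `drop` policy
removes the whole metabolite. Flagging is the default because a zero
reference in one batch says nothing about the metabolite's validity in
other batches.

## Baseline operators

* **Scalar** — each sample divided by its own total sum or median
  (missing excluded). Scale-equivariant per sample; distorts data when
  major analytes genuinely differ between samples.
* **QC median** — per metabolite and batch, divide by
  `median(QC in batch) / median(QC pooled over all batches)`. Undefined or
  nonpositive medians leave the metabolite unchanged, flagged.
* **QC-RLSC** — per metabolite, a degree-1 LOESS of QC intensity on run
  order (plain fit, zero robustness iterations, default span 0.75); each
  value is divided by the fit at its run order (clamped to the QC run-order
  range) and rescaled by the global QC median so corrected values stay on
  the intensity scale, keeping RSDs comparable with uncorrected data.
  Metabolites with fewer than `min_qc_points` (default 4) QC values fall
  back to QC-median correction, flagged. With two reference injections per
  batch this method has ample points across batches but cannot model
  within-batch structure; it is a baseline here, not the package's method.
  Degenerate LOESS windows (exactly two QC points) are evaluated by linear
  interpolation between the fitted QC points, which for a two-point
  degree-1 window is the exact connecting line.

## Diagnostics

* **RSD** — 100·sd/mean per metabolite within groups of nominally identical
  samples; sample standard deviation (n−1), matching the spreadsheet
  convention such tables are usually produced with. Groups with <2 values
  or zero mean give missing RSD. The before/after summary counts **strict**
  decreases; ties count against the correction.
* **RSD vs abundance** — signed Pearson correlation of RSD against mean
  abundance, reported for both raw and log10 abundance since the axis
  transformation of such plots varies between studies.
* **PCA** — on the correlation matrix: columns standardized to mean 0,
  sd 1, zero-variance columns excluded and reported, remaining missing
  cells imputed at 0 (the column mean) for the decomposition only. Percent
  variance is eigenvalue/total·100; loading vectors are oriented so their
  largest-magnitude element is positive, for reproducible score plots. The
  before/after comparison reports the PC1+PC2 percent change: positive
  deltas mean the correction spread variance across more components.
* **Ward HCA** — on Euclidean distances of standardized data, using the
  variant whose merge height between two singletons equals their Euclidean
  distance (heights are √(2·ΔESS)), so heights are nondecreasing. Verified
  in tests against direct enumeration of error-sum-of-squares increments.
  Exported as a 4-column merge table and as Newick with heights converted
  to branch lengths.

## Synthetic-data generator

The simulator emulates a batched acquisition campaign at a reduced scale
chosen so the full test suite runs in seconds: **98 metabolites, 6 batches,
5 entries × 2 biological replicates per batch**, one reference sample
injected at the middle and the end of each batch run (12 injections per
batch, 72 total), global run order across batches.

Defaults (all overridable via `SimulationConfig` / YAML):

| parameter | default | meaning |
|---|---|---|
| `abundance_log10_mean/sd` | 2.0 / 1.0 | metabolite baselines span ~4 orders of magnitude (scale relative to IS) |
| `sigma_bio` | 0.4 | sd of per-entry log-fold biological effects (shared by an entry's replicates) |
| `sigma_batch` | 0.3 | marginal sd of per-metabolite log batch factors |
| `batch_correlation` | 0.5 | shared fraction of batch-factor variance (see below) |
| `drift_rate` | 0.002/run | exponential sensitivity decay, shared with the IS channel |
| `column_change_run` | none | run after which per-metabolite step factors (log-sd `column_step_log_sd`=0.25) apply |
| `cv_base`, `cv_low_abundance` | 0.10, 0.5 | noise CV = cv_base + cv_low_abundance/√abundance; at the median baseline abundance (100) this gives CV 0.15 |
| `is_cv`, `is_nominal` | 0.05, 5·10⁴ | internal-standard channel noise and nominal area |
| `dry_weight_range_mg` | 2.5–3.5 | uniform dry-weight sampling, the plausible weighing range |

Noise is multiplicative log-normal, `exp(N(−σ²/2, σ))`, so its mean is
exactly 1 and values stay positive; σ is set to the target CV (exact CV is
√(exp(σ²)−1) ≈ σ for σ ≤ 0.3). Batch factors decompose as
`log b[m,batch] = σ_batch(√ρ·z_batch + √(1−ρ)·e[m,batch])`: a batch-level
sensitivity component shared by all metabolites plus an independent
metabolite-specific part, with the marginal per-metabolite sd kept at
`sigma_batch`. The shared component is what makes samples of one batch
cluster together in PCA/HCA, as real campaigns show; with ρ = 0 the batch
effects would be invisible to low-dimensional projections even though
per-metabolite RSDs are identical.

What the generator does **not** emulate: retention-time drift, peak
overlap/co-elution (matrix effects on the IS), derivatization kinetics,
non-multiplicative detector saturation, and structured missingness
(missingness must be injected manually). Passing tests therefore show the
operators are mathematically correct and effective against multiplicative
batch structure — not that the ratio method fixes co-elution artefacts or
censored low-abundance peaks in real data.

## Numerical and design choices

* Missing values are explicit NaN, never zero; zero is a legitimate
  measured intensity and normalizes to zero.
* Matrix orientation is normalized to samples-in-rows on read (a transpose
  flag accepts the other convention).
* Validation is lenient by default (positivity); strict mode additionally
  enforces the 2.5–3.5 mg dry-weight weighing range.
* `run_order` is global, so nearest-reference distances and drift are well
  defined across the whole sequence; batch membership is carried
  separately.
* Every operator appends itself to the matrix's normalization chain;
  `normalize_to_reference` warns (does not fail) if applied without a prior
  IS/dry-weight step.
* Batch count, entry panel and replicate counts are data-driven everywhere;
  nothing assumes the default design.
* The PC1+PC2 delta is only sign-stable when batch variance dominates the
  biological structure: with a small entry panel (5 entries), removing
  batch effects concentrates the remaining variance on few biological
  components and can make the delta negative even though RSDs improve. The
  qualitative delta>0 check therefore runs under a batch-dominant setting
  (`sigma_batch=0.5, batch_correlation=0.8, sigma_bio=0.2`); the RSD
  criterion uses the unchanged defaults.
* Single seed governs all simulator randomness; identical configs are
  bit-reproducible.

## Problem sizes

The default simulation (72 samples × 98 metabolites) runs in well under a
second; the 10-seed acceptance computation takes ~2 s and the full pytest
suite ~10 s on one CPU.
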