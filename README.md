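# refnorm

Reference-sample ratio normalization and batch-effect diagnostics for
multi-batch GC-MS metabolomics.

## The problem

Large metabolite-phenotyping campaigns run hundreds of samples over weeks,
split into acquisition batches. GC-MS signal changes systematically between
batches — column degradation, derivatization variability, detector drift —
so intensities from different batches cannot be compared directly, and the
batch effect is analyte-specific: a single internal standard (IS) cannot
capture how every metabolite's response drifts.

`refnorm` implements a correction built on a **pooled reference sample**
injected twice in every batch (at the middle and at the end of the batch
run). Because every reference injection derives from the same bulk
material, each analyte in a test sample can be expressed as a ratio to its
counterpart in the batch-matched reference, cancelling whatever multiplier
that batch applied to that analyte.

## The method

For sample *i*, metabolite *m*, with internal-standard peak area IS*ᵢ* and
dry weight *wᵢ* (mg), the corrected value is

```
y[i,m] = x[i,m] / (ISᵢ · wᵢ)                 (IS / dry-weight normalization)
z[i,m] = y[i,m] / y[ref(i),m]                (reference-ratio normalization)
```

where `ref(i)` is the reference injection of sample *i*'s batch nearest to
it in run order (an exact tie averages the two reference intensities before
dividing). If the observed intensity factorizes as
`x[i,m] = c[i,m] · wᵢ · b[m,batch] · noise`, with `c` the true per-mg
concentration and `b` the analyte-specific batch factor, then `z[i,m] =
c[i,m]/c[ref,m]` exactly in the noise-free limit — the batch factor, IS
response and dry weight all cancel.

The package also provides the standard baseline corrections for comparison
(per-sample total/median scaling, QC median-factor correction, QC-RLSC
LOESS drift correction), a diagnostic battery (per-metabolite RSD% =
100·sd/mean before vs after correction, RSD-vs-abundance correlation, PCA
on the correlation matrix with percent-variance accounting, Ward
hierarchical clustering), and a synthetic-data generator reproducing the
acquisition structure — per-metabolite multiplicative batch factors,
run-order drift, a column-replacement step change, and
concentration-dependent noise — so every claim is testable against known
ground truth.

## Worked example

```python
from refnorm import (SimulationConfig, simulate_experiment, build_layout,
                     normalize_is_dryweight, assign_references,
                     normalize_to_reference, compute_rsd,
                     rsd_reduction_summary)

cfg = SimulationConfig(seed=1)          # 98 metabolites, 6 batches,
matrix, records, truth = simulate_experiment(cfg)  # 5 entries x 2 replicates
layout = build_layout(records)

before = normalize_is_dryweight(matrix, records).matrix
after = normalize_to_reference(before, assign_references(layout, records)).matrix

grouping = {r.sample_id: r.entry for r in records if r.role == "test"}
summary = rsd_reduction_summary(compute_rsd(before, grouping),
                                compute_rsd(after, grouping))
print(f"fraction of metabolite RSDs reduced: {summary['fraction_reduced']:.3f}")
```

prints

```
fraction of metabolite RSDs reduced: 0.824
```

i.e. 82% of per-entry metabolite RSDs strictly decreased after reference
normalization; the median across-batch RSD drops from 34.1% to 20.8% on
this simulation, and the references' RSD correlates negatively with log10
abundance (r = −0.55), the expected low-abundance noise pattern.

The same workflow is available from the shell:

```sh
refnorm simulate --seed 1 --out-dir sim/
refnorm normalize --matrix sim/matrix.csv --metadata sim/metadata.csv \
    --method is_dw+ref --out-dir norm/
refnorm diagnose --matrix sim/matrix.csv --after norm/normalized.csv \
    --metadata sim/metadata.csv --out-dir diag/
```

`diag/summary.json` then holds the RSD-reduction fraction and the PC1+PC2
percent-variance change, alongside the RSD tables, PCA scores and Ward
linkage exports.

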