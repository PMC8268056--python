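# Methods

## The prioritization model

The funnel treats candidate selection as pure threshold set-logic over
pre-normalized expression matrices — deliberately so: no moderated
statistics, no differential-expression model, no multiple-testing
machinery. Its core baseline is the **panel average**: for one dataset,
the mean of all panel-protease abundances pooled over genes × samples.
The panel standard deviation uses the n−1 (sample) denominator, chosen
for unbiasedness. Two overexpression calls are built on it:

- *above-average in every sample* (used for cell-line cohorts): the gene
  must strictly exceed the panel mean in each column. A dataset carrying
  replicate samples of one cell line therefore requires all replicates to
  clear the mean — the strictest reading of "above average in every cell
  line".
- *above-average dataset mean* (used for patient cohorts): the gene's
  mean over the selected samples must strictly exceed the panel mean
  computed over the same selection. By default only tumor samples enter,
  so adjacent normals neither dilute the panel mean nor the gene mean.
  Whether the per-sample-unanimous rule should instead be applied to
  patient cohorts is genuinely open; `patient_call_rule` exposes both.

The high-expression cutoff is `panel_mean + k · panel_sd` with k = 1.5 by
default; `k = 0` degrades to the plain above-average rule.

All internal values are linear-scale abundances. Fold changes are ratios
of group means, not means of per-pair ratios; cross-cohort aggregation is
the arithmetic mean of per-cohort fold changes (geometric mean available
via `fc_aggregation` — with ratios this close to 1–3 the two rarely
disagree on a 1.5 cutoff, but the choice is recorded in every report).

### Tie and boundary rules

- Every "above average" comparison is strict (`>`): a gene exactly at the
  panel mean is never called. This matters only for degenerate constant
  matrices but is the documented contract.
- The fold-change cutoff is inclusive (`>=`): a gene averaging exactly
  1.5-fold passes, since "1.5 times higher" describes the survivors.
- The leukocyte/organ screens are strict (`< low_ratio_threshold`) and
  must pass in **every** leukocyte dataset and **every** organ; a gene
  absent from any required dataset cannot be verified low and fails the
  stage (the absence is logged).
- k-of-n consensus counts membership in ≥ k callsets; k = n is the
  intersection, k = 1 the union, and survivors shrink monotonically in k.
- Final ranking: descending mean fold change, ties broken alphabetically.

### Cross-platform comparisons

Comparisons within one dataset (overexpression calls, tumor/normal fold
change, the leukocyte screen) never cross platforms, which makes them
invariant to any per-dataset scale factor. The leukocyte screen is
implemented as a within-dataset ratio — each leukocyte dataset must carry
tumor-group reference profiles on its own platform — because a raw
cross-platform ratio would confound platform scale with biology. Only the
organ screen crosses platforms; there both sides are first divided by the
dataset's mean abundance of a housekeeping normalizer (ACTB by default),
which cancels multiplicative platform effects exactly. These invariances
are contract, not accident: the test suite rescales whole datasets by
random constants and requires identical survivor sets, with panel
statistics scaling exactly.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `allowed_localizations` | extracellular, transmembrane, secreted, plasma_membrane | terms counted as surface-accessible; a multi-localized protease passes if *any* term is allowed, keeping transmembrane proteases with intracellular domains |
| `k_of_n` | 5 | patient cohorts that must call the gene (of n configured) |
| `fc_cutoff` | 1.5 | minimum mean tumor/adjacent-normal ratio (linear) |
| `sd_multiplier` | 1.5 | k in the high-expression cutoff |
| `low_ratio_threshold` | 0.5 | "low in leukocytes/organs" bound; no published threshold exists for "low", so this is an explicit package choice — vary it in sensitivity analyses |
| `normalizer_gene` | ACTB | housekeeping symbol for cross-platform normalization |
| `fc_aggregation` | arithmetic | cross-cohort fold-change average |
| `patient_call_rule` | dataset_mean | per-cohort summary vs per-sample-unanimous call |

The localization vocabulary is a fixed ten-term controlled set; mapping a
real annotation source (e.g. Gene Ontology cellular-component terms) onto
it is the caller's responsibility and the single most consequential
configuration decision, since it defines the panel over which every
average is computed.

## The synthetic-study generator

`generate_study` emulates the structure of a multi-repository expression
meta-analysis: 3 cell-line cohorts, 6 patient cohorts (3 with paired
adjacent normals), 4 leukocyte cohorts (each with same-platform tumor
reference samples, mirroring within-platform comparison practice) and one
organ cohort with 8 organs, several donors per organ. Defaults: 60
proteases (45% surface-accessible) plus 40 non-protease background genes,
8 samples per dataset, donors per organ = half of that.

Abundance model, per value:

```
x(gene, sample) = baseline(gene) · effect(gene, group) · scale(dataset) · 2^ε,
ε ~ N(0, noise_sigma²)
```

- `baseline` ~ 2^N(6, 1.5²) — typical linear microarray intensities with
  a realistic log-normal spread.
- `effect` plants the truth multiplicatively on group means: tumor and
  cell-line samples get `tumor_fc`, leukocyte samples
  `tumor_fc · leukocyte_ratio`, organ samples `tumor_fc · organ_ratio`,
  adjacent normals 1. True ratios are therefore exact in expectation and
  exactly recovered at σ = 0.
- Planted tumor-enriched genes sit 2.5 SD above the baseline log2 mean,
  so in the noiseless limit they clear every above-average call by
  construction; unplanted genes have identical group means and die at the
  fold-change stage (ratio exactly 1). The funnel's noiseless survivor
  set consequently equals the planted should-pass set — the oracle
  equivalence the acceptance tests pin.
- `scale(dataset)` ~ Uniform(0.5, 2) models platform differences and must
  never change funnel output.
- The housekeeping normalizer (ACTB) has a constant high baseline and
  receives the platform scale but no per-sample noise: housekeeping genes
  are selected for stability, and the generator contract is that the
  normalizer is a stable reference.
- Multiplicative log-normal noise in log2 units (default σ = 0.5) is the
  standard microarray error structure.

Consistency of each planted gene's `should_pass_funnel` flag with the
paired pipeline thresholds is checked at generation time, so an
infeasible configuration fails before any test runs. Replicate r of a
recovery experiment uses seed `seed + r`, making every reported number
reproducible from the base seed.

The generator does **not** model gene–gene correlation, batch effects
within a dataset, probe-level artifacts, compositional effects or real
cohort sizes (real cell-line panels have ~100 samples; we default to 8
per dataset to keep experiments fast at desk scale). Passing tests
therefore demonstrate the cascade's logic, its invariances and its noise
robustness under this idealized error model — not performance on real
repository data, where normalization quality and annotation mapping
dominate.

## Assay arithmetic

Cleavage activity is fold change over a **time-matched no-enzyme
control**, not over the t = 0 baseline:
`fold(t) = (S(t) − B(t)) / (C(t) − B(t))`, with the buffer blank B
optional (whether to subtract one is assay-dependent; both paths are
exposed). Replicate wells sharing a condition are averaged pointwise
before the ratio. Time-to-maximum-cleavage is the earliest *measured*
time at which the fold curve reaches a fraction (default 0.95) of its
maximum — no interpolation, because plate-reader grids are coarse
(15 min) and threshold times should be reported on the grid. Dose
monotonicity is a non-strict check at one time point. Entrapment
efficiency is the loaded/initial drug-mass fraction with domain checks.
Kinetic model fitting (Michaelis–Menten, IC50 dose-response) is out of
scope.

## Numerical and I/O choices

- Canonical scale is linear; `scale_declared="log2"` input is converted
  by `2^x` on ingest. Negative linear values, NaNs and unmatched sample
  ids are hard errors (no imputation).
- Duplicate gene rows (microarray probes) collapse by the max-mean rule
  with first-occurrence tie-break, a common array convention.
- Linear TSV round-trips are bit-identical (`repr` float formatting on
  write, round-trip float parsing on read), and reports serialize with
  sorted keys so identical runs produce byte-identical files.
- Problem sizes in tests and the acceptance script: studies of ≤ 101
  genes × ≤ 14 datasets × ≤ 8 samples, 20 noiseless and 50 stochastic
  replicates — small enough to re-run in seconds, large enough that every
  funnel stage eliminates something.

## Known limitations

- The funnel's conclusions inherit whatever normalization the input
  matrices carry; the package deliberately performs no between-array
  normalization.
- "Low in leukocytes/organs" has no principled threshold; 0.5 is a
  default to be stress-tested, not a finding.
- The leukocyte screen requires tumor reference samples on each leukocyte
  platform; datasets lacking them cannot be screened within-platform and
  would need the housekeeping-normalized route instead.
- With `patient_call_rule="all_samples"` and heterogeneous cohorts the
  patient stage becomes very conservative; the default per-cohort-mean
  rule is the recommended reading.
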