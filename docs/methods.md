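# Methods

## Model and assumptions

`refval` treats reference-gene discovery as deterministic per-gene filtering,
not as a statistical stability model. The unit of analysis is a gene's
vector of mean TPM values across k ≥ 2 conditions; all variability
statistics are computed on the log₂ scale, where fold changes are additive
and a multiplicative library effect shifts every gene's mean by a constant
without touching its SD (the suite asserts this numerically).

The implicit assumptions are: (i) TPM normalization has already made
libraries comparable, so no further normalization is applied; (ii) replicate
structure is nuisance — replicates are collapsed to unweighted arithmetic
condition means (by this package for Salmon input, upstream for table
input) before any filter runs, so the expression filter applies to the
*mean*: a condition whose replicates average above zero passes even if one
replicate is zero; (iii) stability across condition means is the quantity of
interest — within-condition variance is deliberately ignored.

Selection is a cascade: filters run in a fixed order and a gene is charged
to the first filter it fails. The survivor counts in `CascadeReport` are
therefore order-dependent even though final membership is not (each filter
is a pure per-gene predicate, which is also why the brute-force oracle in
the tests can check membership filter-by-filter without the cascade).

## Parameters

| parameter | scale | default | role |
|---|---|---|---|
| `min_tpm` | TPM | 0 | expression floor, strict, both paths |
| `sd_max` | log₂TPM | 1 | stability ceiling, reference path |
| `dev_max` | log₂TPM | 2 | single-library outlier ceiling, reference path |
| `mean_min` | log₂TPM | 5 | expression-level floor (TPM ≈ 32), both paths |
| `cv_max` | dimensionless | 0.2 | relative-stability ceiling, reference path |
| `sd_min` | log₂TPM | 1 | variability floor, validation path |
| `ddof` | — | 1 | SD divisor: 1 → n−1 (sample), 0 → n |

All six inequalities are strict exactly as specified, so boundary values
fail — a constant gene at TPM 32 (mean log₂ exactly 5) is *not* a reference
candidate, and a gene with sample SD exactly 1 appears on neither path.
Every cutoff is adjustable; none is locked. The SD divisor is exposed
because tabular-analysis toolchains default to n−1 while the n convention
is also seen in the field; n−1 is the default here.

## Numerical and design choices

* **CV guard.** CV = σ/x̄ of log₂ values is only meaningful for x̄ > 0.
  With the default `mean_min` = 5 the mean floor runs first and the CV
  stage never sees a non-positive mean; if a user sets `mean_min` ≤ 0,
  genes with x̄ ≤ 0 reaching the CV stage are excluded with a warning
  rather than compared through a sign-flipped ratio.
* **Tie-break.** Equal CV (reference) or SD (validation) ties are broken by
  gene identifier, lexicographically — output order is a pure function of
  the input.
* **Degenerate inputs.** An empty matrix yields empty tables and a zeroed
  report, not an error; a single-condition matrix, duplicate or blank gene
  identifiers, negative, non-finite or non-numeric values are rejected at
  load with the offending gene/column named. Numeric parsing accepts '.'
  decimals only; locale comma-decimals are rejected for cross-platform
  determinism.
* **Output formatting.** Ranked tables print SD and CV to 7 decimal places
  and the log₂TPM average to 4 (both configurable); the validation table's
  CV cell holds the literal text "Not calculated". Re-reading a written
  table reproduces records to that printed precision.
* **Estimator surface.** The cascades are scikit-learn selectors
  (`SelectorMixin`): `fit` takes conditions × genes, `get_support`/
  `transform` reduce to the candidate genes, and all cutoffs are
  constructor parameters, so the selectors compose with sklearn pipelines
  and `clone`. The functional API (`select_reference_candidates`,
  `analyze`, …) wraps them.

## Synthetic benchmark generator

The generator emulates a quantification table with a known answer, not a
sequencing experiment. Defaults: 50,000 genes × 6 libraries, values in
[0.01, 1000] (no zeros, so the benchmark needs no pre-processing by tools
that reject zero expression), in three groups — 49,500 genes that fail at
least the CV filter, 400 that pass every reference filter, and 100 stable
low-expression genes failing only the expression-level floor. Variant 2
additionally constrains the third group to CV < 0.05, the adversarial case
separating filtering from rank-only stability scoring.

Construction is rejection sampling, vectorised: each candidate gene draws a
base log₂ level uniformly from a group-specific window (pass-all: (5.3,
log₂1000 − 0.2); stable-low: (0.5, 4.7); fail-group: the full value range)
and a per-gene jitter scale (pass-all: 0.02–0.8; stable-low: 0.01–0.15, or
0.004–0.04 under variant 2; fail-group: 1.2–4.0), adds i.i.d. N(0, scale)
jitter per library, clips to the value range, and is kept only if the
independent classifier confirms the intended group (plus the CV < 0.05
check for variant-2 stable-low genes). Windows and scales were chosen once
to cover each group's constraint region with margin — e.g. the stable-low
window keeps means safely inside (0, 5) so CV stays positive and
well-defined — and acceptance is enforced by the classifier, not by the
draw law, so the emitted quotas are exact by construction. Sampling fails
loudly (`GenerationError`) after `attempt_factor × quota` draws (default
1000×) rather than looping on an infeasible cutoff combination. Group rows
are shuffled together before gene1…geneN names are assigned, so position
carries no label information; one seed drives every draw and identical
seeds give bit-identical output.

What the benchmark does *not* emulate: read-count noise, library-size or
gene-length effects, replicate structure, zero inflation, or correlated
genes. Passing it shows the cascade implements its definition and separates
the constructed groups exactly; it says nothing about how informative the
cutoffs are on any real transcriptome.

## Problem sizes

The acceptance script runs both benchmark variants at the full
50,000 × 6 scale (a few seconds end to end); the test suite uses
desk-scale benchmarks (hundreds to thousands of genes) plus 100+ random
matrices of ≤ 200 genes × 2–10 conditions cross-checked against a
pure-Python brute-force oracle.

## Known limitations

* Condition means are unweighted: replicate counts per condition do not
  weight the Salmon averaging.
* Genes present in some but not all `quant.sf` files are an error, not
  imputed as zero; transcript-to-gene aggregation is out of scope.
* The CV ranking compares log₂-scale ratios, so reference ranking is only
  meaningful above the expression floor; this is by design (candidates must
  be amplifiable) but means the tool cannot rank low-expression genes at
  all.
* No Cq-based stability statistics (geNorm M-values, NormFinder variance
  decomposition, BestKeeper, ΔCt) and no differential-expression testing;
  the tool screens candidates, wet-lab validation remains the arbiter.
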