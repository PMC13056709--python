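# Methods

## Model and design

The package analyzes paired-timepoint single-nucleus RNA-seq: a baseline
sample (day 0) and a cultured sample (day 14) from the same tissue, as raw
UMI count matrices with per-cell sample/timepoint metadata. The question it
answers is *how much of each cell type's distinguishing expression profile
survives the culture interval*, and its core output is a cell-type ×
cell-type Pearson matrix of log2 fold-change profiles.

The design is deliberately asymmetric. Day-0 profiles are each type against
the rest of day 0. Day-14 profiles are *substituted*: the type's day-14
cells become the target while the baseline stays the day-0 rest, with the
type's own day-0 counterpart removed from the baseline. Both rounds are
therefore expressed in the same frame of reference (the other day-0 types),
so the correlation between them isolates change *within* the type rather
than change of the background. A strict-inclusion variant (counterpart kept
in the baseline) is available via
`build_profiles(..., exclude_day0_counterpart=False)` for sensitivity
analysis; with the default composition it changes diagonal r by well under
0.01.

When several samples are analyzed jointly (e.g. multiple patients of the
same tissue class), their cells are pooled by raw concatenation *before*
any DE, controlled by the `aggregate` sample list.

## Exact negative-binomial test

For gene *g* and groups A, B with effective masses `nA`, `nB` (sums of
member size factors; size factor = depth / median depth), the test
conditions on the total count `T = sumA + sumB`. Under the null of equal
per-unit-mass expression,

```
P(a | T)  ∝  f_NB(a; nA·mu, phi/nA) · f_NB(T−a; nB·mu, phi/nB),   mu = T/(nA+nB)
```

with NB parameterized by mean and dispersion (variance = mu + phi·mu²).
The two-sided p-value is the minimum-likelihood sum: all outcomes whose
conditional probability does not exceed the observed one (with a 1+1e-12
relative slack absorbing floating-point ties). `phi = 0` makes both factors
Poisson and the conditional law exactly binomial(T, nA/(nA+nB)); the test
then reduces to the exact binomial two-sided test. `T = 0` returns p = 1 by
convention. Handling depth through the conditioning *masses* rather than by
rescaling counts keeps the enumeration on integers.

Per-gene dispersions are method-of-moments estimates on normalized counts
(pooled within-group variance, corrected by `mean(1/sf)` for the extra
variance normalization injects), clamped at 0 and shrunk toward the
across-gene mean dispersion with weight `w = s/(s + n_genes)`; the default
`s = n_genes` gives w = 1/2. This is a fixed, documented concretization of
sSeq-style shrinkage; exact numerical replication of any particular
browser tool's p-values is not promised (its shrinkage target and weight
are unpublished).

Genes enter testing only if their mean count across the dataset is ≥ 1
("average occurrence" floor). Inside `build_profiles` this floor is applied
once over *all* active cells of both timepoints, so every profile shares
one gene axis and the universe is guaranteed alignable; standalone `run_de`
applies it to the union of its two groups. BH correction runs across the
retained genes only.

### Numerics

- The scalar reference path (`exact_nb_test`) evaluates the full support
  with `gammaln`. The production batch path builds log-weights recursively
  (`w(a)/w(a−1)` is a ratio of four linear terms), anchoring each gene at
  its window start; a test verifies batch ≡ scalar to < 1e-9.
- Enumeration is restricted to conditional mean ± (16·sd + 64), always
  widened to include the observation. The conditional pmf is log-concave,
  so the excluded tail mass is ≲ 1e-13 and p-values are exact to that
  absolute scale.
- For per-group scaled dispersion below 1e-8 the NB pmf is evaluated in its
  Poisson limit: beyond that point the two are statistically
  indistinguishable, and the large-`r` gammaln differences would lose
  precision to cancellation.
- BH adjustment delegates to `statsmodels.stats.multitest.multipletests`
  (`fdr_bh`); an independent hand-rolled step-up serves as the test oracle.

## Gene universe and preservation matrix

The universe is the lexicographically sorted union of genes flagged
significant (BH-adjusted p < alpha) in at least one profile. Day-14
substituted profiles contribute by default (`include_day14=True`); whether
they should is not decidable from the published description of the design,
so both behaviours are implemented and the default documented. The matrix
entry `r[t14, t0]` is the Pearson correlation of the two log2FC vectors
over the *whole* universe, regardless of per-profile significance.
Constant vectors have no defined correlation and are reported as NaN, never
coerced to 0. Types below `min_cells` (default 20; the analysis tolerates
absent types) are skipped with a logged notice at each timepoint
independently, so the matrix may be rectangular.

## QC

Keep = (detected genes ≥ 600) ∧ (UMIs ≥ 1000) ∧ (mito% < 8) ∧ (below the
per-(sample, timepoint) upper Tukey fences on detected genes and UMIs).
Published threshold phrasing fixes the minima as inclusive and the mito
rule as strict. The 1.5×IQR rule's quartile convention and the metrics it
caps are not specified there; this package uses linear-interpolation
quartiles (`numpy.quantile` default) and caps the two metrics with no other
upper bound (mito already has one). Caps are computed on pre-filter values;
the operation is non-destructive (a `keep` flag), and re-running on a
filtered table can only shrink the kept set, never resurrect.

## Annotation

A deliberately compact stand-in for iterative reference annotators: collapse
a fine-label median-expression reference into broad classes by unweighted
column means, log-normalize the query (`ln(1 + scale·x/depth)`, scale 1e4),
and score each cell against each class by Spearman correlation over a
marker space (union over ordered class pairs of the top 50 genes by
reference log fold difference). One refinement round re-scores the two top
classes on their mutual markers only. Ties break to the earlier class in
reference order; constant vectors score 0. Rank correlation makes the
scores invariant to monotone transforms, so the scale mismatch between
log-normalized query and linear reference is immaterial. This module is a
declared simplification — it captures the discriminative core, not any
specific tool's numerics.

## Preranked GSEA

Genes are ranked by log2FC (descending, ties lexicographic by id — the
ranking statistic is a package choice, as is standard practice when only
thresholds are published). The classic weighted Kolmogorov–Smirnov running
sum (weight p = 1) gives the ES; because the input is a preranked list the
null is gene-label permutation: `n_perm` random same-size position sets.
NES is sign-stratified (ES divided by the mean |null ES| of matching sign;
if no same-sign nulls exist, the overall mean magnitude is used), and
`p_perm = (1 + #{same-sign null at least as extreme}) / (1 + #same-sign)`,
so p ≥ 1/(1+n_perm). BH runs across sets; a set passes at |NES| > 1.5 and
adjusted p < 0.05. All-zero-statistic rankings fall back to uniform hit
increments. Tied |extrema| resolve to the positive side in both the scalar
and vectorized paths.

## Synthetic generator

`generate_experiment` emulates the study conditions the statistics were
built for: K discrete types (default four broad brain classes), counts
NB(mean = L_c·exp(M[g,k]), dispersion phi) with per-cell lognormal depth
factors L (sd `libsize_sigma` = 0.35, mean 1), per-gene lognormal base
means (sd `gene_sigma` = 1, mean `base_mean` = 0.8 counts/gene/cell ≈ 1600
UMIs per 2000-gene cell — typical snRNA-seq depth), disjoint 50-gene marker
blocks elevated `marker_fold` = 8× in their type, and a mito subset (id
prefix `MT-`, fraction 0.02, with a mean-inflation knob for exercising the
8% filter). Day-14 log-means are day-0 log-means plus independent
N(0, drift_sd²) per (gene, type) — markers perturbed like any other gene,
which makes diagonal preservation r a smooth monotone function of drift.
Default drift_sd = 0.3 yields diagonals ≈ 0.93 and 0.5 yields ≈ 0.83
(both measured by `scripts/acceptance.py`), i.e. the moderate-to-strong
preservation regime one expects of healthy cultured tissue. Composition defaults use
fractions (0.40, 0.25, 0.20, 0.15) at day 0 and (0.20, 0.30, 0.28, 0.22)
at day 14 — the neuronal share halved, as observed in culture. Allocation
is largest-remainder rounding (exact composition; ties to earlier types)
with an optional multinomial mode. Outputs are a pure function of the
config including its seed.

What the generator does *not* emulate: ambient RNA, doublets, batch/patient
effects, mean-dispersion trends, or correlated gene programs. Passing tests
therefore demonstrate correctness of the statistics under a clean NB world
with known truth — calibration and recovery — not robustness to every
artifact of real tissue data.

## Problem sizes and test design

Acceptance-level checks run at the design scale of the synthetic study
conditions: 2000 genes, 4 types, 3000+3000 cells for drift recovery (drift
∈ {0, 0.2, 0.5, 1.0} × 5 seeds), 2000-gene null simulations (3 seeds) for
type-I calibration, 1000–1500 cells for substitution identity and
annotation recovery, 1000 permutations for the GSEA spike-in. Smaller unit
fixtures (hundreds of genes/cells) cover the individual operations and
their oracles: brute-force conditional enumeration for the exact test,
independent step-up for BH, hand-stepped running sums for ES, group-by
means for reference collapse, and direct predicate evaluation for QC.

## Known limitations

- The exact test enumerates integer totals; extremely deep genes make the
  window wide and the test slower (linear in windowed support).
- Dispersion shrinkage toward a single global mean ignores mean-dispersion
  trends; under strong trends p-values for extreme-mean genes will be
  mildly mis-calibrated.
- The annotator labels cells independently; it has no cluster prior and no
  "unassigned" rejection threshold.
- Composition tables are descriptive; no statistical test of proportion
  shifts is performed.
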