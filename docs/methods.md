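# Methods

## Problem and model

Bulk RNA-seq of brain tissue measures a mixture: each sample's expression
is, to first order, a proportion-weighted combination of the expression
programs of its constituent cell types. cortexmix estimates those
proportions for the four major brain cell classes — neurons, astrocytes,
oligodendrocytes, microglia — anchored by marker genes, i.e. genes
expressed predominantly in one class.

All engines operate on linear-space, non-negative abundances (TPM-like)
restricted to marker rows, and first rescale every sample to a common
total over the markers in use. This within-sample normalization makes all
three engines exactly invariant to per-sample scale factors (library size,
arbitrary rescaling) and is the only transformation applied before
fitting; expression is never log-transformed inside the engines, since
non-negative factorization requires the linear scale. Estimates are
relative mRNA fractions: a cell type with larger per-cell mRNA content is
over-represented relative to its cell-count fraction, and no cell-size
correction is attempted.

### Semi-supervised NMF (`ssnmf`, primary engine)

The marker-row bulk matrix V (m markers × s samples) is factorized as
V ≈ W·H under the Frobenius loss with Lee–Seung multiplicative updates.
The semi-supervision is a hard structural constraint on the basis: for a
marker of cell type k, the entries of its row of W in all columns ≠ k are
exactly zero, enforced by projection after every W update (entries
initialized at zero also remain zero under multiplicative updates, so the
projection never increases the objective and the residual trace is
non-increasing). W is initialized from the reference panel's per-type
marker means, column-normalized to unit sum so the basis and the
normalized data share a scale; H starts uniform. Iteration stops when the
relative change of the residual falls below `tol` (default 1e-6), when the
residual falls below 1e-10 of ‖V‖ (exact fits), or at `max_iter` (default
2000). The default initialization is deterministic; seeded random restarts
of H are available but off by default. Output proportions are the columns
of H renormalized to the simplex.

Because every marker row is constrained, W is block diagonal and a
one-column deconvolution converges in a few iterations to the per-type
least-squares projection onto the panel marker means. This makes the
engine fast and fully reproducible, and it has a consequence spelled out
under *Limitations*.

### Digital-sorting linear estimation (`dsa`)

Uses marker identities only. With M[j,k] the mean marker expression of
type k in sample j, the model M[j,k] = s_k·p[j,k] with a shared per-type
scale and row sums Σ_k p[j,k] = 1 gives the linear system M·x = 1 for
x_k = 1/s_k, solved by non-negative least squares across samples;
proportions are M·x renormalized per row. The system needs as many
linearly independent samples as cell types; rank-deficient designs raise
an error suggesting more samples or more specific markers.

### Marker-mean relative index (`mean_profile`)

Each marker row is scaled to unit maximum across samples (balancing
magnitudes between high- and low-expressed markers); a sample's estimate
for a type is the mean of that type's scaled markers, renormalized per
sample. The result is flagged `relative_index`: it orders samples
correctly but is a relative signal, not an absolute mRNA fraction, unless
the sample set contains near-pure extremes for every type.

## Reference-panel curation

Purified reference samples from human and mouse experiments are
harmonized by case-insensitive gene-symbol identity (uppercase canonical
namespace, duplicates collapsed by sum; no orthology tables — adequate for
the well-known marker namespace, inadequate for transcriptome-wide use).
Candidate markers are kept when their own-type mean expression is at least
`min_specificity` (default 2) times their highest other-type mean. Panel
quality is inspected with a PCA of log1p-transformed, within-sample
normalized marker expression and the mean silhouette of the cell-type
labels in the top-2 component space.

Curation runs leave-one-out cross-validation: each sample is held out,
deconvolved as a one-column bulk against the remaining panel, and its
predicted self-type proportion recorded. Samples are kept only when that
proportion is strictly greater than the threshold (default 0.80);
removals within a round are simultaneous, hold-out order is sample-ID
lexicographic, and rounds repeat until a fixpoint or `max_rounds`
(default 10; a single pass is `max_rounds=1`). Removal that would leave a
cell type with fewer than two samples stops curation with the partial
report attached to the error.

## Chimeric validation and robustness

Accuracy is scored on synthetic admixtures with known composition. The
default design holds 32 proportion vectors inside the per-type ranges
(neurons 2–36%, astrocytes 22–76%, oligodendrocytes 6–62%, microglia
1–5%) repeated 720 times (23,040 tasks) at 400,000 reads per library.
Exact vectors can be supplied as a file and are validated against the
ranges; otherwise a seeded Halton low-discrepancy draw inside the ranges,
renormalized to the simplex and re-checked, is used and labeled
"generated" in the design. Donor selection rotates deterministically: a
seeded permutation per type, indexed by (repeat + distribution) modulo the
donor count, so the full design is reproducible without storing
assignments.

Libraries are assembled in two modes. Expression mode (the desk-scale
default) mixes donor expression profiles linearly at the design
proportions. Read mode allocates per-type read counts by largest-remainder
rounding — counts sum exactly to the read total for every proportion
vector — and samples reads without replacement from donor read pools
(with replacement, with a warning, when a pool is smaller than its
allocation). Each task is deconvolved with a reference panel excluding the
contributing donors (hold-out), and the pooled RMSE over all proportion
entries is reported.

Gene-dropout robustness re-runs the validation once per marker gene with
that gene removed and reports the RMSE between full-panel and dropped-gene
estimates (genes that are the sole marker of their type are skipped with
a warning). LOOCV accuracy reports each purified sample's predicted
self-type proportion plus the RMSE against one-hot label vectors.

## Association stage

Proportions are analyzed on their natural scale, so effects are
differences in proportion units. Per cell type, ordinary least squares
regresses the proportion on a predictor (disease status, an ordinal
severity score, a genotype group) plus covariates such as RIN, PMI, age at
death, and batch; categorical predictors are coded against a control-like
reference level (overridable), so "case vs control" effects carry the
expected sign. Collinear designs raise an error naming the aliased
columns. For multi-region or family-clustered designs, a linear mixed
model adds a random intercept per donor or family (random slopes
optional); Wald p-values are used throughout, with no multiplicity
correction by default and a Benjamini–Hochberg helper available.
Covariate selection is bidirectional stepwise search minimizing AIC from
the full model, deterministic given the data. Power is estimated by Monte
Carlo — the rejection fraction of the OLS group contrast over simulated
datasets whose group means differ by the effect under Gaussian noise —
which matches the closed-form noncentral-t power for the two-group case.
Meta-analysis is fixed-effect inverse-variance pooling (SE of k identical
studies shrinks by exactly 1/√k).

## Synthetic data: what it emulates and what it does not

The generator produces the three inputs the pipeline consumes, all driven
by one integer seed fanned out per stage via
`SeedSequence([seed, crc32(label), …])`, so every stage is independently
and bit-exactly reproducible.

* **Purified reference profiles.** A marker of type k has expected
  expression `fold × baseline` in its own type (default fold 20, baseline
  10) and `baseline` elsewhere; background genes sit at baseline
  everywhere. Every entry is multiplied by log-normal noise
  exp(N(0, σ²)) with σ = 0.2 by default — multiplicative log-normal noise
  matches the dispersion of RNA-seq abundances, and the nominal value is
  the noise-free median. No published variance estimates exist for
  purified brain reference samples, so these defaults are stated choices,
  not fitted values.
* **Read pools.** Per sample, reads are drawn multinomially with
  probability proportional to expression; pools hold exactly `pool_size`
  reads.
* **Case/control cohorts.** Control mean proportions default to neuron
  0.35, astrocyte 0.30, oligodendrocyte 0.30, microglia 0.05 (inside the
  chimeric admixture ranges). Planted effects shift the case means of the
  named types (defaults: neuron −0.17, astrocyte +0.23, magnitudes typical
  of AD temporal-cortex contrasts); the complement is absorbed by the
  unshifted types in proportion to their control means, so each planted
  shift is realized exactly, and a shift that would push a mean outside
  [0, 1] is rejected before sampling. Subject-level proportions are
  truncated-Gaussian perturbations around the group mean (sd 0.05),
  clipped and renormalized — chosen over a Dirichlet because the effect
  size is then controlled directly on the scale the association models
  estimate. Bulk columns are proportion-weighted combinations of the
  type-mean profiles under the same multiplicative noise, and technical
  covariates (RIN, PMI, age, batch) are drawn independently of status.

Not emulated: splicing/isoform structure, GC or positional bias,
alignment artifacts, cell-size differences, covariate–status confounding,
or cross-species orthology beyond symbol identity. Passing the synthetic
benchmarks therefore demonstrates the correctness and stability of the
estimation machinery under the stated noise model, not performance on any
real cohort.

## Numerical choices and edge cases

Engines reject negative inputs, samples with zero total marker
expression, and cell types with no marker present, naming the offender.
Proportion rows are checked to sum to 1 within 1e-6 (1e-9 for generated
truths). Largest-remainder allocation breaks remainder ties by index
order. The grid and least-squares cross-checks used in the tests
(exhaustive 0.01-step simplex scan, simplex-constrained least squares)
are implemented independently of the engines.

## Limitations

The hard zero constraint means marker cross-expression is excluded from
the basis by construction. Under the synthetic generator — where every
marker is expressed at `baseline` in off-target types — a purified
sample's predicted self-type proportion is capped at
`fold / (fold + K − 1)`, i.e. 20/23 ≈ 87% at the default fold 20 with
K = 4 types, and mixture estimates carry a bias of (1 − K·p)/(fold + K − 1)
per entry. Real curated marker panels have far larger effective fold
changes (often 10²–10³), which is why LOOCV self-recovery above 95% is
reported for panels built from real purified samples but is not attainable
in the default synthetic regime; raising `marker_fold_change` above ~60
reproduces that regime synthetically. The chimeric RMSE benchmark is
insensitive to this ceiling because admixture proportions are small-to-
moderate, where the bias largely cancels in the pooled error.

Mixed models use a random intercept by default; "random slopes and
intercepts" structures are exposed but not the default, and grouping
structures beyond one level (donor within family) are not modeled.
Mouse/human harmonization by symbol identity will silently miss genes
whose orthologs are named differently.
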