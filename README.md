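# cortexmix

Digital deconvolution of brain bulk RNA-seq: estimate the relative
proportions of neurons, astrocytes, oligodendrocytes, and microglia in
homogenized brain tissue from a curated reference panel of purified
cell-type samples, validate the estimates on chimeric admixtures of known
composition, and test whether the inferred proportions shift with disease.

The package is aimed at groups analyzing post-mortem brain cohorts (e.g.
Alzheimer's disease case/control studies) where single-cell sequencing of
frozen tissue is not an option, and at methodologists who want a fully
synthetic, seeded test bed for marker-based deconvolution.

## The model

Bulk expression is treated as a non-negative mixture of cell-type
signatures. Restricted to marker genes, the bulk matrix **V** (markers ×
samples) is factorized as

    V ≈ W H,   W ≥ 0, H ≥ 0

under the Frobenius loss with multiplicative updates, where the
semi-supervised constraint pins each column of **W** to a named cell type:
a marker of type *k* has exactly zero weight in every other column. **W**
is initialized from the per-type marker means of the reference panel, and
the columns of **H**, renormalized to the probability simplex, are the
estimated mRNA proportions. Two lighter engines share the same interface:
a digital-sorting linear estimator (non-negative least squares on per-type
marker means under the sum-to-one constraint) and a scaled marker-mean
relative index. Estimates are relative mRNA fractions; no cell-size
correction is applied.

The surrounding pipeline mirrors how such panels are built and trusted in
practice: leave-one-out cross-validated curation of the purified reference
samples (samples kept only when their predicted self-type composition
exceeds 0.80), accuracy scoring on chimeric admixtures via

    RMSE = sqrt( Σᵢ (ŷᵢ − yᵢ)² / n ),

single-gene dropout robustness, and linear / linear-mixed models relating
proportions to phenotype with stepwise (AIC) covariate selection,
Monte-Carlo power estimation, and fixed-effect meta-analysis.

## Worked example

`examples/` contains one short script per capability. Running
`python examples/03_chimeric_validation.py` prints:

```
chimeric design: 32 distributions x 45 repeats = 1440 admixture tasks
pooled RMSE vs known proportions: 0.0327 (a well-curated panel should stay at or below 0.08)
single-gene dropout over 200 markers: mean RMSE delta 0.0020, sd 0.0009
A small mean delta means no individual marker gene drives the estimated cellular composition.
```

Each of the 1440 tasks mixes purified donor profiles at known proportions
drawn inside the admixture ranges (neurons 2–36%, astrocytes 22–76%,
oligodendrocytes 6–62%, microglia 1–5%), deconvolves the mixture with a
panel that excludes the contributing donors, and scores the error against
the known truth; 0.0327 means estimates are typically within about three
percentage points per cell type. The dropout scan re-runs the benchmark
200 times with one marker removed at a time — the 0.002 mean shift shows
the panel is redundant rather than driven by any single gene.

`python examples/04_association.py` deconvolves two simulated case/control
cohorts with a planted neuronal decrease and prints the fitted effects and
their meta-analysis:

```
study 1: neuron effect (case vs control) beta=-0.153, SE=0.007, p=2.74e-40, n=120
study 2: neuron effect (case vs control) beta=-0.138, SE=0.007, p=1.77e-38, n=120
meta-analysis: beta=-0.145, SE=0.005, p=1.44e-175
```

A thin CLI wraps the same stages
(`cortexmix simulate|deconvolve|validate|associate|run`); see
`cortexmix --help`.

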