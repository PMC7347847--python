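# Methods

This note documents the models, defaults and numerical choices behind
`gep_panel`, and what the synthetic cohorts do and do not establish about
real data.

## Data model

A study is a log2 probe × sample matrix with a probe → gene annotation and
per-sample group (DA/AA/GBM) and batch (cohort of origin) labels, exchanged
as three TSV files. Multiple probes per gene are kept throughout — panel
collapse happens only after differential testing. Probes without a gene
symbol and control probes (ids prefixed `AFFX`) are dropped at load with a
logged count. Missing values are rejected by default; per-probe mean
imputation is available behind a flag because the upstream normalization
(RMA) normally leaves none.

## Synthetic cohorts

`simulate_study` draws probe values as

  gene group mean + batch shift γ + batch scale δ · ε,  ε ~ N(0, sd²)

with the differential profile defaulting to the 27-gene discriminatory
panel (per-group mean log2 expression for each gene), a flat non-differential
background at log2 intensity 7, and cohort compositions mirroring the study
design: 19/28/108 (DA/AA/GBM) for discovery and 14/24/75 for validation.
Each gene gets 1–3 probes (uniform); probe layout and, in the
heteroscedastic mode, per-probe noise sd are drawn from a separate
`probe_layout_seed` so that discovery and validation cohorts can share one
"platform". Batch effects are location–scale per probe row — exactly the
family the empirical-Bayes adjustment models — drawn per batch from
N(shift_mean, shift_sd) and exp N(log_scale_mean, log_scale_sd).

Defaults and why:

- `noise_sd = 0.5` log2 units. The published profile reports means without
  recoverable dispersions, so this is a package choice: 0.5 is a typical
  residual sd for RMA-processed arrays and leaves the smallest planted gap
  (2.02 log2 units) at four noise sd — separable but not trivial.
  `noise_sd = 0` is allowed to exercise exact-recovery limits.
- `n_background_genes = 973` (≈2 000 probes in total). Full-platform scale
  (44 723 probes) adds nothing to correctness checks; the CUR stage still
  performs a genuine 2 040 → 1 000 selection.
- Heteroscedastic option: per-probe variances from a scaled inverse
  chi-square (df 4), the conjugate model the moderated t assumes; used to
  exercise variance shrinkage.

What the simulations do **not** emulate: probe-level cross-hybridization,
intensity-dependent variance, correlated gene modules beyond the planted
profile, annotation errors, or covariate structure (age/sex). Passing tests
therefore demonstrate algorithmic correctness and statistical calibration
under the stated model, not clinical performance on real cohorts.

## Batch adjustment

Parametric empirical Bayes (the standard location–scale ComBat model):
standardize each probe against its grand mean (batch-size-weighted) and
pooled variance; per batch estimate location γ̂ and scale δ̂²; shrink with a
normal prior on γ and inverse-gamma prior on δ² whose hyperparameters are
moment-fitted across probes; iterate the coupled posterior updates until
max |Δγ*| < 1e-6 (at most 100 iterations); back-transform. Group labels are
**not** included as covariates by default — group and cohort are partially
confounded when series are pooled, and protecting the group signal risks
re-introducing batch structure; `protect_groups=True` adds group dummies to
the standardization model for the alternative reading. Probes with zero
pooled variance cannot be standardized and are set to their grand mean with
a warning. Shrinkage is monotone by construction (γ* is a convex
combination of γ̂ and the prior mean), and in the noiseless pure-location
case the adjustment is exact and idempotent.

## CUR leverage selection

Leverage of probe j is (1/R) Σ_{r≤R} v_jr² over the right singular vectors
of the per-probe-centered matrix, so Σⱼ lⱼ = 1 and lⱼ is probe j's share of
the retained variability. The "all variability" rank policy is
operationalized as the smallest R whose cumulative variance fraction
reaches 1 − 1e-8 (the numerical rank); a variance-fraction override (e.g.
`fraction:0.95`) sharpens the contrast between dominant and background
probes, since at full rank leverage flattens toward 1/J. Centering is on by
default so leverage measures variability rather than mean intensity;
`center=False` gives the uncentered reading. Ties in the top-k selection
break lexicographically by probe id for determinism.

## Differential expression

Two-sample pooled-variance t per probe; moderated by default: (d₀, s₀²) are
fitted by the method of moments on log sample variances (trigamma
inversion), giving posterior variances s̃² = (d₀s₀² + d·s²)/(d₀ + d) and
d₀ + d degrees of freedom. d₀ = ∞ (spread no wider than chi-square noise)
falls back to a fully shrunk z-like test; d₀ = 0 reproduces the ordinary t
exactly. Probes with zero pooled variance get p = 0 when the means differ
and p = 1 otherwise — the correct degenerate limit, which also makes the
noiseless pipeline exact. BH adjustment is applied within each comparison
(not pooled across the three), matching per-comparison significance counts.
Fold change is FC = 2^|Δ of log2 group means|, so FC ≥ 4 ⇔ |Δlog2| ≥ 2; the
panel keeps genes with p_adj < α and FC ≥ fc_min, unioned over comparisons,
with each gene represented by its maximum-FC probe (all passing probes are
recorded). Selection is monotone in both thresholds.

## NMF consensus clustering

Frobenius objective with Lee–Seung multiplicative updates on the raw log2
panel submatrix (nonnegative already; no shift or scaling by default).
Numerical choices: W is updated before H each iteration; factors are
initialized half-normal, |N(0, 1)|·sqrt(mean(X)/K) — during development the
flat-uniform init occasionally converged to spurious stationary points with
an essentially identical objective but a wrong sample partition, which the
half-normal init eliminated across seeds; stopping at relative objective
decrease < 1e-6 or 2 000 iterations; W columns normalized to unit sum (the
scale moves into H), which pins the scaling indeterminacy. The objective
trace is checked non-increasing on every run. Samples are assigned to the
argmax membership coefficient; ties take the lower cluster index.

Consensus over 30 seeded restarts per rank (15 in the batched acceptance
runs, which repeat the procedure twenty times): co-clustering frequencies →
average-linkage tree on 1 − consensus → cophenetic correlation; recommended
K maximizes the cophenetic correlation with ties to the smaller K. A
degenerate consensus whose pairwise dissimilarities are all identical is
assigned cophenetic 1 (the tree represents it perfectly).

## Canonical biplot and LDA

Both stages share one eigenstructure: B·u = λ·S_W·u with B the
between-group scatter and S_W the pooled within covariance (divisor n − G).
Axes are S_W-orthonormal, so canonical scores have identity within-group
covariance and the between-group scatter along axis a equals λ_a; with
three groups there are two nontrivial axes. Gene markers default to
structure correlations (gene ↔ canonical variate correlations), which are
bounded and stable when the panel size approaches the group sizes; raw
eigenvector weights are available behind a flag. 95% confidence radii for
group means (χ²₂-based, radius √(χ²₀.₉₅/n_g) in canonical units) are
emitted for plotting by the caller. A ridge of 1e-8·trace/J is added to S_W
only when its Cholesky factorization fails, and is logged.

LDA uses the same pooled covariance with empirical class priors (uniform
behind a flag) and a ridge of 1e-6·mean(diagonal) when the condition number
exceeds 1e10. Two validation modes: `transfer` (fit on discovery, classify
validation — the default) and `refit` (fit within the validation cohort),
since either protocol is defensible for a held-out accuracy figure.

## Pipeline

`run_pipeline` executes adjust → CUR → differential expression → NMF →
biplot → LDA, writing every intermediate as TSV plus a JSON manifest with
parameters, seeds, per-stage dimensions and output hashes; reruns with the
same config are byte-identical. The batch stage is skipped (and recorded as
skipped) when only one batch is present. Any stage failure aborts with the
stage name and a machine-readable code; earlier outputs are retained.

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses: 20 seeded discovery-sized cohorts (155
samples, 27 panel genes) with 15-restart consensus NMF over K ∈ {2, 3, 4};
batch recovery on 500 probes × 2 batches × 200 samples; test calibration on
10 000 null genes (10 vs 10); and one noiseless ~2 000-probe pipeline pass
plus an sd-0.5 transfer-LDA validation (113 samples). These sizes keep each
quantity's Monte-Carlo error well below its acceptance margin.

## Known limitations

- Only the parametric ComBat variant is implemented (no nonparametric
  priors, reference batch, or count-data mode).
- NMF is Frobenius-only; the KL objective common in some consensus
  implementations is out of scope.
- The canonical biplot implements the MANOVA variant only, and marker
  scaling conventions differ across biplot software — coordinates are
  comparable up to per-axis scale.
- Real-cohort accuracy figures require the original multi-series microarray
  data and are outside what synthetic recovery can establish.
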