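# Methods

This note records the models implemented in `gxekit`, the defaults and why
they were chosen, and what the synthetic benchmarks do and do not show.

## The G×E encoding

For *s* environments the design matrix **E** is lower-triangular with an
all-ones first column (additive contrast) and, for *j* ≥ 2, a single 1 in
row *j* (indicator of environment *j*; environment 1 is the baseline). The
expanded genotype is the Kronecker product **E** ⊗ **G**, laid out
environment-major in rows and effect-class-major in columns (all *m*
additive columns, then one interactive block per non-baseline environment).
For two environments this is the familiar block matrix `[[G, 0], [G, G]]`.

Notation caveat: writing the product as **G** ⊗ **E** would, under the
standard convention, produce a different (permuted) matrix; the block
structure above is **E** ⊗ **G** and is what the package implements,
because the block layout — `[G; G]` additive, `[0; G]` interactive — is
what gives the columns their meaning.

Choices worth stating:

* **Row order** is environment-major (all individuals of the baseline
  environment first). This makes every block contiguous and directly
  testable; any consistent order would do.
* **Generalization to s > 2** uses one indicator column per non-baseline
  environment, so interactive effects are deviations *from the baseline
  environment*, and there are s − 1 of them per marker (one fewer than the
  number of environments, avoiding linear dependence with the additive
  column).
* **Phenotypes** are z-scored per environment (sample SD, n − 1) before
  stacking, so environments with different scales contribute equally.
  Normalization is idempotent and masked (missing) cells are excluded from
  the moments and stay masked.
* **The mean-value comparator** averages the *normalized* environment
  columns. Normalizing first puts the comparator on the same phenotype
  scale as the stacked vector, which keeps accuracy comparisons fair; this
  is a deliberate package choice where conventions differ.
* Monomorphic markers are kept (flagged) so column indices always align
  with the input; the scan skips them with p = 1.

## Phenotype simulation

`simulate.simulate(G, nqtn, h2, r, s, seed)`:

1. draw `nqtn` distinct QTN columns uniformly from the polymorphic markers;
2. draw per-QTN effect vectors i.i.d. from MVN(0, Σ) with Σ
   compound-symmetric: unit diagonal, all off-diagonals equal to the
   genetic correlation *r* (exchangeable environments; PSD requires
   r > −1/(s−1); r = 1 is special-cased to a broadcast draw so the columns
   are exactly equal);
3. genetic values g = G[:, qtn] · effects;
4. per environment, residuals are i.i.d. normal with SD
   `sqrt(var(g_e) · (1 − h2)/h2)`, where `var` is the *realized sample
   variance* — so the realized h² matches the target in expectation even at
   small n. Residuals are independent across environments; only the genetic
   correlation is manipulated.

All QTNs share a unit prior effect variance (no geometric decay), and the
default grid mirrors the benchmark design: h² and r each in
{0.2, 0.5, 0.8}, 20 QTNs, two environments.

## Mixed-model scan

Model per tested marker: `y = C b + x β + u + e`, `u ~ N(0, σ²_g K)`,
`e ~ N(0, σ²_e I)`, with C = intercept + 3 principal components of the full
expanded matrix, and K the VanRaden centered cross-product of the same
matrix (`K = ZZ'/c`, c = summed column variances, giving mean diagonal
exactly 1 on polymorphic data; eigenvalues floored at 1e−8).

Variance components are estimated once under the null (no marker) by
REML — eigendecompose K, profile out b and σ²_g, and optimize the ratio
δ = σ²_e/σ²_g over a 61-point log grid on [1e−5, 1e5] followed by bounded
refinement — and reused for every marker (P3D). This is the only way a
2m-column scan stays cheap; an exact per-marker re-estimation path exists
behind `p3d=False` and agrees with P3D to within 0.2 −log₁₀ units for ≥95%
of markers on the test fixtures.

Each marker is tested by GLS at fixed δ with a per-model re-estimated
scale: σ̂² = weighted RSS/(N − p), t = β̂/se(β̂), df = N − p (p counts all
fixed-effect columns including intercept and marker), two-sided p from the
t distribution. Re-estimating the scale per marker makes the σ²_g = 0 limit
*exactly* the OLS t-test, which anchors the implementation against
closed-form oracles.

Because the expanded matrix tests each original marker s times, the
`collapse_pvalues` step reduces the copies to one row per marker: the
minimum p (recording the winning effect class) or a Bonferroni-adjusted
minimum (×s, capped at 1). Power/FDR curves deduplicate the same way so the
expanded method's longer list cannot mechanically distort the rates.

Two calibration facts, measured on the synthetic fixtures and asserted in
the tests:

* Under a global null the scan is mildly conservative (empirical type-I
  ≈ 0.047 at nominal 0.05) because every tested marker also sits inside K
  (proximal contamination) — a property of building the kinship from all
  columns, not a bug.
* With r = 1 and independent residuals the *interactive* tests carry no
  signal and are likewise conservative, never inflated. In the fully
  degenerate case (identical environments sharing the same residual draws)
  the interaction contrast is noiseless and interactive p-values pile up
  near 1; the tests check each regime for its actual behavior.

## Power and FDR

At rank cut t of the p-sorted, deduplicated list: power = (true QTNs in the
top t)/m_r and fdr = (non-QTNs in the top t)/M_f, where m_r and M_f are the
total QTN and non-QTN marker counts. Dividing by M_f makes the second
quantity a false-positive *rate*, which is how it is conventionally printed
in this benchmarking literature; the usual false-discovery proportion
(FP/t) is available via `conventional=True`. Both curves are non-decreasing
and end at (1, 1). Ties in p are broken by (chromosome, position) with a
stable sort, so curves are deterministic. Replicate curves are averaged
pointwise with a sample-SD band.

## Genomic prediction

**GBLUP.** `y = 1μ + u + e`, `u ~ N(0, σ²_u K)` with K from the full
expanded matrix (a single kinship — not separate additive/interactive
variance components — matching the whole-kinship formulation of
marker-ridge tools). Variance components by REML or ML on the
eigendecomposition of the training-row kinship (1e−8·I floor), gEBVs for
all rows via the kinship cross-block:
`u = σ²_u K[:, train] V⁻¹ (y_train − μ)`. With `K = ZZ'/c` and
σ²_u = c·σ²_β this is algebraically identical to ridge regression on
centered markers with λ = σ²_e/σ²_β (verified to 1e−6 in the tests — the
module's primary correctness anchor). The ML variant exists because the
missing-environment experiments conventionally use it.

**Bayesian regressions.** Single-site Gibbs samplers over an intercept,
per-block marker effects, block/marker variances and the residual variance,
with the additive and interactive column blocks entered as two separate
model terms (so each gets its own variance):

| model | prior on marker effects |
| --- | --- |
| BRR | Gaussian, one variance per block (scaled-inv-χ²) |
| BayesA | Gaussian with marker-specific scaled-inv-χ² variances (scaled-t) |
| BayesB | point mass at 0 with fixed π, BayesA-style slab |
| BayesCπ | common slab variance, π ~ Beta posterior |
| BL | double-exponential via exponential scale mixture (inverse-Gaussian τ⁻² updates, Gamma λ² update) |

Hyper-prior scales follow the R²-rule (prior R² = 0.5 split evenly across
blocks, df = 5); π₀ = 0.5 where applicable. Chains are exactly reproducible
given (seed, niter, burnin, thin); default test chains are 1500/500 —
short chains are known to under-converge the variable-selection models
(BayesB, BayesCπ), so production analyses should use the conventional
12000/10000 via parameters. A clamped-variance mode (`fix_resid_var`,
`fix_block_var`) turns BRR into a conjugate ridge sampler, which is how the
sampler is validated against the closed-form ridge solution.

Prediction accuracy is the Pearson correlation between predicted gEBV and
the observed (normalized) phenotype on inference rows, overall and per
environment; undefined cases (fewer than 3 pairs, zero variance) are
flagged and excluded from averages.

## Cross-validation and missing environments

Folds are drawn at the *individual* level so all environment rows of an
individual move together. Three masking schemes on the stacked phenotype:
`standard`/`double_env_missing` mask every environment row of the inference
individuals (for s = 2 these coincide, differing only in reporting);
`single_env_missing` masks only the chosen environment, leaving the other
environment's phenotype in training — prediction of the masked cells then
borrows strength through the kinship between an individual's own rows.
Masked cells are set to NaN before any engine sees them (a sentinel-
poisoning test asserts no leakage). Methods under comparison (expanded
encoding, additive-only, interactive-only, mean) share fold assignments, so
differences are paired; `compare_methods` reports the mean, SD, relative
change versus the mean-value baseline and a paired t-test over per-rep
means.

The mean-value comparator cannot represent partial masking (it collapses
environments), so under `single_env_missing` its inference individuals are
masked entirely and it is scored against the same masked-environment cells
as the expanded method. `standardize=False` runs the whole CV on raw
(unstacked z-score skipped) phenotypes for assessing the effect of
standardization.

## What the synthetic benchmarks show — and what they do not

The generator draws **unlinked** markers (per-marker allele frequency
uniform on [maf_low, maf_high], genotypes Binomial(2, p)) with no linkage
disequilibrium, population structure, or relatedness. Consequences:

* Encoding, scan, curve and sampler correctness checks transfer directly —
  they are linear-algebra identities independent of the genotype law.
* Absolute prediction accuracies are pessimistic relative to real panels:
  with N training individuals and M independent markers, GBLUP accuracy
  against the phenotype is capped near sqrt(h²·N/(N + M)) (≈0.4 at
  N = 240, M = 1000, h² = 0.8), whereas real panels with extensive LD
  behave as if M were much smaller and routinely exceed 0.5 under standard
  masking. The benchmarks therefore read *orderings* (expanded vs mean,
  single- vs double-environment masking) rather than absolute levels,
  except in the single-environment scheme where the observed correlated
  phenotype lifts accuracy above 0.5 even without LD.
* Power levels likewise depend on the QTN effect distribution and marker
  independence; the Power-FDR *gap* between methods at low genetic
  correlation is the reproducible quantity.

Problem sizes used by the default test suite and the acceptance script
(n = 300, m = 1000 for GBLUP/GWAS benchmarks; m = 400 and 1500/500 chains
for the Bayesian comparison; 10–30 replicates) are the package's chosen
desk-scale conditions; directional comparisons are asserted with one-sided
2-standard-error bands.

## Numerical conventions

* Genotype missing values are imputed with the marker mode; major/minor
  ties at p = 0.5 break alphabetically; chromosomes sort naturally
  (2 before 10).
* Kinship eigenvalue floor 1e−8; GBLUP training-kinship ridge 1e−8·I.
* REML δ search on [1e−5, 1e5] (log grid + bounded refinement, xatol 1e−8).
* All randomness flows through `numpy.random.Generator` seeds; every
  simulation, fold split and chain is bit-reproducible given its seed.
* p-values are floored at the smallest positive float so they stay in
  (0, 1].

## Known limitations

* No dominance or epistasis encodings; environments are indicator-based
  (no continuous environmental covariates).
* No compressed MLM, multi-locus models (FarmCPU/BLINK), LD pruning, or
  genomic-control correction.
* GBLUP is single-kinship; no multi-trait unstructured-covariance variant,
  no RKHS kernels.
* VCF/BED input is out of scope (HapMap text and numeric matrices only).
* The Gibbs samplers store posterior means and hyper-parameter chains, not
  full effect chains; convergence diagnostics beyond trace export are the
  user's responsibility.
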