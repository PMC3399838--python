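# Methods

## Model and assumptions

The package treats a quantitative trait as the sum of very many locus
effects arranged along a continuous genome.  Numerically this is handled by
partitioning the genome into m bins and regressing the phenotype on one
covariate per bin.  Two covariate constructions are provided:

- **Unweighted bin average** Z̄_jk = (1/p_k) Σ_h Z_jhk.  Valid when (a)
  within-bin LD is high, so the markers move together, and (b) within-bin
  effects are homogeneous, so they do not cancel.  Both hold approximately in
  line-cross populations (F2/BC/DH) with bins up to a few tens of cM.
- **Adaptive weighted score** S_jk = (1/p_k) Σ_h w_hk Z_jhk with
  w_hk = b̂_hk / mean_h |b̂_hk|, where b̂ are single-marker least-squares
  estimates.  The signed weights align within-bin effect directions, which
  rescues the model when LD is low or absent.  Because the weights come from
  the data, they are re-estimated inside each cross-validation training fold
  by default (see *Weight and penalty policies*).

Genotypes are coded AA = +1, Aa = 0, aa = −1.  This is the only coding under
which the F2 indicator has Var(Z) = 1/2 and Cov(Z_h, Z_l) = (1 − 2 r_hl)/2;
the bin-average variance

    Var(Z̄) = (1/p²) [ p/2 + 2 Σ_{h<l} (1 − 2 r_hl)/2 ]

then interpolates between 1/2 (complete linkage) and 1/(2p) (no linkage),
which is why power degrades as unlinked markers are pooled.  The covariance
expression was re-derived from the two-gamete construction (each gamete
contributes Cov = (1 − 2r)/4; gametes are independent) and confirmed by
Monte Carlo before being used anywhere else.

## Fitting and testing

Bin effects are estimated by the Lasso objective
(1/2n)‖y − β₀ − Bγ‖² + λ‖γ‖₁ with an unpenalized intercept
(scikit-learn's coordinate descent).  The λ grid is fixed at 50
logarithmically spaced points from λ_max (the smallest penalty that zeroes
every effect) down four decades, so λ values are comparable across runs.
Inner cross-validation (default 10-fold, seeded) picks the grid point with
the smallest validation error; exact ties resolve to the larger, more
parsimonious λ.  During selection the coordinate descent runs at a loose
tolerance (1e-3, ≤ 1000 iterations) — ranking grid points does not need
full-precision solutions; the final fit uses tol 1e-5 with an extended
iteration budget and treats persistent non-convergence as a hard error.
λ = 0 falls back to ordinary least squares via `lstsq`.

σ̂² = RSS/(n − df) with df = (active-set size + 1), the standard
active-set heuristic for the Lasso's effective degrees of freedom.  Each
nonzero effect is tested with the marginal approximation
Var(γ̂_k) ≈ σ̂²/Σ_j (B_jk − B̄_k)², W_k = γ̂_k²/Var(γ̂_k),
LOD_k = W_k/(2 ln 10).  This is a single-covariate (F-test-style)
approximation, not the full sandwich covariance: it ignores between-bin
correlation and post-selection effects, so LOD values are indicative rather
than exactly calibrated.  Zero-effect bins carry no test, since the penalty
forces their estimation error to zero.  Null simulations (OLS mode, m = 20,
n = 400) keep the LOD ≥ 3 rate well below 1%.

## Cross-validation and predictability

k-fold CV (default k = 10) uses a seeded shuffle with fold sizes differing
by at most one.  The entire pipeline — scan, weights, scores, penalty
selection, fit — is wrapped in a builder that runs on each training fold, so
out-of-fold predictions are leakage-free by construction (verified by an
instrumentation test that corrupts held-out phenotypes and checks the
training-fold parameters are unchanged).  MSE is averaged over all n
held-out predictions; R² = 1 − MSE/var(y) uses the sample variance (ddof 1)
of the full phenotype vector, on the covariate-adjusted scale when
phenotypes were pre-adjusted.  R² is reported raw and clipped at zero (MSE
at or above var(y) means no predictability).  Bin-size scans share one fold
partition across all (size, mode) entries so their MSEs are paired, and the
profile minimum is reported with the one-standard-error band of its
fold-wise MSE, since adjacent bin sizes are often statistically
indistinguishable.

### Weight and penalty policies

Two deliberate departures from full nesting are available because they
correspond to the workflow the bin model is historically run with:

- `weights="whole-data"` estimates the adaptive weights once from the full
  sample before CV.  This leaks the held-out fold into the covariate
  construction and materially flatters the adaptive model's MSE in low-LD
  settings; `weights="fold"` (default) is the honest variant, under which
  the adaptive advantage persists but is smaller.
- `lam="pretune"` (the `scan_bin_sizes` default) selects λ once per
  (size, mode) on the whole sample and holds it fixed across outer folds —
  the "predetermined by cross-validation" usage of glmnet-style tools.
  `lam="cv"` re-selects λ inside every training fold.

Both choices are reported in output metadata so results are unambiguous.

## Synthetic data generator

Gametes are simulated as Markov walks along the genetic map: first allele
Bernoulli(1/2), subsequent alleles flipping with the Haldane recombination
fraction r(d) = (1 − e^(−2d/100))/2.  Haldane (no interference) was chosen
because it makes the walk Markov and matches recombination-fraction usage;
map functions with interference (e.g. Kosambi) are not implemented.  Two
independent gametes sum to the F2 genotype.  Phenotypes are
y = Σ a_k Z_k + Σ g_ab Z_a Z_b + ε with ε ~ N(0, σ²_ε); QTL are anchored to
the nearest marker (ties to the lower index).

Four preset architectures are provided (single 2400 cM chromosome unless
noted), with per-QTL effects calibrated **analytically**: effects are scaled
so that the quadratic form a'Ca (C the F2 covariance matrix over QTL
positions) equals the design's published aggregate variance.

| design | markers | spacing | QTL | target variance | σ²_ε default |
|---|---|---|---|---|---|
| I   oligogenic        | 120 001 | 0.02 cM | 20 + 20 epistatic pairs | 64.12 main, 26.52 epistatic | 20 (options 10/20/40/100) |
| II  clustered polygenic | 120 001 | 0.02 cM | 20 clusters × 500 | 81.94 total | 20 (options 10/20/50/100) |
| III uniform polygenic | 120 001 | 0.02 cM | 1000 (500 +, 500 −) | 81.94 total | same |
| IV  oligogenic, no LD | 120 001 | 100 cM | 20, no epistasis | 64.12 main | 25.59 |

Details and open choices:

- The individual oligogenic QTL effects are not published, only their
  aggregate variance; the preset uses a fixed palette (positions spread
  irregularly over the genome from a frozen generator, |effect|² ramping
  1:15, mixed signs) rescaled to the target.  Users may override `qtl`
  entirely.
- Epistatic pairs take equal magnitudes with Σ g²/4 = 26.52 (products of
  near-unlinked F2 loci have variance g²/4); the realized epistatic variance
  is reported empirically per dataset, not guaranteed analytically.
- Design IV's residual variance is likewise unpublished; it is set to
  89.71 − 64.12 = 25.59 so the expected phenotypic variance matches the
  published 89.71.
- Heritability uses h² = V_main/(V_main + V_epi + σ²_ε): epistatic variance
  counts as residual because only main effects are estimated.
- `scale` shrinks the marker count (and the polygenic QTL counts, with
  floors) while preserving the architecture: designs I–III keep the 2400 cM
  genome and widen the spacing; design IV keeps the 100 cM spacing — the
  absence of LD *is* its architecture — and shrinks the genome.  Oligogenic
  counts (20 QTL, 20 pairs) are never reduced.

The generator emulates F2 segregation (1:2:1), Haldane LD decay, additive
and pairwise-epistatic architectures, and Gaussian noise.  It does **not**
emulate genotyping error, missing-call patterns, allele-frequency spectra of
outbred panels, population structure, or dominance; passing tests therefore
demonstrate correctness of the method under idealized line-cross genetics,
not robustness to real-data artifacts.  Low-LD outbred panels are
approximated only through design IV's wide marker spacing.

## Preprocessing conventions

- MAF is computed from non-missing calls as f = (2·n_AA + n_Aa)/(2·n_calls);
  markers with min(f, 1−f) below the threshold (default 0.05) are removed,
  zero-call markers flagged separately.  The filter is idempotent.
- Missing genotypes are marker-mean imputed (values in [−1, 1]) before any
  binning, preserving column means and bin-average semantics.  This is the
  package's choice; how the original carcass-weight panel handled missing
  calls is not recorded.
- Covariate pre-adjustment regresses the trait on an intercept plus
  treatment-coded dummies (categoricals) and raw numerics; aliased columns
  are dropped with a warning; residuals (zero mean, orthogonal to the
  design) feed the downstream analysis with `adjusted=True`.

## Numerical and coordinate conventions

- Bins are half-open `[start, start + Δ)` anchored at position 0 per
  chromosome; the final bin is truncated at the chromosome end and the
  marker sitting exactly on the end joins it.  A marker on an interior
  boundary belongs to the right-hand bin.  Empty bins are kept (stable
  indexing across bin-size scans) but excluded from the design matrix.
- `log10_bp` bin sizes mean a width of 10^s base pairs on the physical map;
  `markers` means a fixed marker count per bin.
- Degenerate cases: all-zero scan bins get zero weights (threshold 1e-12 on
  the mean absolute estimate); constant covariate columns are dropped with a
  warning; σ̂² = 0 reports infinite Wald statistics with a flag.
- All randomness (gametes, noise, fold shuffles, λ selection) flows from
  explicit integer seeds; identical seeds give bitwise-identical outputs.

## Problem sizes used in the test suite

The behavioral test suite runs the published designs at reduced scale,
chosen once as the smallest sizes at which the phenomena are
Monte-Carlo-stable: bin-variance theory vs simulation at n = 20 000;
planted-effect recovery at n = 500, m = 50, 100 seeds; the no-LD contrast
on design IV at scale 0.02 (2401 markers, n = 500, 50 seeds, largest bin
10 000 cM, whole-sample weights as in the original workflow); the U-shaped
profile on design I at scale 0.02 (1 cM grid, n = 200, σ²_ε = 50, 50 seeds,
the published seven bin sizes).  Inner λ selection in these scans uses
5 folds.

## Known limitations

- The Wald/LOD test is a marginal approximation; no post-selection
  correction is attempted.
- Lasso is the only solver; Bayesian shrinkage, G-BLUP and grouped or
  elastic-net penalties are out of scope, as are bin×bin epistasis terms,
  data-driven bin boundaries, and crossover interference.
- Binary genotype containers (PLINK BED, VCF) are not read; input is
  delimited text.
- `theoretical_bin_variance` assumes F2 segregation; for other population
  types its constants (1/2, (1−2r)/2) do not apply.
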