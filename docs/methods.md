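# Methods

## Model

`diallelgs` evaluates hybrid performance in a half-diallel breeding program
with the additive+dominance GBLUP model

    y = 1 mu + g_A + g_D + e,
    g_A ~ N(0, sigma2_A K_A),   g_D ~ N(0, sigma2_D K_D),   e ~ N(0, sigma2_e I),

where `y` holds one phenotypic record per training hybrid.  The genomic
relationship matrices are `K_A = (1/p) X_A X_A'` and `K_D = (1/p) X_D X_D'`
over standardized marker scores: additive scores code the minor-allele
homozygote, heterozygote and major-allele homozygote as −1/0/+1; dominance
scores code the heterozygote as 1 and both homozygotes as 0.

"Standardized" is implemented as a column z-score (center by the mean,
divide by the n−1 standard deviation).  This puts the mean diagonal of each
GRM near 1, the conventional scale for genomic relationships.  Orientation
of the additive code (which homozygote is "major") and the column statistics
are always computed over a single *reference set* — the combined training
and breeding hybrids for a full evaluation, or the training rows of a fold
during cross-validation — and reused for any other rows, so the square and
cross relationship blocks share one scale.  Sign conventions cancel inside
`X X'`, so GRMs and GEBVs do not depend on the orientation choice.

Genotypes are dosage matrices in {0,1,2} with missing entries.  Inbred
parents must be homozygous ({0,2}); residual heterozygous calls are a hard
error by default because silent acceptance would corrupt hybrid synthesis
(a permissive flag demotes them to missing and re-imputes).  An F1 hybrid's
dosage is the midpoint of its parents' dosages.

### QC pipeline

Order: missing-rate filter → major-allele imputation → MAF filter is applied
jointly at the filtering step (missing-rate rule first, so a marker failing
both is tallied under missing), then coding, then removal of markers whose
dominance column is all zero over the reference set (no heterozygote
anywhere: no dominance information and a zero-variance column).  Defaults
`max_missing_rate = 0.05`, `min_maf = 0.05`.  A major-allele frequency tie
at exactly 0.5 imputes dosage 0, deterministically, with a warning.

## Estimation

### Henderson system

For given variance ratios `lambda_A = sigma2_e/sigma2_A`,
`lambda_D = sigma2_e/sigma2_D`, the BLUE/BLUPs solve the symmetric
(2n+1)×(2n+1) system with blocks `[[n, 1', 1'], [1, I + K_A⁻¹λ_A, I],
[1, I, I + K_D⁻¹λ_D]]` and right-hand side `[1'y, y, y]`.  The system is
solved through a symmetric factorization (`scipy.linalg.solve(assume_a=
"sym")`), never by explicit inversion; the test suite checks it against an
independent closed-form GLS/BLUP oracle.

GRM inverses use a Cholesky factorization with an escalating diagonal
ridge: on failure, `ridge_scale × mean(diag K)` (default `ridge_scale =
1e-6`) is added and doubled up to 10 times; the ridge actually used is
recorded on the `KinshipSet` and logged.  Dominance GRMs over a full
diallel are near-singular essentially always (the dominance score of hybrid
(i,j) is a deterministic XOR-like function of the parental alleles, which
collapses the row space), so this path is routine, not exceptional.  When a
ridge fires, the ridged matrix is stored as the working GRM so that `K` and
`K⁻¹` remain an exact pair throughout the sampler and predictor.

### Gibbs sampler

Variance components and location effects are estimated jointly by a Gibbs
sampler with scaled-inverse-chi-square variance draws:

1. init: `mu = mean(y)`, `g_A = g_D = 0`, `sigma2_e = 1`,
   `sigma2_A = sigma2_D = 0.5`;
2. per iteration, sequential block draws of mu, g_A, g_D from
   `N(C_ii⁻¹(γ_i − C_{i,−i} g_{−i}), sigma2_e C_ii⁻¹)`;
3. residual `e = y − mu − g_A − g_D`;
4. `sigma2_e = (e'e + S*v*) / χ²_{n+v*}`, and likewise `sigma2_A` with
   `q = g_A' K_A⁻¹ g_A`, `sigma2_D` with `q = g_D' K_D⁻¹ g_D`;
5. refresh the lambdas.

Defaults: `K = 5000` iterations, the last `0.1 K` retained and averaged,
`M = 5` independent chains whose means are averaged, prior scale
`S* = 0.5 V` (V the sample variance of y) with `v* = 5` degrees of freedom.
Chain m is seeded `seed + m`, so runs are bitwise reproducible.  The 90%
burn-in fraction is unusual but deliberate and configurable.

Implementation note: the conditional precision blocks are
`C_ii = I + λ K⁻¹`.  Eigendecomposing each `K⁻¹ = U diag(s) U'` once per
chain diagonalizes every conditional for every λ — eigenvalues `1 + λ s`
change, eigenvectors do not — so each iteration costs O(n²) (a few
matrix–vector products) instead of a fresh O(n³) factorization, with no
approximation.  The generic Cholesky-based block sampler is also exposed
and tested against the same conditionals.

The prior scale `S* = 0.5V` on all three components is informative: with
n in the low hundreds it pulls each variance toward `0.5V`, which biases
h² upward when the generating h² is below the prior's implied value.  The
synthetic-recovery tests quantify this (median ĥ² ≈ 0.67–0.71 at a
generating 0.6 with n = 210).

### Breeding-population prediction and combining ability

BLUPs for the `N1 = C(N0,2)` diallel hybrids follow by projection,
`g_A^(bp) = K_A^(bp) K_A⁻¹ g_A` (dominance analogously), and
`GEBV = mu + g_A^(bp) + g_D^(bp)`.  GEBVs are never re-derived from
GCA/SCA (the two decompositions differ by a population-level offset).

The additive BLUP of a hybrid decomposes as `g_A^(ij) = GCA_i + GCA_j` and
the dominance BLUP is the SCA.  GCA is recovered by
`GCA_i = (N0−1) Ḡ_A^(i)/(N0−2) − N0 Ḡ_A / (2(N0−2))`, with `Ḡ_A^(i)` the
mean over the N0−1 hybrids containing parent i and `Ḡ_A` the mean over the
N1 unordered hybrids, **each counted once**.  Counting ordered pairs (each
hybrid twice) would double `Ḡ_A`, shift every GCA by a constant, leave
rankings and MPH unchanged, but change BPH; the unordered reading is the
one under which the formula inverts the pair-sum structure exactly (it also
equals the least-squares projection of the additive BLUPs onto that
structure — both identities are property-tested).  Heterosis on the GEBV
scale: `MPH_ij = SCA_ij` and `BPH_ij = SCA_ij − |GCA_i − GCA_j|`, so
BPH ≤ MPH with equality exactly for equal-GCA parents.  Ranked reports
sort by GEBV (hybrids) or GCA (parents) descending with deterministic
lexicographic tie-breaks; rounding (default 3 dp) is presentation-only.

## Synthetic data

`evalkit` generates what the estimators consume: inbred parental panels
(per-marker MAF uniform in (0.05, 0.5] by default; each parent homozygous,
carrying the major allele with its frequency; monomorphic columns redrawn),
midpoint F1 genotypes for every cross, and phenotypes drawn from the model
with PSD-safe factorization of the GRMs (eigenvalues clipped at zero, an
indefinite matrix beyond −1e−8·trace is an error).

The generator emulates idealized panels: unlinked markers in linkage
equilibrium, no population structure among parents, no missing data after
imputation, exact homozygosity, and phenotypes exactly from the fitted
model.  Real panels violate all of these (LD blocks, heterotic groups,
genotyping error, epistasis), so passing recovery tests demonstrates
correctness of the machinery under the model's own assumptions, not
field-data performance.

Default scenario sizes are desk-scale by design: a 16-parent diallel
(120 hybrids, mirroring the 119-hybrid pumpkin training set) with p = 500
markers and 100 phenotype replicates for the simulation-study harness
(configurable up to the full 3000), and a 21-parent diallel (210 hybrids)
for heritability-recovery checks.

### Protocol harnesses

* **Simulation study** — one synthetic diallel fixes the kinship;
  phenotypes are redrawn per replicate from the generating variance
  components (e.g. the pumpkin-fitted 0.306/0.159/0.111) and passed to any
  `estimator(pheno, kin, seed)`; the harness reports per-component bias
  and dispersion.
* **Cross-validation** — per repeat, a fresh random partition into
  `n_folds` clusters (sizes within 1); marker orientation, standardization
  and kinship are recomputed from the training rows of each fold (strictly
  leakage-free, possibly stricter than other implementations); held-out
  GEBVs come from the fold's cross-GRMs; Pearson's r per fold, with
  zero-variance folds recorded as missing and excluded from the summary
  with a logged count.  Default 10 folds × 5 repeats = 50 correlations.

## Numerical choices and edge cases

* All randomness flows through `numpy.random.default_rng` from explicit
  integer seeds; derived seeds are drawn below 2³¹.
* Variance draws are strictly positive; a zero quadratic form with a zero
  prior scale is an error (degenerate prior), a negative quadratic form is
  an error (broken kinship inverse).
* `heritability` requires nonnegative components with a positive sum;
  GCA requires N0 ≥ 3 (the formula divides by N0−2).
* Duplicate phenotype records are rejected with instructions to
  pre-average; duplicate individual/marker ids are rejected at load.
* Eigenvalues of `K⁻¹` are clipped at zero before use in the sampler to
  absorb −1e−15-scale round-off.

## Limitations

* One record per hybrid (repeated measurements must be pre-averaged
  upstream; no repeated-record Z matrices).
* No epistatic components; SCA is pure dominance.
* No REML or RKHS estimators; the estimator interface accepts
  user-supplied callables but ships only the Gibbs sampler and an exact
  MME solve at fixed variance ratios.
* LD-based marker pruning, phasing and SNP calling are out of scope; the
  QC implemented is missing-rate/MAF/zero-dominance filtering with
  major-allele imputation.
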