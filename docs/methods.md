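# Methods

## Model

Phenotypes of n individuals follow y = Xβ + ξ + ε with ξ ~ N(0, K σ_A²)
and ε ~ N(0, I σ²).  The polygene ξ aggregates all marker effects
γ_k ~ N(0, σ_γ²) through ξ = Σ_k Z_k γ_k, giving the polygenic variance
σ_A² = m σ_γ².  The kinship is the raw average of per-locus outer products,
K′ = (1/m) Σ_k Z_k Z_kᵀ, deliberately without allele-frequency centering or
VanRaden scaling: the only normalization is the trace rescale
K = n K′/tr(K′), which puts σ_A² on the same per-individual scale as σ².
Fully homozygous ±1-coded panels already have tr(K′) = n, so the rescale
is then the identity and σ_A² = m σ_γ² exactly — the identity the
parameter-recovery test relies on.

Assumptions: a single univariate trait, i.i.d. residuals (R = I), no
genotype-by-environment interaction, no dominance or epistasis.  The
fixed-effect design defaults to an intercept column; arbitrary covariate
matrices are accepted through files.

## REML / ML

The restricted log-likelihood (constants dropped) is

    L = −½ ln|V| − ½ ln|XᵀV⁻¹X| − ½ (y−Xβ̂)ᵀV⁻¹(y−Xβ̂),  V = Kσ_A² + Iσ²,

with β̂ the GLS estimate at V; the ML objective omits the middle term.  A
single eigendecomposition K = U D Uᵀ rotates (y, X) so V is diagonal in
λ = σ_A²/σ²; σ² then profiles out in closed form and the problem reduces
to a bounded scalar maximization in log λ over λ ∈ [1e−6, 1e6]
(`scipy.optimize.minimize_scalar`, xatol 1e−9).  This is exact for the
two-component model and instant at n ≈ 210.  Both components are bounded
below at 1e−5; boundary candidates are compared against the interior
optimum before reporting.  The reported log-likelihood is re-evaluated at
the returned (σ_A², σ²) with the unprofiled formula, so it is directly
comparable with grid or external evaluations of the same objective.

Degeneracies: constant y raises before optimization.  When the profile
objective is flat in λ (K ≈ I, where only σ_A² + σ² is identified), the
fit carries a `degenerate` flag and a warning instead of pretending the
reported split is meaningful.

## BLUE / BLUP and held-out prediction

Two algebraically equivalent routes are implemented: the literal Henderson
block system (which requires K⁻¹ and therefore an invertible K — it raises
with a condition diagnostic otherwise) and the V-inverse route
β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y, ξ̂ = Kσ_A²V⁻¹(y − Xβ̂), which is valid for any PSD
K and is the default.  Held-out individuals are predicted by the
conditional expectation ŷ₂ = X₂β̂ + K₂₁σ̂_A²(K₁₁σ̂_A² + Iσ̂²)⁻¹(y₁ − X₁β̂);
V₁₁ is always invertible because σ² is bounded away from zero, so no ridge
is added (a condition-number warning is logged above 1e10).

## Cross-validated heritability

k-fold plans permute individuals uniformly and cut into k blocks differing
in size by at most one.  Within each fold, variance components *and* β are
re-estimated from the k−1 training folds (`per_fold` mode, the default) —
the only fully leak-free protocol; a `global` mode (full-data components,
CV predictions) exists for comparison and is documented as partially
leaky.  The kinship is computed once from all genotypes and sliced per
fold; genotypes carry no phenotype information, so this is not leakage.

After CV, with y_centered the phenotype minus the *fold-specific* X₂β̂
(a per-fold mean shift under the intercept design):

    Hcv     = Var(ξ̂_cv) / (Var(ξ̂_cv) + Var(y_centered − ξ̂_cv))
    Hcv_alt = Var(ξ̂_cv) / Var(y)
    Pcv     = corr(y_centered, ξ̂_cv)²

All sample variances use the n−1 denominator.  One statistic per repeat is
computed from the pooled n-vector (not averaged over folds); repeats are
summarized by mean and standard deviation.  Defaults: k = 5; the
rice-style workflow uses 10-fold × 10 repeats.  Constant predictions give
Pcv = 0 with a warning rather than an exception.

## ANOVA benchmark

For balanced n-line × r-replicate tables the two-way fixed-effects
decomposition yields MS_line, MS_replicate, MS_error by the closed-form
balanced-design sums of squares (cross-checked against statsmodels'
`anova_lm` in the tests).  The heritability is taken on the
single-observation basis: σ̂²_line = (MS_line − MS_error)/r and
Haov = σ̂²_line/(σ̂²_line + MS_error), with negative σ̂²_line truncated to
zero under a warning.  The single-plot basis was chosen because its
expectation matches the per-observation signal fraction
Var(ξ)/(Var(ξ)+σ_e²) irrespective of r, which is exactly the constancy the
replicate-grid study demonstrates; the line-mean basis (MS_error/r in the
denominator) would instead climb with r.  Unbalanced designs are rejected
rather than approximated, and r = 1 raises an error directing the user to
the GS path, which needs no replicates.

## Simulator

RIL genotypes are generated directly at fixation: within a chromosome,
parental origin follows a left-to-right Markov chain whose switch
probability between adjacent loci is the RIL-by-selfing recombination
fraction R = 2r/(1+2r), with r from the Haldane map function
r = (1 − e^(−2d/100))/2 (no interference).  This matches the expected
pairwise LD of selfing-derived RILs at a fraction of the cost of
generation-explicit simulation, and is validated in the tests against a
literal per-meiosis selfing simulator.  Heterozygotes are supported in
genotype files (F2 input) but never produced by the RIL simulator.

Traits: effects first (γ_k i.i.d. N(0, σ_g²), optionally restricted to a
random causal subset with the rest set to zero), then residuals
replicate-major, all from a single seeded generator, so outputs are
bit-reproducible.  The true ξ vector is retained for recovery tests.

The default panel mirrors a rice-like bin map: 210 lines, 1619 loci on 12
chromosomes of 150 cM each (a realistic total map length for rice).  On
this synthetic map with i.i.d. effects, σ_g/σ_e = 1/20 yields a realized
signal fraction Var(ξ)/(Var(ξ)+σ_e²) near m σ_g²/(m σ_g²+1) ≈ 0.8, not
0.5: the ~0.5 figure associated with that ratio on the real rice panel
reflects the rice bins' particular LD structure, which an equal-spacing
synthetic map does not reproduce.  Studies that need a target signal level
therefore set σ_g = sqrt(s/(1−s)/m) for the desired fraction s rather
than quoting a σ_g/σ_e ratio.

What the simulator does *not* emulate: segregation distortion, genotyping
error and missingness, selection during line development, dominance and
epistasis, real marker spacing, or block/location effects (replicates are
simple technical replicates).  Passing tests on these panels demonstrate
the estimators' statistical behaviour under the stated model, not
performance on any particular real dataset.

## Numerical choices and problem sizes

- PSD guard: kinship eigenvalues below −1e−8 × (largest) raise; tiny
  negatives are clamped to zero.
- Missing genotypes are imputed to per-locus means before the kinship sum,
  with a logged count; monomorphic loci are kept by default (the defining
  sum has no frequency filter) with an option to drop them.
- Kinship files round-trip bit-exactly (written at 17 significant digits,
  read with round-trip float parsing).
- The test suite and the acceptance script run panels at the full
  210 × 1619 study dimensions — the eigendecomposition REML makes this
  cheap — with 20-panel sweeps for distributional claims and 50 panels for
  the bias check; the simulator calibration uses 20 000 lines.

## Known limitations

- The Henderson block route needs an invertible K; rank-deficient kinships
  (fewer markers than individuals) must use the default V-inverse route.
- Heritability from a degenerate (flat-likelihood) fit is meaningless; the
  flag must be checked by callers that construct ratios themselves.
- ANOVA is restricted to balanced single-factor-replicate designs by
  design; Type-I/II/III ambiguity for unbalanced data is out of scope.
- Standard errors of h² (from the information matrix) are not reported.
- Multi-trait models, G×E terms and non-identity residual structures are
  out of scope.
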