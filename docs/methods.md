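# Methods

## The model

`sgekit` quantifies **social genetic effects (SGE)** — associations between
the genotypes of an individual's cage mates and the individual's own
phenotype — jointly with direct genetic effects (DGE), their environmental
analogues, and shared cage effects. For a cohort of n group-housed,
genetically related individuals the phenotype vector is modelled as

    y = X b + a_D + Z a_S + e_D + Z e_S + W c

where `Z` is the cage-mate indicator (`Z[i,j] = 1` iff i ≠ j share a cage;
`Z[i,i] = 0`), `W` the cage incidence matrix, `a_D`/`a_S` direct and social
additive genetic effects, `e_D`/`e_S` their environmental counterparts and
`c` a cage effect. The random effects are jointly Gaussian with

    (a_D, a_S) ~ N(0, [[s2_AD*H1, s_ADS*H2], [s_ADS*H2', s2_AS*H3]])
    (e_D, e_S) ~ N(0, [[s2_ED*I1, s_EDS*I2], [s_EDS*I2', s2_ES*I3]])
    c          ~ N(0, s2_C*I4)

which yields the phenotypic covariance

    cov(y) = s2_AD*H1 + s_ADS*(H2 Z' + Z H2') + s2_AS*(Z H3 Z')
           + s2_ED*I1 + s_EDS*(I2 Z' + Z I2') + s2_ES*(Z I3 Z')
           + s2_C*(W I4 W').

The covariance `s_ADS` between an animal's direct and social effects is the
crux: when relatives share cages, an animal's genotype is correlated with
its social environment (gene–environment correlation), and ignoring the
social terms biases heritability estimates — upward for `s_ADS > 0`,
downward for competition-like `s_ADS < 0`.

### Relationship matrices

Relatedness enters through a single matrix that covers genotyped and
non-genotyped animals coherently:

- **A** — Wright's numerator relationship matrix from the pedigree
  (tabular method; unknown parents are unrelated, non-inbred founders).
- **G** = `M M' / (2 Σ p_i q_i)` with `M` the dosage matrix centered by
  twice the observed allele frequency; monomorphic loci are dropped and
  missing dosages mean-imputed (equivalently, centered to zero).
- **G\*** = `0.95 (a + b G) + 0.05 A_gg` aligns the genomic matrix with the
  pedigree base population; `(a, b)` either as the constants printed for
  the reference colony (0.015, 0.982) or solved from the matrices so the
  mean diagonal and mean off-diagonal of `b G + a` match `A_gg` (the mode
  used for synthetic cohorts, whose drift is their own).
- **H** (single-step) — `H^-1 = A^-1 + blockdiag(0, G*^-1 − A_gg^-1)` on
  the (non-genotyped, genotyped) partition. The implementation uses the
  minus sign, which is the unique choice satisfying both limits `H = A`
  (nobody genotyped) and `H = G*` (everybody genotyped); both limits are
  asserted in the test suite, and the mixed case is checked against the
  direct partitioned-matrix identity.

### The sampleVar scaling

Every design matrix is rescaled by `sampleVar(M) = Tr(PMP)/(n−1)`,
`P = I − 11'/n`, the average variance a covariance matrix induces across a
centered sample (`sampleVar(I) = 1`). `H1 = H/sampleVar(H)`,
`H3 = H/sampleVar(ZHZ')`, and `H2 = H/sqrt(sampleVar(H)·sampleVar(ZHZ'))`;
`I1–I4` analogously. After this scaling each variance parameter reads
directly as its contribution to the sample phenotypic variance, and
`rho_ADS = s_ADS/(s_AD·s_AS)` is a bona fide correlation in [−1, 1] — the
geometric-mean convention for `H2` is required for that; a plain product in
the denominator would allow |rho| > 1, contradicting simulated values such
as 0.92.

## Estimation

Variance components are estimated by **REML**. The two 2×2 covariance
blocks are parameterized by their Cholesky factors (enforcing positive
semidefiniteness, hence |rho| ≤ 1) and the cage variance by a square, so
the parameter space is unconstrained. The restricted likelihood includes
`+½ log|X'X|`, making it invariant to the choice of fixed-effect basis
(asserted numerically, together with invariance to translation of y).

Optimization is quasi-Newton (L-BFGS-B) with analytic gradients
(`∂l/∂c_k = −½[tr(P K_k) − y'P K_k P y]`, chained through the block
jacobians) from a three-point restart schedule — a null start (residual
variance dominant), a direct-genetics-heavy start, and an equal split —
stopping early when two starts agree within 1e−4 log-likelihood units.
Convergence requires a projected gradient below 1e−5. The optimum has been
cross-checked against derivative-free Nelder-Mead maximization of an
independent slogdet-based likelihood implementation (agreement < 1e−4).
Failed Cholesky factorizations during the search are penalized; matrix
inversions elsewhere use escalating diagonal jitter (1e−10 → 1e−6), logged.

**Standard errors** come from the expected information
`I_jk = ½ tr(P K_j P K_k)` at the optimum. When components sit on the
boundary the information matrix can be numerically singular; SEs are then
reported for the well-conditioned subset and flagged for the rest. Note
the expected information equals the average of observed Hessians over data
replicates, not the Hessian of any single realization; the test suite
checks exactly that property by Monte Carlo, plus an SD-versus-SE
calibration across replicates.

**Significance** of SGE uses a restricted likelihood-ratio test removing
`s2_AS` and `s_ADS` while retaining all environmental terms (s_EDS stays:
it is an environmental, not genetic, parameter), referred to χ²(2). Because
the variance sits on the boundary of its parameter space under the null,
the reference distribution is conservative; calibration runs confirm
rejection rates below nominal. Multiple testing across traits uses Storey
q-values (λ-grid 0.05–0.95, cubic-polynomial π₀ smoother; π₀ = 1 reduces
the procedure exactly to Benjamini–Hochberg).

**Variance partitioning** reports, per component, its contribution to the
sample variance of the fitted covariance (for the scaled genetic terms this
is the parameter itself) over the sample variance of the full fitted
covariance, as a percentage.

### Identifiability guards

- **Constant group size.** When every cage holds the same number of
  animals, the four environmental bases all lie in span{I, Z} (with size s:
  `ZZ' = (s−2)Z + (s−1)I`, `WW' = Z + I`), so `s2_ED, s_EDS, s2_ES, s2_C`
  are not separately identifiable. The fitter detects this and collapses
  the environmental side to an exchangeable within-cage residual
  `s2_E·I + tau·Z`, parameterized through the per-cage block eigenvalues so
  positive definiteness is automatic (tau may be negative). Genetic
  components are unaffected. This mirrors the standard argument for paired
  designs, where the residual correlation may be negative and the model
  cannot be rewritten as cage effects plus iid noise.
- **No genetic contrast.** If the scaled direct-genetic basis coincides
  with the identity (all individuals unrelated), the direct genetic and
  direct environmental variances are confounded; the genetic terms are
  dropped with a logged notice. Similarly a cage basis identical to the
  identity (all singleton cages) drops the cage term.
- **No co-housing.** With no co-housed pairs all social terms vanish and
  are dropped.

## The two-inbred-strain design

With two strains (coded 0/1) and two animals per cage, genetic effects are
fixed effects: `y_f = β_D X_f + β_S X_cm + β_DS X_f X_cm + e_f`, with
exchangeable within-cage residual correlation `cov(e_i, e_j) = ρ σ²_E` for
cage mates. Group size 2 makes direct/social/cage environmental variances
unidentifiable, and ρ may be negative (−1 ≤ ρ ≤ 1); for ρ ≥ 0 the model is
exactly a cage-random-intercept model (asserted against an independent
mixed-model implementation). The GLS profile over ρ uses the closed-form
inverse and determinant of the exchangeable block.

Conventions, matching how such experiments are analysed: AIC model
selection over the marginality-respecting term sets {∅, D, S, D+S,
D+S+D:S} × {iid, compound-symmetry} uses ML fits (`AIC = 2k − 2LL`, k
counting fixed effects plus free covariance parameters); per-strain SGE
tests are ML likelihood-ratio tests of `β_S` on χ²(1) (REML likelihoods
are not comparable across fixed-effect structures); variance partitioning
uses the REML fit. The variance explained by a fixed term is
`var(β̂ x)` across individuals over the mean sample variance of 10,000
Monte-Carlo draws from the fitted model, with first-order (delta-method)
propagation of coefficient uncertainty for the SE.

Phenotypes are normalized beforehand by a **covariate-aware Box-Cox**
transform: λ maximizes the profile likelihood of a linear model containing
focal strain, cage-mate strain and their interaction (grid on [−2, 2]
refined by bounded optimization). The design informs λ only — genetic
effects are not regressed out by the transform. Experimental covariates
screened at p < 0.05 per covariate are regressed out by default (an
include-as-fixed-effects mode exists for sensitivity analyses).

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
not any particular colony:

- **Population**: `n_families` founder pairs drawn in Hardy–Weinberg
  equilibrium at per-locus frequencies uniform on (0.1, 0.9); offspring by
  Mendelian gene dropping (one transmitted allele per parent per locus,
  loci unlinked). Full-sib families of configurable size.
- **Cages**: filled by weighted sampling preferring same-family animals
  (weight 0 → exchangeable assignment, weight 1 → full-sib packing), so
  cage mates are more related than average — the gene–environment
  correlation that makes heritability bias appear.
- **Phenotypes**: `(a_D, a_S)` drawn jointly from the 2n-dimensional
  normal implied by the model (jitter 1e−8 before factorizing), the
  environmental pair from its 2×2 kronecker structure, cage effects iid;
  the same scaled matrices are used for generation and fitting, so
  variance proportions serve directly as component magnitudes.
- **Paired experiment**: B6/B6, B6/D2, D2/D2 cages (defaults 14/16/13,
  both animals focal), bivariate-normal residuals with correlation ρ,
  strain-specific social effects through the interaction coefficient.

What the generator does **not** emulate: linkage and LD (loci are
independent), the 8-founder haplotype mosaic structure of a heterogeneous
stock, selection or non-random mating beyond family structure, and
real-world covariate structure. Passing tests therefore demonstrate
statistical correctness of the estimators under the assumed model, not
robustness to the full complexity of real colony data.

### The reference scenario and its trade-offs

The reference cohort used by the simulation study is 600 housed mice from
200 full-sib families of three, cages of three with sibling co-housing
weight 0.5 (within-cage mean relatedness ≈ 0.12 against a population mean
≈ 0.002), 80% of the cohort genotyped at 2,000 loci so relatedness flows
through the single-step H matrix.

Two consequences of the constant cage size are worth stating plainly.
First, the environmental collapse applies (see guards above), which leaves
the social genetic variance separated from the exchangeable residual only
by the relatedness weighting in `Z H3 Z'` — point estimates of a small
`s2_AS` therefore have a large sampling SD (≈ 6 percentage points at
n = 600) and, being constrained non-negative, a positively biased mean of
roughly `E[max(N(truth, 6), 0)]` when the truth is small. The bias halves
by n = 1200 and is negligible at a few thousand animals — consistent with
unbiasedness claims at full cohort sizes. Second, an alternative with
variable cage sizes (2–7) was evaluated and rejected as the default: size
variation hands the null model's environmental terms exactly the
directions needed to absorb size-correlated social variance, collapsing
likelihood-ratio power (from >90% to ~16% at 27% SGE, n = 600) while not
curing the small-sample bias. It remains available as
`simulate.REALISTIC_CAGE_SIZES`.

The simulation scenarios are the two headline parameter sets (all-trait
average: DGE 15%, SGE 4%, ρ_ADS 0.5, direct environment 52%, cage 22%;
high-SGE: DGE 5%, SGE 27%, ρ_ADS 0.92, direct environment 5%, cage 51%)
plus single-parameter grids around the average set.

## Problem sizes

The replicated studies run at: recovery batches of 100 replicates
(acceptance script) or 50 (test suite) at n = 600; likelihood-ratio
calibration 500 replicates at n = 240; bias study 60 replicates at
n = 300; the covariance-assembly oracle 50,000 Monte-Carlo draws on a
60-animal cohort. Each REML fit takes a couple of seconds at n = 600 on a
single core.

## Known limitations

- Single-trait analyses only; no bivariate/multi-trait REML and no
  per-locus association mapping of social effects.
- The expected-information SEs are asymptotic and degrade for components
  at or near the boundary (flagged, not fabricated).
- The LRT reference χ²(2) is conservative at the boundary; power
  statements are therefore conservative too.
- Storey π₀ estimation needs a few dozen tests to be stable; below that
  the implementation falls back to π₀ = 1 (Benjamini–Hochberg).
- `pedigree_A` is dense (O(n²) memory); fine for thousands of animals,
  not for livestock-scale pedigrees.
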