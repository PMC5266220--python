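# sgekit

Social genetic effects (SGE, also called indirect genetic effects) are
associations between the genotypes of an individual's social partners and
the individual's own phenotype — cage mates' genes shaping a mouse's
anxiety, immune traits or wound healing through whatever mediating
behaviours those genes drive. `sgekit` is a Python library for quantifying
SGE in group-housed laboratory populations, for two complementary designs:

- **Outbred cohorts** (genetically unique, pedigree-related animals):
  a linear mixed model partitions phenotypic variance into direct genetic
  effects (DGE), social genetic effects, their covariance, the matching
  direct/social environmental effects, and cage effects,

  cov(y_i, y_j) = σ²_AD·H1 + σ_ADS·(H2 Z' + Z H2') + σ²_AS·(Z H3 Z')
  + σ²_ED·I1 + σ_EDS·(I2 Z' + Z I2') + σ²_ES·(Z I3 Z') + σ²_C·(W I4 W')

  with Z the cage-mate indicator, W the cage incidence, and H the
  pedigree/genomic/single-step relationship matrix scaled by
  sampleVar(M) = Tr(PMP)/(n−1) so every component reads directly as a
  share of phenotypic variance. Estimation is REML with the direct–social
  blocks Cholesky-parameterized (|ρ_ADS| ≤ 1 guaranteed); significance is
  a conservative 2-df restricted likelihood-ratio test; multiple testing
  uses Storey q-values.

- **Two inbred strains, paired housing** (B6/B6, B6/D2, D2/D2 cages):
  fixed-effect models y_f = β_D X_f + β_S X_cm + β_DS X_f X_cm + e_f with
  compound-symmetry residuals (−1 ≤ ρ ≤ 1), AIC model selection on ML
  fits, per-strain likelihood-ratio tests of the cage-mate effect, and
  fixed-effect variance partitioning with Monte-Carlo phenotypic variance.

A central result the package reproduces on synthetic data: when relatives
share cages, DGE and SGE are correlated, and **heritability estimates that
ignore SGE are biased** — fitting cage effects alone does not remove the
bias.

It also ships the building blocks: Wright's pedigree relationship matrix
A, the allele-frequency-centered genomic matrix G, base-population
blending G*, the single-step H matrix for partially genotyped populations,
covariate-aware Box-Cox normalization, and generators for pedigrees,
gene-dropped genotypes, relatedness-biased cage assignments and phenotypes
drawn from the full model. See `docs/methods.md` for the model and its
assumptions.

## Worked example

`examples/heritability_bias.py` simulates phenotypes on a synthetic cohort
in which direct and social genetic effects are positively correlated
(ρ_ADS = 0.5, SGE = 20% of variance), then fits three models per
replicate:

```
$ python examples/heritability_bias.py
         dge_bias        sge_bias
             mean    std     mean    std
model
dge         18.21  11.85   -20.00   0.00
dge_cage    -4.16   7.14   -20.00   0.00
full        -0.70   9.02    -0.14  13.29

dge_bias is the estimated minus simulated DGE percentage. The 'dge'
model (no SGE, no cage) is strongly biased upward; the full model is
near zero. 'dge_cage' absorbs the within-cage social covariance into
the cage variance — how much residual bias it keeps depends on the
cage structure, and it can even overcorrect.
```

The direct-genetics-only model overstates heritability by ~18 points of
phenotypic variance in this 300-mouse cohort; the full model is unbiased
within noise. The other examples cover the trait scan
(`outbred_scan.py`), the paired-strain analysis (`inbred_experiment.py`)
and relationship-matrix construction (`relationship_matrices.py`); each
prints a short interpretation of its numbers.

There is also a thin CLI for shell-driven pipelines:

```bash
sgekit simulate --scenario average --reps 10 --seed 1 --out sim/
sgekit scan --phenotypes sim/phenotypes.tsv --cages sim/cages.tsv \
            --relatedness sim/relatedness.h5 --out scan/
sgekit inbred --data paired.tsv --out inbred/
sgekit bias-study --scenario average --reps 50 --seed 1 --out bias/
```

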