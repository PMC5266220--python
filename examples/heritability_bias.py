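"""Show how ignoring social genetic effects biases heritability estimates.

Simulates phenotypes in which direct and social genetic effects are
positively correlated (relatives share cages, so an animal's genotype is
correlated with its social environment) and fits three models per
replicate: direct genetics only, direct genetics + cage effects, and the
full social-effects model. The direct-genetics-only model overestimates the
DGE variance; cage effects shrink but do not remove the bias; the full
model is approximately unbiased.
"""

from sgekit import build_reference_design, run_bias_study, scenario

design = build_reference_design(n_families=100, family_size=3, n_loci=800, seed=7)
vc = scenario("grid", sge=0.20, rho_ads=0.5)

table = run_bias_study(design, vc, n_reps=20, seed=11)
summary = table.groupby("model")[["dge_bias", "sge_bias"]].agg(["mean", "std"])
print(summary.round(2))
print()
print("dge_bias is the estimated minus simulated DGE percentage. The 'dge'")
print("model (no SGE, no cage) is strongly biased upward; the full model is")
print("near zero. 'dge_cage' absorbs the within-cage social covariance into")
print("the cage variance — how much residual bias it keeps depends on the")
print("cage structure, and it can even overcorrect.")
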