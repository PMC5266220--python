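"""Scan simulated traits of an outbred, group-housed cohort for social
genetic effects.

Builds a 300-mouse synthetic colony (full-sib families, relatives co-housed
more often than chance, single-step relatedness from pedigree + genotypes),
plants a social genetic signal in two of four traits, and runs the scan:
per-trait restricted likelihood-ratio tests, q-values, and DGE/SGE variance
percentages with standard errors.
"""

import numpy as np
import pandas as pd

from sgekit import build_reference_design, run_scan, scenario
from sgekit.simulate import PhenotypeSimulator

design = build_reference_design(seed=7)  # 600 mice, 200 full-sib families

social = scenario("high-sge")              # 27% social genetic variance
null = scenario("grid", sge=0.0, dge=0.20)  # direct genetics only

Y_social = PhenotypeSimulator(social, design.scaled, design.cages).draw(seed=1, n_reps=2)
Y_null = PhenotypeSimulator(null, design.scaled, design.cages).draw(seed=2, n_reps=2)

phenotypes = pd.DataFrame({
    "id": design.cages.ids,
    "immune_a": Y_social[:, 0],
    "immune_b": Y_social[:, 1],
    "weight_a": Y_null[:, 0],
    "weight_b": Y_null[:, 1],
})

table, manifest = run_scan(phenotypes, design.cages, design.H, seed=3)
print(table.round(4).to_string(index=False))
print()
print("Traits with a planted social genetic component (immune_*) should show")
print("small SGE p/q-values and SGE percentages in the region of 27%; the")
print("weight_* traits carry direct genetic effects only, so their SGE")
print("estimates stay small and non-significant.")
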