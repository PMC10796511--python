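"""Trial statistics: BLUEs, REML heritability, Tukey letters, transgression.

Plot records follow y = mu + genotype + year + block(year) + error.  BLUEs
are least-squares genotype means; heritability on a plot basis is
H2 = sigma_g2 / (sigma_g2 + sigma_e2 / r) with r the harmonic mean of
replicate counts and sigma_g2 from REML with genotype random.
"""

import numpy as np
import pandas as pd

from dhinducer import (
    fit_blue,
    transgressive_summary,
    tukey_groups,
    variance_components,
)

rng = np.random.default_rng(5)
genos = [f"G{i}" for i in range(1, 9)]
true_g = rng.normal(10.0, np.sqrt(6.0), len(genos))  # genetic values
rows = []
for g, gv in zip(genos, true_g):
    for year, yeff in [("Y1", 0.0), ("Y2", 1.0)]:
        for block, beff in [("B1", 0.4), ("B2", -0.4)]:
            rows.append((g, year, block, gv + yeff + beff + rng.normal(0, 1.0)))
records = pd.DataFrame(rows, columns=["genotype", "year", "block", "HIR"])

blues = fit_blue(records, "HIR")
vc = variance_components(records, "HIR")
letters = tukey_groups(blues)

print("genotype  BLUE   Tukey")
for _i, r in blues.table.sort_values("estimate", ascending=False).iterrows():
    print(f"{r['genotype']:8s}  {r['estimate']:5.2f}  {letters[r['genotype']]}")
print(f"\nsigma_g2 = {vc.sigma_g2:.2f}, sigma_e2 = {vc.sigma_e2:.2f}, "
      f"r = {vc.r_harmonic:.0f}  ->  H2 = {vc.H2:.2f}")
# genotypes not sharing a letter differ by Tukey's test at the 5% level

# transgressive segregation: progeny beyond both parental extremes
parents = blues.table.iloc[:2]
from dhinducer.phenostats import BLUETable

parent_blues = BLUETable("HIR", parents, blues.residual_var, blues.residual_df)
rep = transgressive_summary(parent_blues, blues)
print(f"\nparents range [{rep.parent_min:.2f}, {rep.parent_max:.2f}], "
      f"progeny range [{rep.dhi_min:.2f}, {rep.dhi_max:.2f}] "
      f"-> high={rep.high_transgressive}, low={rep.low_transgressive}")
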