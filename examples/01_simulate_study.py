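"""Generate a synthetic DH-inducer program and inspect its ground truth.

Eight homozygous founder inducers are crossed in a half-diallel (28 F1s);
each F1 contributes 20 doubled haploid lines, every line fixed from a single
Poisson-crossover meiosis, so the simulator knows each line's exact
centimorgan-weighted parental contribution.
"""

import numpy as np

from dhinducer import SimConfig, simulate_study

study = simulate_study(SimConfig(n_markers=1200, n_dh_per_cross=10), seed=7)

print(f"founders:        {study.founders.n_lines}")
print(f"families:        {len(study.pedigree.families)}")
print(f"DH lines:        {study.panel.n_lines} x {study.panel.n_markers} SNPs")
frac = study.truth.true_p1_fraction
print(f"true parent-1 contribution: mean {frac.mean():.3f}, sd {frac.std():.3f}")
print(f"phenotype plots: {len(study.phenotypes)} "
      f"({study.phenotypes['year'].nunique()} years x "
      f"{study.phenotypes['block'].nunique()} blocks)")
print(f"per-cross DH success rates: "
      f"{study.success['success_rate_pct'].min():.1f}% - "
      f"{study.success['success_rate_pct'].max():.1f}%")

# The mean contribution sits at 0.5 because meiosis is symmetric between the
# two F1 haplotypes; the spread reflects only ~10 chromosomes of shuffling.
assert abs(frac.mean() - 0.5) < 3 * frac.std() / np.sqrt(len(frac))
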