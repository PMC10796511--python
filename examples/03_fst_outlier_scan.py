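"""Genome-wide Fst scan with Q99 outliers and the sensitivity statistic.

Two comparisons are contrasted on the same panel: a pedigree-based one
(parents vs their DH progeny) and a phenotype-based one (top-2 vs bottom-2
lines per family for a trait).  The sensitivity is the fraction of the
phenotype comparison's Q99 outlier SNPs that the pedigree comparison also
flags — near the 1% tail mass when nothing links the two.
"""

import numpy as np

from dhinducer import (
    SimConfig,
    fit_blue,
    fst_scan,
    nam_partition,
    phenotype_groups,
    q99_outliers,
    sensitivity,
    simulate_study,
)
from dhinducer.fstscan import nam_pedigree_pair
from dhinducer.genodata import GenotypeMatrix
from dhinducer.phenostats import add_derived_traits

study = simulate_study(SimConfig(n_markers=2000, n_dh_per_cross=10), seed=11)
combined = GenotypeMatrix(
    study.founders.line_ids + study.panel.line_ids,
    study.panel.markers,
    np.vstack([study.founders.calls, study.panel.calls]),
)

# nested populations anchored on three reference parents
pops = nam_partition(study.pedigree)
ref, families = next(iter(pops.items()))
ped_pair = nam_pedigree_pair(study.pedigree, ref, families)
ped_scan = fst_scan(combined, ped_pair)
ped_out = q99_outliers(ped_scan)
print(f"pedigree comparison ({ref}): Q99 threshold "
      f"{ped_scan.q99_threshold:.3f}, {len(ped_out)} outlier SNPs")

# phenotype comparison: superior vs inferior DH lines for days to flowering
pheno = add_derived_traits(study.phenotypes)
dhi_recs = pheno[pheno["genotype"].isin(set(study.pedigree.dhi_ids))]
blues = fit_blue(dhi_recs, "DTF").estimates()
pop_dhis = {d for f in families for d in study.pedigree.families[f]}
from dhinducer.genodata import Pedigree

sub = Pedigree([r for r in study.pedigree.records if r[0] in pop_dhis])
pair = phenotype_groups({g: v for g, v in blues.items() if g in pop_dhis}, sub, k=2,
                        trait="DTF")
phe_scan = fst_scan(combined, pair)
phe_out = q99_outliers(phe_scan)
print(f"phenotype comparison (DTF): Q99 threshold "
      f"{phe_scan.q99_threshold:.3f}, {len(phe_out)} outlier SNPs")

s = sensitivity(ped_out, phe_out)
print(f"sensitivity = {s:.3f}  "
      "(fraction of phenotype outliers shared with the pedigree scan; "
      "values < 0.05 mean no systematic allele-frequency shift)")
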