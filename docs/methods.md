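# Methods

This note documents the models behind `dhinducer`, the defaults of the
synthetic-data generator, and the numerical and design choices that were
genuinely open.

## Genotype model and coding

All lines handled by the package — inbred founders and doubled haploid (DH)
progeny — are fully homozygous, so a biallelic SNP call is a single allele
and genotypes are coded per locus as +1 (homozygous for the major allele),
−1 (homozygous minor), 0 (missing). The major allele is the one with
frequency ≥ 0.5 among non-missing calls in the matrix being encoded; an
exact 0.5/0.5 tie goes to the alphabetically first allele so the coding is
reproducible. A heterozygous call in a DH line is evidence of contamination
or a genotyping artifact; the default policy is to raise (naming line and
marker), with `set_missing` available for noisy real data.

The minor-allele-frequency filter reads "less than 5%" strictly: MAF equal
to the threshold is retained. It is applied to whatever matrix is passed in
(the combined parent + progeny panel in the pipeline) and logs which panel
was used, since the choice changes which markers survive. Genotype
imputation is out of scope — the package accepts already-imputed calls and
offers only the explicit per-line missing-data policies described below.

## Parental genome contribution

For a DH line from P1 × P2, only the m loci where the parents carry
different non-missing alleles are informative. The weight vector
β = (x₁−x₂)/((x₁−x₂)′(x₁−x₂)) has entries ±2/(4m) under ±1 coding, and
PGC = x′<sub>DHI</sub>β + 0.5 is then exactly the fraction of informative
loci at which the line matches P1. Consequences used as test oracles:
PGC(x₁) = 1 and PGC(x₂) = 0 exactly; swapping the parent labels maps PGC to
1 − PGC; loci where P1 = P2 carry zero weight. With strict ±1 coding the
estimate cannot leave [0, 1]; if upstream data ever injects other values
the estimate is reported unclamped with a warning rather than truncated,
preserving the diagnostic signal. PGC is always reported as the
contribution of **parent1 as listed in the pedigree record**.

Missing DH calls at informative loci are dropped and β recomputed on the
observed subset (`renormalize`, the default). This keeps the estimator an
unbiased match fraction under missingness at random; `fail` is available
when missingness itself should be fatal. The pooled population summary
(quartiles by type-7 linear interpolation, mean, median) is reported over
all lines by default; because family sizes can differ, a family-equal-weight
variant is also produced and labelled — the two answer different questions
and neither is canonical.

## Fst scan, Q99 outliers, sensitivity

Per SNP, with group frequencies pᵢ of the +1 allele and sizes nᵢ,

Fst = [p̄(1−p̄) − Σ cᵢ pᵢ(1−pᵢ)] / p̄(1−p̄),  cᵢ = nᵢ/Σnⱼ,  p̄ = Σ cᵢ pᵢ.

The weights are proportional to the per-marker genotyped sample sizes and
p̄ is the same weighted mean; this is the classical Nei-style partition and
guarantees Fst ∈ [0, 1] whenever defined (Jensen). A locus monomorphic in
the pooled pair gives 0/0; it is recorded as undefined and excluded from
quantile computation — absence of variation is not evidence of zero
differentiation. Fst is symmetric in the group labels.

Outliers are SNPs strictly above the type-7 99% quantile of the defined
values, computed **per comparison** (each NAM population × basis × trait
has its own threshold); a pooled option exists but per-comparison is the
default because outlier sets are expected to be population-specific. Below
100 defined values the upper quantile is fragile and a warning is emitted.

Group constructors: the pedigree basis contrasts the union of a nested
population's parents with all their DH progeny; the phenotype basis takes
the top-k and bottom-k lines per family (k = 2 by default) ranked by BLUE,
ties broken by lexicographic line id, with the bottom-k drawn from the
remainder after removing the top-k so the groups stay disjoint under heavy
ties; families with fewer than 2k phenotyped lines are skipped with a
warning. Nested populations are anchored on reference parents: each
population is the set of families containing that parent, and a family
whose two parents are both references belongs to both populations — the
only non-lossy assignment, and it is logged.

Sensitivity = |pedigree outliers ∩ phenotype outliers| / |phenotype
outliers|. Under independence of the two comparisons its expectation is the
Q99 tail mass (~0.01), which is the calibration the acceptance checks
verify; observed values below ~0.05 are read as "no systematic
allele-frequency shift associated with the phenotype contrast". The
one-sample, one-sided t-test of mean sensitivity > 0 is reported in two
layouts — per trait with the nested populations as replicates (primary) and
per population with traits as replicates — because either unit of
replication is defensible. A zero-variance sample makes the t statistic
degenerate; the p-value is then reported as its limit (0 for a positive
mean, 1 otherwise) instead of raising.

## Trial statistics

**BLUEs.** The model y = μ + genotype + year + block(year) + ε with all
effects fixed is fitted by OLS (treatment-coded dummies, pseudoinverse for
rank-deficient designs, with a warning since some means may then be
non-estimable). Each genotype's BLUE is its marginal mean: the average of
model predictions over the full year × block grid with equal cell weights —
algebraically identical to the sum-to-zero formulation and verified in
tests by an unbalanced three-plot design whose normal equations solve by
hand to G1 = 12, G2 = 22. On a balanced design this reduces exactly to the
per-genotype arithmetic mean.

**Variance components.** Genotype is random, year and block(year) stay
fixed. For the single-random-effect model V = σ²ε(I + λZZ′) with
λ = σ²g/σ²ε, the restricted likelihood is profiled to a function of λ
alone; (I + λZZ′)⁻¹ is applied in O(n) using the per-genotype block form,
and the profile is minimized by bounded scalar search on log λ (tolerance
1e-10), with the λ = 0 boundary checked explicitly and estimates floored at
zero. Oracles: the balanced one-way closed form σ̂²g = (MS_g − MS_e)/r, and
statsmodels MixedLM as an independent implementation. Constant data
degenerates to σ²g = σ²ε = 0 with H² reported as undefined (NaN).

**Heritability.** H² = σ²g/(σ²g + σ²ε/r) on a plot basis, r the harmonic
mean of per-genotype replicate counts. Monotone in σ²g and in r.

**Derived traits.** HIR = haploid/total kernels ×100, with plots under the
minimum kernel count (default 800, strict) excluded rather than
down-weighted. ASI = DTS − DTF, positive when silking trails pollen shed —
the standard breeding convention, which also makes the expected ASI–success
correlation negative. Success rate = DH lines obtained / haploids
transplanted ×100.

**Tests.** Pearson correlations use the exact t-transform
t = r√(n−2)/√(1−r²). Superior/inferior group comparisons use Welch's
unequal-variance t-test, reporting the difference as inferior − superior.
Tukey letters come from all pairwise comparisons at the studentized-range
critical value q(1−α; k, df)/√2·√(SEᵢ²+SEⱼ²) followed by the
insert-and-absorb compact-letter algorithm: start with one letter covering
all genotypes, split it for every significant pair, discard letter sets
contained in others, label in order of the highest contained mean.
Transgressive flags use strict inequality: a progeny line equalling the
best parent is not transgressive.

## Synthetic-data generator

The generator emulates an elite-by-elite inducer improvement program at
desk scale. Defaults: 8 founders; all 28 half-diallel F1s; 6,636 SNPs
evenly spaced on 10 chromosomes of 170 cM (≈1,700 cM total, the magnitude
of the maize consensus map); 20 DH lines per cross; two years × two blocks;
800 kernels scored per induction plot around a 10% base induction rate; 100
haploids transplanted per cross with mean DH success 13%.

Meiosis is the Haldane model: per chromosome the crossover count is
Poisson(L/100) with i.i.d. uniform positions and a fair starting parent —
no interference, chosen because it is the simplest standard model with
closed-form checks (recombinant fraction (1−e^(−2d/100))/2, verified by
simulation at 1/10/50/100 cM). A DH line is one F1 gamete doubled, so a
single round of recombination separates it from its parents, and every line
is homozygous by construction. Ground truth records crossover positions and
the cM-weighted parent-1 share per line.

Founder allele frequencies are drawn per marker from Uniform(0.1, 0.5) for
the minor allele — a stand-in spectrum, since nothing constrains the real
founders' frequencies; it yields ~30–50% of loci polymorphic within a
typical cross. Phenotypes add, per trait, one planted QTL, a genotype-level
polygenic deviate, fixed year and block-within-year effects, and i.i.d.
plot residuals; trait means and variances are set to magnitudes typical of
an Iowa inducer trial (DTF ≈ 63 d, PHT ≈ 154 cm, PBL ≈ 160 cm, plot-basis
H² in the 0.6–0.9 band). HIR counts are Binomial(kernels, rate) with a
genotype-level rate built from a planted QTL plus noise. Per-cross success
probabilities follow a logistic model centred on the mean success rate with
a negative ASI slope (−0.45 per day) and positive DTF slope (0.12 per day),
reproducing the observed direction of both correlations.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: linkage disequilibrium among founders beyond what
the diallel induces, genotyping error and missingness (the generator emits
complete calls; the missing-data policies are exercised by dedicated unit
fixtures), haploid mis-sorting and selfing contamination, crossover
interference, spatial field trends, and genotype × year interaction. The
acceptance checks therefore validate the estimators' correctness and
calibration, not the field conclusions one would draw from any particular
dataset.

## Problem sizes

Tests run the full stack at the study scale the defaults define (560 DH
lines × 6,636 markers) for the recovery checks, and at reduced scale
(hundreds of markers, a few DH per cross) for structural tests; the
acceptance script uses the full default scale for PGC recovery and the
success-rate correlations, 10,000 gametes per distance for the Haldane
check, 50 replicates of 200 genotypes × 2 reps for REML recovery, and 100
replicate random splits for the null-sensitivity calibration. These sizes
give Monte-Carlo errors comfortably inside the asserted tolerances.

## Known limitations

- PGC assumes the listed parents are the true parents; pedigree errors
  surface only indirectly (values piling near 0.5 with low informative-locus
  counts, or warnings when a "cross" is monomorphic).
- The Fst statistic is the heterozygosity-partition estimator, not
  Weir–Cockerham θ; with the small per-group sizes typical of parent-vs-
  progeny comparisons its null mean is inflated (~1/(2n) per group), which
  is why outlier calling is threshold-based per comparison rather than
  absolute.
- The REML machinery handles exactly one random effect (genotype); crossed
  or nested random designs are out of scope.
- Tukey letters use a greedy insert-and-absorb assignment; like all
  compact-letter displays it is a readable summary, not a substitute for
  the underlying pairwise p-values.
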