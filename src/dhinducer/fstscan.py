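"""Genome-wide Fst outlier scanning between pedigree- and phenotype-defined groups.

The per-SNP statistic is the heterozygosity partition

    Fst = [pbar (1 - pbar) - sum_i c_i p_i (1 - p_i)] / [pbar (1 - pbar)]

where p_i is the +1-allele frequency in group i, c_i = n_i / sum n_j weights
groups by their genotyped sample size at the marker, and pbar = sum c_i p_i
is the pooled frequency.  Because the lines are fully homozygous, line
fractions equal allele fractions.  With size-proportional weights the
statistic is the classical Nei-style partition and lies in [0, 1] whenever
defined; it is undefined (and excluded from quantile computation) at markers
monomorphic in the pooled pair.

Outliers are the SNPs whose Fst strictly exceeds the 99% quantile (type-7)
of the defined values for that comparison.  The *sensitivity* of a
phenotype-based comparison is the fraction of its outlier SNPs that are also
outliers in the corresponding pedigree-based (parents vs progeny)
comparison; values well below 0.05 indicate no systematic allele-frequency
shift tied to the phenotype contrast.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from dhinducer.genodata import MISSING, GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GroupPair:
    """Two disjoint, non-empty groups of line ids to contrast."""

    label: str
    group_a: frozenset[str]
    group_b: frozenset[str]
    basis: str = "pedigree"  # or "phenotype"
    trait: str | None = None
    nam_population: str | None = None

    def __post_init__(self) -> None:
        a = frozenset(self.group_a)
        b = frozenset(self.group_b)
        if not a or not b:
            raise ValueError(f"{self.label}: both groups must be non-empty")
        if a & b:
            raise ValueError(f"{self.label}: groups overlap: {sorted(a & b)}")
        object.__setattr__(self, "group_a", a)
        object.__setattr__(self, "group_b", b)


@dataclass
class FstScan:
    """Per-marker Fst for one comparison, with its outlier call."""

    group_pair: GroupPair
    marker_ids: list[str]
    fst: np.ndarray  # NaN where undefined
    q99_threshold: float | None = None
    outlier_ids: frozenset[str] = field(default_factory=frozenset)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.fst)


@dataclass(frozen=True)
class SensitivityResult:
    trait: str
    per_population: dict[str, float]
    mean_sensitivity: float
    t_statistic: float
    p_value: float


# ---------------------------------------------------------------------------
# Allele frequencies and the Fst statistic
# ---------------------------------------------------------------------------


def allele_freq(calls: np.ndarray) -> tuple[float, int]:
    """(+1-allele frequency, non-missing count) for one group at one marker.

    Lines are homozygous, so the fraction of +1 lines equals the allele
    frequency.  Raises if every call is missing.
    """
    calls = np.asarray(calls)
    nonmiss = calls != MISSING
    n = int(nonmiss.sum())
    if n == 0:
        raise ValueError("all calls missing: frequency undefined for this group")
    return float((calls[nonmiss] == 1).mean()), n


def fst_snp(freqs, sizes) -> float:
    """Single-marker Fst from per-group frequencies and sample sizes.

    Returns NaN (undefined) when the pooled frequency is 0 or 1 — a locus
    monomorphic across both groups carries no differentiation information.
    """
    p = np.asarray(freqs, dtype=float)
    n = np.asarray(sizes, dtype=float)
    if p.size < 2:
        raise ValueError("need at least two groups")
    if n.shape != p.shape or (n <= 0).any():
        raise ValueError("sizes must be positive and match freqs")
    c = n / n.sum()
    pbar = float(c @ p)
    het_total = pbar * (1.0 - pbar)
    if het_total == 0.0:
        return float("nan")
    het_within = float(c @ (p * (1.0 - p)))
    return (het_total - het_within) / het_total


def fst_scan(panel: GenotypeMatrix, pair: GroupPair) -> FstScan:
    """Vectorized per-marker Fst for one two-group comparison.

    Markers where either group has no genotyped line, or where the pooled
    pair is monomorphic, are recorded as undefined (NaN).
    """
    missing_ids = (pair.group_a | pair.group_b) - set(panel.line_ids)
    if missing_ids:
        raise KeyError(f"{pair.label}: ids absent from panel: {sorted(missing_ids)}")
    fst = np.full(panel.n_markers, np.nan)
    pa, na = _group_freqs(panel, sorted(pair.group_a))
    pb, nb = _group_freqs(panel, sorted(pair.group_b))
    ok = (na > 0) & (nb > 0)
    ca = na[ok] / (na[ok] + nb[ok])
    cb = 1.0 - ca
    pbar = ca * pa[ok] + cb * pb[ok]
    het_total = pbar * (1.0 - pbar)
    het_within = ca * pa[ok] * (1 - pa[ok]) + cb * pb[ok] * (1 - pb[ok])
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(het_total > 0, (het_total - het_within) / het_total, np.nan)
    fst[ok] = vals
    return FstScan(pair, panel.marker_ids, fst)


def _group_freqs(panel: GenotypeMatrix, ids: list[str]) -> tuple[np.ndarray, np.ndarray]:
    calls = panel.subset_lines(ids).calls
    nonmiss = (calls != MISSING).sum(axis=0).astype(float)
    plus = (calls == 1).sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nonmiss > 0, plus / np.maximum(nonmiss, 1), np.nan)
    return p, nonmiss


def q99_outliers(scan: FstScan, q: float = 0.99) -> frozenset[str]:
    """Call outliers strictly above the type-7 ``q`` quantile of defined Fst.

    The threshold and the outlier id set are written back onto ``scan``.
    Fewer than 100 defined values makes the upper quantile fragile; a
    warning is emitted.
    """
    vals = scan.fst[scan.defined]
    if vals.size == 0:
        raise ValueError(f"{scan.group_pair.label}: no defined Fst values")
    if vals.size < 100:
        warnings.warn(
            f"{scan.group_pair.label}: only {vals.size} defined Fst values; "
            "the upper quantile threshold is unstable"
        )
    threshold = float(np.quantile(vals, q))
    ids = frozenset(
        mid
        for mid, v, ok in zip(scan.marker_ids, scan.fst, scan.defined)
        if ok and v > threshold
    )
    scan.q99_threshold = threshold
    scan.outlier_ids = ids
    return ids


# ---------------------------------------------------------------------------
# Group constructors
# ---------------------------------------------------------------------------


def phenotype_groups(
    blues: dict[str, float],
    pedigree: Pedigree,
    k: int = 2,
    trait: str | None = None,
    label: str | None = None,
    nam_population: str | None = None,
) -> GroupPair:
    """Superior (top-k per family) vs inferior (bottom-k per family) lines.

    ``blues`` maps genotype id to its trait value (typically a BLUE).
    Families with fewer than 2k phenotyped lines are skipped with a warning.
    Ties are broken by lexicographic line id; the bottom-k are drawn from
    the lines left after removing the top-k so the groups stay disjoint
    even under heavy ties.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    top: set[str] = set()
    bottom: set[str] = set()
    for fam, members in sorted(pedigree.families.items()):
        scored = sorted(
            (m for m in members if m in blues and np.isfinite(blues[m])),
            key=lambda m: (-blues[m], m),
        )
        if len(scored) < 2 * k:
            warnings.warn(f"family {fam}: only {len(scored)} phenotyped lines; skipped")
            continue
        chosen_top = scored[:k]
        rest = sorted(scored[k:], key=lambda m: (blues[m], m))
        top.update(chosen_top)
        bottom.update(rest[:k])
    if not top or not bottom:
        raise ValueError("no family large enough to form top/bottom groups")
    return GroupPair(
        label or f"superior-vs-inferior:{trait or 'trait'}",
        frozenset(top),
        frozenset(bottom),
        basis="phenotype",
        trait=trait,
        nam_population=nam_population,
    )


def pedigree_groups(
    pedigree: Pedigree,
    parents: set[str],
    progeny: set[str],
    label: str | None = None,
    nam_population: str | None = None,
) -> GroupPair:
    """Parents vs their DH progeny (the pedigree-based comparison)."""
    if set(parents) & set(progeny):
        raise ValueError(f"parents and progeny overlap: {sorted(set(parents) & set(progeny))}")
    return GroupPair(
        label or "parents-vs-progeny",
        frozenset(parents),
        frozenset(progeny),
        basis="pedigree",
        nam_population=nam_population,
    )


def nam_partition(
    pedigree: Pedigree, reference_lines: list[str] | None = None
) -> dict[str, list[str]]:
    """Nested (NAM-style) populations anchored on reference parents.

    Each population is the set of families in which the reference line is a
    parent; a family whose parents are both reference lines appears in both
    populations (the only non-lossy assignment), which is logged.
    Returns {reference line: [family ids]}.
    """
    refs = reference_lines or pedigree.reference_lines
    if not refs:
        raise ValueError("no reference lines given or recorded in the pedigree")
    fam_parents = pedigree.family_parents
    pops: dict[str, list[str]] = {}
    for ref in refs:
        fams = sorted(f for f, (p1, p2) in fam_parents.items() if ref in (p1, p2))
        if not fams:
            raise ValueError(f"reference line {ref} appears in no family")
        pops[ref] = fams
    for fam, (p1, p2) in fam_parents.items():
        if p1 in refs and p2 in refs:
            logger.info("family %s involves two reference lines; assigned to both", fam)
    return pops


def nam_pedigree_pair(
    pedigree: Pedigree, reference: str, families: list[str]
) -> GroupPair:
    """Parents-vs-progeny pair for one nested population."""
    fam_parents = pedigree.family_parents
    parents = {p for f in families for p in fam_parents[f]}
    fams = pedigree.families
    progeny = {d for f in families for d in fams[f]}
    return pedigree_groups(
        pedigree, parents, progeny,
        label=f"parents-vs-progeny:{reference}", nam_population=reference,
    )


# ---------------------------------------------------------------------------
# Sensitivity
# ---------------------------------------------------------------------------


def sensitivity(
    outliers_pedigree: frozenset[str] | set[str],
    outliers_phenotype: frozenset[str] | set[str],
) -> float:
    """Fraction of phenotype-based outlier SNPs also found pedigree-based."""
    phe = set(outliers_phenotype)
    if not phe:
        raise ValueError("phenotype outlier set is empty: sensitivity undefined")
    return len(set(outliers_pedigree) & phe) / len(phe)


def sensitivity_test(values, trait: str = "") -> SensitivityResult:
    """One-sample, one-sided t-test that the mean sensitivity exceeds zero.

    ``values`` maps population label to sensitivity (or is a plain sequence).
    With zero variance the t statistic degenerates; the p-value is reported
    as its limit (0 for a positive mean, 1 otherwise) rather than raising.
    """
    if isinstance(values, dict):
        per_pop = dict(values)
    else:
        per_pop = {f"pop{i + 1}": v for i, v in enumerate(values)}
    v = np.asarray(list(per_pop.values()), dtype=float)
    if v.size < 2:
        raise ValueError("need at least two sensitivities to test")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if sd <= 1e-12 * max(1.0, abs(mean)):
        t = float("inf") if mean > 0 else 0.0
        p = 0.0 if mean > 0 else 1.0
    else:
        t, p = stats.ttest_1samp(v, 0.0, alternative="greater")
        t, p = float(t), float(p)
    return SensitivityResult(trait, per_pop, mean, t, p)


def scan_table(scans: list[FstScan], panel: GenotypeMatrix):
    """Tidy per-marker table over comparisons (marker, chrom, pos, fst, outlier)."""
    import pandas as pd

    chrom = {m.id: m.chromosome for m in panel.markers}
    pos = {m.id: m.position_bp for m in panel.markers}
    rows = []
    for scan in scans:
        for mid, v in zip(scan.marker_ids, scan.fst):
            rows.append(
                {
                    "comparison": scan.group_pair.label,
                    "marker": mid,
                    "chrom": chrom[mid],
                    "pos": pos[mid],
                    "fst": v,
                    "is_outlier": mid in scan.outlier_ids,
                }
            )
    return pd.DataFrame(rows)


def plot_scan(scan: FstScan, path) -> None:
    """Manhattan-style plot of one comparison (markers in map order)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(len(scan.fst))
    ax.scatter(x, scan.fst, s=4, c="steelblue")
    if scan.q99_threshold is not None:
        ax.axhline(scan.q99_threshold, ls="--", c="grey", lw=1)
        out = np.array([m in scan.outlier_ids for m in scan.marker_ids])
        ax.scatter(x[out], scan.fst[out], s=10, c="crimson", marker="x")
    ax.set_xlabel("marker index")
    ax.set_ylabel("Fst")
    ax.set_title(scan.group_pair.label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
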