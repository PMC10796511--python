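"""Parental genome contribution (PGC) of doubled haploid progeny.

For a DH line from the cross P1 x P2 with coded genotype vector x_DHI, the
contribution of parent 1 is estimated by projecting x_DHI onto the parent
difference direction over the loci where the parents differ:

    beta = (x1 - x2) / ((x1 - x2)' (x1 - x2))
    PGC  = x_DHI' beta + 0.5

With +/-1 coding every polymorphic locus contributes weight +/-2 / (4 m)
(m informative loci), so PGC is the fraction of informative loci at which
the DH line matches parent 1.  PGC(x1) = 1 and PGC(x2) = 0 exactly, and
swapping the parent labels maps PGC to 1 - PGC.

PGC is reported as the contribution of parent1 *as listed in the pedigree
record*.  Values outside [0, 1] are possible if a line carries calls that
match neither parent (e.g. genotyping error) and are reported unclamped,
with a warning, to preserve the diagnostic signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dhinducer.genodata import MISSING, GenotypeMatrix, Pedigree, polymorphic_loci


class DegenerateCrossError(ValueError):
    """The two parents share every genotyped allele: PGC is undefined."""


@dataclass(frozen=True)
class PGCResult:
    dhi_id: str
    family_id: str
    parent1: str
    parent2: str
    n_informative_loci: int
    pgc: float

    def __post_init__(self) -> None:
        if self.n_informative_loci < 1:
            raise ValueError("n_informative_loci must be >= 1")
        if not np.isfinite(self.pgc):
            raise ValueError("pgc must be finite")


def compute_beta(x1: np.ndarray, x2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Projection weights onto the parent-difference direction.

    Returns ``(beta, loci)`` where ``loci`` are the indices of loci
    polymorphic between the parents (both non-missing, different calls) and
    ``beta`` holds one weight per such locus.
    """
    loci = polymorphic_loci(x1, x2)
    if len(loci) == 0:
        raise DegenerateCrossError("parents are identical at every genotyped locus")
    d = (np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float))[loci]
    return d / (d @ d), loci


def compute_pgc(
    x_dhi: np.ndarray,
    x1: np.ndarray,
    x2: np.ndarray,
    missing_policy: str = "renormalize",
) -> tuple[float, int]:
    """PGC of one DH line against its parent pair.

    Returns ``(pgc, n_informative_loci)``.  With
    ``missing_policy="renormalize"`` (default), loci missing in the DH line
    are dropped and the weights recomputed on the observed polymorphic
    subset, keeping the estimator unbiased under missingness at random;
    ``"fail"`` raises on any missing informative call.
    """
    if missing_policy not in ("renormalize", "fail"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    _beta, loci = compute_beta(x1, x2)
    x = np.asarray(x_dhi)
    if x.shape != np.asarray(x1).shape:
        raise ValueError("DH vector not aligned with parent vectors")
    observed = x[loci] != MISSING
    if missing_policy == "fail" and not observed.all():
        raise ValueError("DH line has missing calls at informative loci")
    loci = loci[observed]
    if len(loci) == 0:
        raise ValueError("all informative loci are missing in the DH line")
    d = (np.asarray(x1, dtype=float) - np.asarray(x2, dtype=float))[loci]
    beta = d / (d @ d)
    pgc = float(x[loci].astype(float) @ beta + 0.5)
    if pgc < -1e-9 or pgc > 1.0 + 1e-9:
        warnings.warn(
            f"PGC {pgc:.4f} outside [0, 1]: line carries alleles matching "
            "neither parent at some loci (possible genotyping error)"
        )
    return pgc, int(len(loci))


def pgc_panel(
    panel: GenotypeMatrix,
    parents: GenotypeMatrix,
    pedigree: Pedigree,
    missing_policy: str = "renormalize",
) -> list[PGCResult]:
    """PGC for every DH line in the pedigree, each against its own family's
    polymorphic loci."""
    missing_parents = sorted(
        {p for _d, p1, p2, _f in pedigree.records for p in (p1, p2)}
        - set(parents.line_ids)
    )
    missing_dhis = sorted(set(pedigree.dhi_ids) - set(panel.line_ids))
    if missing_parents or missing_dhis:
        raise KeyError(
            f"ids absent from genotype matrices: parents={missing_parents}, "
            f"DHIs={missing_dhis}"
        )
    results = []
    for dhi, p1, p2, fam in pedigree.records:
        pgc, n_loci = compute_pgc(
            panel.row(dhi), parents.row(p1), parents.row(p2), missing_policy
        )
        results.append(PGCResult(dhi, fam, p1, p2, n_loci, pgc))
    return results


def pgc_summary(
    results: list[PGCResult], by_family: bool = False
) -> dict[str, float] | pd.DataFrame:
    """Quartiles (type-7 linear interpolation), median and mean of PGC.

    Pooled over all lines by default; ``by_family=True`` returns one row per
    family plus a family-equal-weight overall row, since pooled and
    family-weighted summaries differ when family sizes do.
    """
    if not results:
        raise ValueError("no PGC results to summarize")
    df = pd.DataFrame(
        {"family_id": [r.family_id for r in results], "pgc": [r.pgc for r in results]}
    )

    def _stats(v: np.ndarray) -> dict[str, float]:
        return {
            "q25": float(np.quantile(v, 0.25)),
            "median": float(np.quantile(v, 0.5)),
            "mean": float(np.mean(v)),
            "q75": float(np.quantile(v, 0.75)),
            "n": int(len(v)),
        }

    if not by_family:
        return _stats(df["pgc"].to_numpy())
    rows = [{"family_id": fam, **_stats(g["pgc"].to_numpy())}
            for fam, g in df.groupby("family_id", sort=True)]
    fam_means = [r["mean"] for r in rows]
    rows.append(
        {
            "family_id": "__overall_family_weighted__",
            "q25": float(np.quantile(fam_means, 0.25)),
            "median": float(np.quantile(fam_means, 0.5)),
            "mean": float(np.mean(fam_means)),
            "q75": float(np.quantile(fam_means, 0.75)),
            "n": len(fam_means),
        }
    )
    return pd.DataFrame(rows)


def pgc_table(results: list[PGCResult]) -> pd.DataFrame:
    """Results as a tidy table (dhi_id, family_id, parents, loci, pgc)."""
    return pd.DataFrame(
        {
            "dhi_id": [r.dhi_id for r in results],
            "family_id": [r.family_id for r in results],
            "parent1": [r.parent1 for r in results],
            "parent2": [r.parent2 for r in results],
            "n_informative_loci": [r.n_informative_loci for r in results],
            "pgc": [r.pgc for r in results],
        }
    )
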