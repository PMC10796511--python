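"""End-to-end orchestration: simulate a study, analyze it, summarize it.

``run_simulate`` writes a complete synthetic study to disk (HapMap + VCF
genotypes, phenotype CSV, pedigree CSV, ground-truth TSV, manifest);
``run_analyze`` reads those files (or any real data in the same formats) and
executes the full analysis — MAF filter, parental genome contribution, BLUEs
and heritability, the nested-population Fst scans with Q99 outliers and
sensitivities, transgressive-segregation and correlation reports — writing
every table as TSV with a manifest of the parameters used.  ``run_report``
renders a bundle into a human-readable summary.

The in-memory entry point :func:`analyze_study` is the library API the file
commands wrap; every stage can equally be called on its own.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dhinducer import __version__
from dhinducer.genodata import (
    GenotypeMatrix,
    Pedigree,
    encode_genotypes,
    filter_maf,
    read_hapmap,
    read_pedigree,
    read_vcf,
    write_hapmap,
    write_vcf,
)
from dhinducer.fstscan import (
    FstScan,
    nam_partition,
    nam_pedigree_pair,
    phenotype_groups,
    fst_scan,
    q99_outliers,
    scan_table,
    sensitivity,
    sensitivity_test,
)
from dhinducer.pgc import pgc_panel, pgc_summary, pgc_table
from dhinducer.phenostats import (
    add_derived_traits,
    fit_blue,
    group_mean_test,
    pearson_test,
    transgressive_summary,
    variance_components,
)
from dhinducer.simulate import SimConfig, simulate_study

logger = logging.getLogger(__name__)

DEFAULT_TRAITS = ("DTF", "HIR", "PHT", "PBL")


@dataclass
class AnalysisParams:
    """Knobs of the analysis pipeline with study defaults."""

    maf_threshold: float = 0.05
    q: float = 0.99
    top_k: int = 2
    traits: tuple[str, ...] = DEFAULT_TRAITS
    min_kernels: int = 800
    het_policy: str = "error"
    reference_lines: tuple[str, ...] = ()


@dataclass
class AnalysisResult:
    """All tables the analyze stage produces."""

    params: AnalysisParams
    n_markers_input: int
    n_markers_after_maf: int
    pgc: pd.DataFrame
    pgc_summary: dict
    blues: dict[str, object]  # trait -> BLUETable (DHIs)
    parent_blues: dict[str, object]
    variance: pd.DataFrame
    scans: list[FstScan] = field(default_factory=list)
    sensitivity_by_trait: pd.DataFrame | None = None
    sensitivity_by_population: pd.DataFrame | None = None
    transgressive: pd.DataFrame | None = None
    group_tests: pd.DataFrame | None = None
    correlations: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# simulate -> files
# ---------------------------------------------------------------------------


def run_simulate(outdir, cfg: SimConfig | None = None, seed: int | None = None):
    """Generate a synthetic study and write it as analysis-ready files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    study = simulate_study(cfg, seed=seed)

    combined = GenotypeMatrix(
        study.founders.line_ids + study.panel.line_ids,
        study.panel.markers,
        np.vstack([study.founders.calls, study.panel.calls]),
    )
    write_hapmap(combined, out / "genotypes.hmp.txt")
    write_vcf(combined, out / "genotypes.vcf")
    study.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    pd.DataFrame(
        [(d, p1, p2) for d, p1, p2, _f in study.pedigree.records],
        columns=["dhi_id", "parent1", "parent2"],
    ).to_csv(out / "pedigree.csv", index=False)
    truth = pd.DataFrame(
        {
            "dhi_id": study.truth.dhi_ids,
            "parent1": study.truth.parent1_ids,
            "parent2": study.truth.parent2_ids,
            "true_p1_fraction": study.truth.true_p1_fraction,
        }
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    study.truth.genetic_values.to_csv(out / "truth_genetic_values.tsv", sep="\t")
    study.success.to_csv(out / "f1_success.csv", index=False)
    cfg_used = study.config
    _write_manifest(
        out,
        stage="simulate",
        seed=cfg_used.seed,
        params={
            "n_founders": cfg_used.n_founders,
            "n_markers": cfg_used.n_markers,
            "n_dh_per_cross": cfg_used.n_dh_per_cross,
            "reference_lines": list(study.pedigree.reference_lines),
        },
    )
    return study


# ---------------------------------------------------------------------------
# analyze
# ---------------------------------------------------------------------------


def analyze_study(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    phenotypes: pd.DataFrame,
    params: AnalysisParams | None = None,
    f1_success: pd.DataFrame | None = None,
) -> AnalysisResult:
    """Run the full analysis on an in-memory dataset.

    ``genotypes`` holds parents and DH progeny together; the pedigree tells
    them apart.  Stages degrade gracefully: a trait with no phenotype column
    is skipped with a warning, and correlation reports only appear when a
    per-cross success table is supplied.
    """
    params = params or AnalysisParams()
    parent_ids = sorted({p for _d, p1, p2, _f in pedigree.records for p in (p1, p2)})
    n_input = genotypes.n_markers
    logger.info("MAF filter applied to the combined parent+DHI panel")
    filtered = filter_maf(genotypes, params.maf_threshold)
    parents = filtered.subset_lines([p for p in parent_ids if p in filtered.line_ids])
    panel = filtered.subset_lines([d for d in pedigree.dhi_ids if d in filtered.line_ids])

    # --- parental genome contribution
    results = pgc_panel(panel, parents, pedigree)
    pgc_df = pgc_table(results)
    pgc_sum = pgc_summary(results)

    # --- derived traits + BLUEs + variance components
    pheno = add_derived_traits(phenotypes, min_kernels=params.min_kernels)
    dhi_set = set(pedigree.dhi_ids)
    blues: dict[str, object] = {}
    parent_blues: dict[str, object] = {}
    var_rows = []
    for trait in params.traits:
        if trait not in pheno.columns or pheno[trait].dropna().empty:
            logger.warning("trait %s missing from phenotypes; skipped", trait)
            continue
        dhi_recs = pheno[pheno["genotype"].isin(dhi_set)]
        if not dhi_recs[trait].dropna().empty:
            blues[trait] = fit_blue(dhi_recs, trait)
            vc = variance_components(dhi_recs, trait)
            var_rows.append(
                {
                    "trait": trait,
                    "sigma_g2": vc.sigma_g2,
                    "sigma_e2": vc.sigma_e2,
                    "r_harmonic": vc.r_harmonic,
                    "H2": vc.H2,
                }
            )
        par_recs = pheno[pheno["genotype"].isin(parent_ids)]
        if not par_recs[trait].dropna().empty:
            parent_blues[trait] = fit_blue(par_recs, trait)
    variance = pd.DataFrame(var_rows)

    # --- nested populations, Fst scans, outliers, sensitivities
    refs = list(params.reference_lines) or pedigree.reference_lines or parent_ids[:3]
    pops = nam_partition(pedigree, refs)
    fams = pedigree.families
    scans: list[FstScan] = []
    sens_rows = []
    for ref, fam_list in pops.items():
        ped_pair = nam_pedigree_pair(pedigree, ref, fam_list)
        ped_scan = fst_scan(filtered, ped_pair)
        ped_out = q99_outliers(ped_scan, params.q)
        scans.append(ped_scan)
        pop_dhis = {d for f in fam_list for d in fams[f]}
        sub_ped = Pedigree(
            [r for r in pedigree.records if r[0] in pop_dhis], pedigree.reference_lines
        )
        for trait, bt in blues.items():
            est = {g: v for g, v in bt.estimates().items() if g in pop_dhis}
            try:
                pair = phenotype_groups(
                    est, sub_ped, k=params.top_k, trait=trait,
                    label=f"superior-vs-inferior:{trait}:{ref}", nam_population=ref,
                )
            except ValueError as exc:
                logger.warning("population %s trait %s: %s", ref, trait, exc)
                continue
            scan = fst_scan(filtered, pair)
            phe_out = q99_outliers(scan, params.q)
            scans.append(scan)
            sens_rows.append(
                {
                    "nam_population": ref,
                    "trait": trait,
                    "n_outliers_pedigree": len(ped_out),
                    "n_outliers_phenotype": len(phe_out),
                    "sensitivity": sensitivity(ped_out, phe_out) if phe_out else np.nan,
                }
            )
    sens = pd.DataFrame(sens_rows)
    sens_by_trait = sens_by_pop = None
    if not sens.empty:
        sens_by_trait = _sensitivity_layout(sens, "trait", "nam_population")
        sens_by_pop = _sensitivity_layout(sens, "nam_population", "trait")

    # --- transgressive segregation + superior/inferior mean tests
    trans_rows, test_rows = [], []
    for trait, bt in blues.items():
        if trait in parent_blues:
            rep = transgressive_summary(parent_blues[trait], bt, trait)
            trans_rows.append(
                {
                    "trait": trait,
                    "min_parents": rep.parent_min,
                    "max_parents": rep.parent_max,
                    "min_dhis": rep.dhi_min,
                    "max_dhis": rep.dhi_max,
                    "high_transgressive": rep.high_transgressive,
                    "low_transgressive": rep.low_transgressive,
                }
            )
        est = bt.estimates()
        try:
            pair = phenotype_groups(est, pedigree, k=params.top_k, trait=trait)
        except ValueError:
            continue
        res = group_mean_test(
            [est[g] for g in sorted(pair.group_a)], [est[g] for g in sorted(pair.group_b)]
        )
        test_rows.append({"trait": trait, **res})
    transgressive = pd.DataFrame(trans_rows) if trans_rows else None
    group_tests = pd.DataFrame(test_rows) if test_rows else None

    # --- success-rate correlations with F1 donor traits
    correlations = None
    if f1_success is not None and "success_rate_pct" in f1_success.columns:
        corr_rows = []
        for covar in ("ASI", "DTF"):
            if covar in f1_success.columns:
                r, p = pearson_test(f1_success[covar], f1_success["success_rate_pct"])
                corr_rows.append(
                    {"pair": f"{covar} vs success rate", "r": r, "p_value": p,
                     "n": len(f1_success)}
                )
        correlations = pd.DataFrame(corr_rows)

    return AnalysisResult(
        params=params,
        n_markers_input=n_input,
        n_markers_after_maf=filtered.n_markers,
        pgc=pgc_df,
        pgc_summary=pgc_sum,
        blues=blues,
        parent_blues=parent_blues,
        variance=variance,
        scans=scans,
        sensitivity_by_trait=sens_by_trait,
        sensitivity_by_population=sens_by_pop,
        transgressive=transgressive,
        group_tests=group_tests,
        correlations=correlations,
    )


def _sensitivity_layout(sens: pd.DataFrame, unit: str, replicate: str) -> pd.DataFrame:
    """t-test of mean sensitivity > 0 with ``replicate`` as the replicates."""
    rows = []
    for key, g in sens.dropna(subset=["sensitivity"]).groupby(unit, sort=True):
        vals = dict(zip(g[replicate], g["sensitivity"]))
        if len(vals) < 2:
            rows.append({unit: key, "mean_sensitivity": float(np.mean(list(vals.values()))),
                         "t": np.nan, "p_value": np.nan, "n_replicates": len(vals)})
            continue
        res = sensitivity_test(vals, trait=str(key))
        rows.append(
            {unit: key, "mean_sensitivity": res.mean_sensitivity,
             "t": res.t_statistic, "p_value": res.p_value, "n_replicates": len(vals)}
        )
    return pd.DataFrame(rows)


def run_analyze(
    indir,
    outdir,
    params: AnalysisParams | None = None,
    genotype_format: str = "hapmap",
) -> AnalysisResult:
    """File-based analyze: read a study directory, write the report bundle."""
    indir, out = Path(indir), Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or AnalysisParams()
    if genotype_format == "hapmap":
        raw = read_hapmap(indir / "genotypes.hmp.txt")
    elif genotype_format == "vcf":
        raw = read_vcf(indir / "genotypes.vcf")
    else:
        raise ValueError(f"unknown genotype_format {genotype_format!r}")
    genotypes = encode_genotypes(raw, het_policy=params.het_policy)
    pedigree = read_pedigree(indir / "pedigree.csv", list(params.reference_lines) or None)
    phenotypes = pd.read_csv(indir / "phenotypes.csv")
    f1_success = None
    if (indir / "f1_success.csv").exists():
        f1_success = pd.read_csv(indir / "f1_success.csv")

    result = analyze_study(genotypes, pedigree, phenotypes, params, f1_success)

    result.pgc.to_csv(out / "pgc.tsv", sep="\t", index=False)
    pd.DataFrame([result.pgc_summary]).to_csv(out / "pgc_summary.tsv", sep="\t", index=False)
    for trait, bt in result.blues.items():
        bt.table.to_csv(out / f"blues_{trait}.tsv", sep="\t", index=False)
    result.variance.to_csv(out / "variance_components.tsv", sep="\t", index=False)
    if result.scans:
        scan_table(result.scans, genotypes).to_csv(out / "fst_scans.tsv", sep="\t", index=False)
    for name, df in (
        ("sensitivity_by_trait", result.sensitivity_by_trait),
        ("sensitivity_by_population", result.sensitivity_by_population),
        ("transgressive", result.transgressive),
        ("group_tests", result.group_tests),
        ("correlations", result.correlations),
    ):
        if df is not None:
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False)
    _write_manifest(
        out,
        stage="analyze",
        seed=None,
        params={
            "maf_threshold": params.maf_threshold,
            "q": params.q,
            "top_k": params.top_k,
            "traits": list(params.traits),
            "min_kernels": params.min_kernels,
            "n_markers_input": result.n_markers_input,
            "n_markers_after_maf": result.n_markers_after_maf,
        },
    )
    return result


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


def run_report(bundle_dir) -> str:
    """Human-readable summary of an analyze bundle (gaps flagged, not fatal)."""
    b = Path(bundle_dir)
    lines = ["DH inducer analysis summary", "=" * 29]

    def _read(name):
        p = b / name
        return pd.read_csv(p, sep="\t") if p.exists() else None

    pg = _read("pgc_summary.tsv")
    if pg is not None:
        r = pg.iloc[0]
        lines.append(
            f"Parental genome contribution (n={int(r['n'])}): "
            f"Q25={r['q25']:.2f}  median={r['median']:.2f}  "
            f"mean={r['mean']:.2f}  Q75={r['q75']:.2f}"
        )
    else:
        lines.append("Parental genome contribution: not computed")

    vc = _read("variance_components.tsv")
    if vc is not None:
        lines.append("Heritability (plot basis):")
        for _i, r in vc.iterrows():
            lines.append(
                f"  {r['trait']}: H2={r['H2']:.2f} "
                f"(sigma_g2={r['sigma_g2']:.3g}, sigma_e2={r['sigma_e2']:.3g}, "
                f"r={r['r_harmonic']:.2f})"
            )
    else:
        lines.append("Variance components: not computed")

    tr = _read("transgressive.tsv")
    if tr is not None:
        lines.append("Trait ranges (parents vs DH progeny):")
        for _i, r in tr.iterrows():
            flags = []
            if r["high_transgressive"]:
                flags.append("high")
            if r["low_transgressive"]:
                flags.append("low")
            lines.append(
                f"  {r['trait']}: parents [{r['min_parents']:.2f}, {r['max_parents']:.2f}]"
                f"  DHIs [{r['min_dhis']:.2f}, {r['max_dhis']:.2f}]"
                f"  transgressive: {'+'.join(flags) or 'none'}"
            )

    se = _read("sensitivity_by_trait.tsv")
    if se is not None:
        lines.append("Fst outlier sensitivity (pedigree vs phenotype, per trait):")
        for _i, r in se.iterrows():
            lines.append(
                f"  {r['trait']}: mean={r['mean_sensitivity']:.3f} "
                f"(t={r['t']:.2f}, p={r['p_value']:.3f})"
            )
    else:
        lines.append("Fst sensitivity: not computed")

    co = _read("correlations.tsv")
    if co is not None:
        lines.append("Success-rate correlations:")
        for _i, r in co.iterrows():
            lines.append(f"  {r['pair']}: r={r['r']:.2f} (p={r['p_value']:.3f}, n={int(r['n'])})")

    return "\n".join(lines)


def _write_manifest(outdir: Path, stage: str, seed, params: dict) -> None:
    payload = {"stage": stage, "version": __version__, "seed": seed, "params": params}
    payload["config_hash"] = hashlib.sha256(
        json.dumps(params, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
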