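"""Synthetic doubled-haploid inducer study generator.

Emulates the structure of a DH-inducer development program: a set of fully
homozygous founder inducers, half-diallel F1 combinations, DH progeny each
fixed from a single F1 meiosis, plot-level trait records over a
years x blocks trial, binomial haploid-induction kernel counts, and per-cross
DH production success rates driven by flowering traits of the F1 donor.

Meiosis follows the Haldane (no-interference) model: per chromosome the
crossover count is Poisson with mean ``length_cM / 100`` and crossover
positions are i.i.d. uniform.  Every simulated line therefore carries exact
ground truth — crossover positions, centimorgan-weighted parental
contribution, genetic values — against which the estimators in the other
modules can be validated.

All randomness flows through explicit :class:`numpy.random.Generator`
streams seeded from ``SimConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from dhinducer.genodata import GenotypeMatrix, Marker, Pedigree

# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChromosomeMap:
    name: str
    length_cM: float
    marker_pos_cM: np.ndarray  # ascending, within [0, length_cM]

    def __post_init__(self) -> None:
        pos = np.asarray(self.marker_pos_cM, dtype=float)
        if len(pos) < 1:
            raise ValueError(f"{self.name}: at least one marker required")
        if (np.diff(pos) < 0).any():
            raise ValueError(f"{self.name}: marker positions must be ascending")
        if pos.min() < 0 or (self.length_cM > 0 and pos.max() > self.length_cM):
            raise ValueError(f"{self.name}: marker positions outside [0, length]")
        object.__setattr__(self, "marker_pos_cM", pos)


@dataclass(frozen=True)
class GeneticMap:
    """Ordered chromosomes with marker positions in centimorgans."""

    chromosomes: tuple[ChromosomeMap, ...]

    @property
    def n_markers(self) -> int:
        return sum(len(c.marker_pos_cM) for c in self.chromosomes)

    @property
    def total_length_cM(self) -> float:
        return float(sum(c.length_cM for c in self.chromosomes))

    def markers(self, bp_per_cM: float = 1e6) -> list[Marker]:
        """Marker objects with synthetic base-pair coordinates (1-based)."""
        out = []
        for c in self.chromosomes:
            for i, cm in enumerate(c.marker_pos_cM):
                out.append(
                    Marker(
                        id=f"{c.name}_m{i + 1}",
                        chromosome=c.name,
                        position_bp=int(round(cm * bp_per_cM)) + 1,
                        position_cM=float(cm),
                    )
                )
        return out

    def chromosome_slices(self) -> list[tuple[ChromosomeMap, slice]]:
        out, start = [], 0
        for c in self.chromosomes:
            k = len(c.marker_pos_cM)
            out.append((c, slice(start, start + k)))
            start += k
        return out


def maize_like_map(
    n_chromosomes: int = 10, length_cM: float = 170.0, n_markers: int = 6636
) -> GeneticMap:
    """Evenly spaced markers on equal-length chromosomes (maize-scale default).

    10 chromosomes of 170 cM give a ~1700 cM genome, the magnitude of the
    maize consensus map; markers are split as evenly as possible.
    """
    base, extra = divmod(n_markers, n_chromosomes)
    chroms = []
    for i in range(n_chromosomes):
        k = base + (1 if i < extra else 0)
        pos = np.linspace(0.0, length_cM, k) if k > 1 else np.array([length_cM / 2])
        chroms.append(ChromosomeMap(f"chr{i + 1}", length_cM, pos))
    return GeneticMap(tuple(chroms))


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TraitSpec:
    """Generative model for one quantitative trait.

    Plot value = mean + QTL effects + polygenic deviate (per genotype)
    + year effect + block-within-year effect + residual.
    """

    name: str
    mean: float
    qtl: tuple[tuple[int, float], ...]  # (marker index, additive effect)
    polygenic_var: float
    residual_var: float
    year_effects: tuple[float, ...] = (0.0, 0.0)
    block_effects: tuple[tuple[float, ...], ...] = ((0.0, 0.0), (0.0, 0.0))

    def __post_init__(self) -> None:
        if self.polygenic_var < 0 or self.residual_var < 0:
            raise ValueError(f"{self.name}: variances must be >= 0")
        if len(self.block_effects) != len(self.year_effects):
            raise ValueError(f"{self.name}: block_effects must nest within years")


def _default_traits(n_markers: int) -> tuple[TraitSpec, ...]:
    # Magnitudes emulate an Iowa inducer trial: DTF ~63 d, PHT ~154 cm,
    # PBL ~160 cm, with plot-basis heritabilities in the 0.6-0.75 band.
    # QTL sit at fixed fractional map positions so any marker count works.
    q = lambda f: int(f * (n_markers - 1))
    return (
        TraitSpec("DTF", 63.0, ((q(0.018), 1.0),), 3.0, 1.6,
                  (0.0, 1.2), ((0.3, -0.3), (0.2, -0.2))),
        TraitSpec("PHT", 154.0, ((q(0.324), 6.0),), 80.0, 55.0,
                  (0.0, -4.0), ((1.5, -1.5), (1.0, -1.0))),
        TraitSpec("PBL", 160.0, ((q(0.618), 25.0),), 2500.0, 2600.0,
                  (0.0, 8.0), ((4.0, -4.0), (3.0, -3.0))),
    )


@dataclass(frozen=True)
class SimConfig:
    """Study-scale parameters for the synthetic DH-inducer program.

    Defaults mirror the magnitude of an elite-by-elite inducer program:
    8 founders, the 28 F1s of their half-diallel, 6,636 SNPs on a
    10 x 170 cM map, ~20 DH lines fixed per cross, two years with two blocks,
    haploid induction scored on 800-kernel plots around a 10% base rate, and
    per-cross DH success probabilities around 13% decreasing with the F1
    donor's anthesis-silking interval.
    """

    n_founders: int = 8
    n_markers: int = 6636
    n_chromosomes: int = 10
    chromosome_length_cM: float = 170.0
    maf_distribution: tuple[float, float] = (0.1, 0.5)
    n_dh_per_cross: int = 20
    traits: tuple[TraitSpec, ...] | None = None  # default scales with n_markers
    asi_mean: float = 1.0
    asi_genetic_var: float = 0.5
    asi_residual_var: float = 0.25
    hir_base: float = 0.10
    hir_qtl: tuple[tuple[int, float], ...] | None = None  # default scales with n_markers
    hir_genetic_sd: float = 0.02
    kernels_per_plot: int = 800
    mean_success: float = 0.13
    asi_success_slope: float = -0.45
    dtf_success_slope: float = 0.12
    haploids_transplanted: int = 100
    seed: int = 20240105

    def __post_init__(self) -> None:
        if self.traits is None:
            object.__setattr__(self, "traits", _default_traits(self.n_markers))
        if self.hir_qtl is None:
            object.__setattr__(
                self, "hir_qtl", ((int(0.813 * (self.n_markers - 1)), 0.015),)
            )
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if not 0.0 < self.hir_base < 1.0:
            raise ValueError("hir_base must be in (0, 1)")
        if not 0.0 < self.mean_success < 1.0:
            raise ValueError("mean_success must be in (0, 1)")
        if self.kernels_per_plot < 1:
            raise ValueError("kernels_per_plot must be positive")
        lo, hi = self.maf_distribution
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_distribution must satisfy 0 < low <= high <= 0.5")

    def genetic_map(self) -> GeneticMap:
        return maize_like_map(self.n_chromosomes, self.chromosome_length_cM, self.n_markers)

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class DHSimTruth:
    """Exact generative truth for a simulated DH panel.

    ``true_p1_fraction`` is the centimorgan-weighted share of the genome
    inherited from parent1 (the comparison target for marker-based PGC);
    ``crossovers`` records per chromosome the crossover positions of the
    gamete each line was fixed from.
    """

    dhi_ids: list[str]
    parent1_ids: list[str]
    parent2_ids: list[str]
    true_p1_fraction: np.ndarray
    crossovers: list[dict[str, np.ndarray]]
    genetic_values: pd.DataFrame | None = None  # index dhi_id, one column per trait
    true_hir: pd.Series | None = None
    cross_success_prob: pd.Series | None = None

    def __post_init__(self) -> None:
        frac = np.asarray(self.true_p1_fraction, dtype=float)
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("true parental contributions must lie in [0, 1]")
        self.true_p1_fraction = frac

    @staticmethod
    def concatenate(parts: list["DHSimTruth"]) -> "DHSimTruth":
        return DHSimTruth(
            dhi_ids=[i for p in parts for i in p.dhi_ids],
            parent1_ids=[i for p in parts for i in p.parent1_ids],
            parent2_ids=[i for p in parts for i in p.parent2_ids],
            true_p1_fraction=np.concatenate([p.true_p1_fraction for p in parts]),
            crossovers=[c for p in parts for c in p.crossovers],
        )


@dataclass
class Gamete:
    """A recombinant haplotype with its crossover record."""

    alleles: np.ndarray  # coded calls taken from one or the other parent
    crossovers: dict[str, np.ndarray]  # chromosome -> ascending cM positions
    p1_fraction_cM: float  # share of map length inherited from parent 1


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def make_founders(cfg: SimConfig, gmap: GeneticMap, rng: np.random.Generator) -> GenotypeMatrix:
    """Fully homozygous founder inducer lines.

    Per marker a minor-allele frequency is drawn from ``maf_distribution``
    (uniform) and each founder independently carries the minor allele with
    that probability.  No missing calls.
    """
    if gmap.n_markers != cfg.n_markers:
        raise ValueError(
            f"map has {gmap.n_markers} markers but config expects {cfg.n_markers}"
        )
    lo, hi = cfg.maf_distribution
    freq_minor = rng.uniform(lo, hi, size=cfg.n_markers)
    draws = rng.random((cfg.n_founders, cfg.n_markers))
    calls = np.where(draws < freq_minor, -1, 1).astype(np.int8)
    ids = [f"P{i + 1}" for i in range(cfg.n_founders)]
    return GenotypeMatrix(ids, gmap.markers(), calls)


def simulate_gamete(
    parent1_hap: np.ndarray,
    parent2_hap: np.ndarray,
    gmap: GeneticMap,
    rng: np.random.Generator,
) -> Gamete:
    """One meiotic product of an F1 whose two haplotypes are the parents'.

    Per chromosome the crossover count is Poisson(length_cM / 100) with
    positions i.i.d. uniform on the chromosome (Haldane model, no
    interference); the starting parent is chosen fairly.
    """
    h1 = np.asarray(parent1_hap)
    h2 = np.asarray(parent2_hap)
    if h1.shape != h2.shape or h1.shape[0] != gmap.n_markers:
        raise ValueError("haplotypes not aligned to the genetic map")
    alleles = np.empty_like(h1)
    crossovers: dict[str, np.ndarray] = {}
    p1_len = 0.0
    for chrom, sl in gmap.chromosome_slices():
        n_co = rng.poisson(chrom.length_cM / 100.0)
        xpos = np.sort(rng.uniform(0.0, chrom.length_cM, size=n_co)) if n_co else np.empty(0)
        start = int(rng.integers(2))  # 0 -> parent1 first
        crossovers[chrom.name] = xpos
        # parent at marker = start flipped once per crossover to its left
        n_left = np.searchsorted(xpos, chrom.marker_pos_cM, side="right")
        which = (start + n_left) % 2
        seg = np.where(which == 0, h1[sl], h2[sl])
        alleles[sl] = seg
        # cM length inherited from parent1: alternate segments over [0, L]
        bounds = np.concatenate(([0.0], xpos, [chrom.length_cM]))
        seg_len = np.diff(bounds)
        p1_len += float(seg_len[start::2].sum())  # parent1 owns alternate segments
    total = gmap.total_length_cM
    if total > 0:
        frac = p1_len / total
    else:  # degenerate all-zero-length map: fall back to marker share
        frac = float(np.mean([
            np.mean(alleles[sl] == h1[sl]) for _c, sl in gmap.chromosome_slices()
        ]))
    return Gamete(alleles=alleles, crossovers=crossovers, p1_fraction_cM=frac)


def make_dh_population(
    p1_id: str,
    p1_row: np.ndarray,
    p2_id: str,
    p2_row: np.ndarray,
    n: int,
    gmap: GeneticMap,
    rng: np.random.Generator,
    id_prefix: str | None = None,
) -> tuple[GenotypeMatrix, DHSimTruth]:
    """DH lines from the cross p1 x p2: each line is one F1 gamete doubled.

    Because a DH line is a doubled gamete it is homozygous at every locus by
    construction; truth records the gamete's crossovers and exact
    cM-weighted parent1 contribution.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if (np.asarray(p1_row) == 0).any() or (np.asarray(p2_row) == 0).any():
        raise ValueError("parents must be fully homozygous with no missing calls")
    prefix = id_prefix or f"{p1_id}x{p2_id}"
    calls = np.empty((n, gmap.n_markers), dtype=np.int8)
    ids, fracs, xovers = [], [], []
    for i in range(n):
        g = simulate_gamete(p1_row, p2_row, gmap, rng)
        calls[i] = g.alleles  # doubling: haploid alleles fixed to homozygosity
        ids.append(f"{prefix}_DH{i + 1:03d}")
        fracs.append(g.p1_fraction_cM)
        xovers.append(g.crossovers)
    panel = GenotypeMatrix(ids, gmap.markers(), calls)
    truth = DHSimTruth(ids, [p1_id] * n, [p2_id] * n, np.array(fracs), xovers)
    return panel, truth


def build_diallel(founder_ids: list[str]) -> list[tuple[str, str]]:
    """All unordered founder pairs, no selfs: k founders -> k(k-1)/2 crosses."""
    if len(founder_ids) < 2:
        raise ValueError("need at least two founders")
    return [
        (founder_ids[i], founder_ids[j])
        for i in range(len(founder_ids))
        for j in range(i + 1, len(founder_ids))
    ]


def simulate_phenotypes(
    dh_panel: GenotypeMatrix,
    truth: DHSimTruth,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Plot-level phenotype records for the panel.

    For each genotype x year x block plot:
    ``y = mean + sum(QTL effect * coded call) + polygenic deviate
    + year effect + block(year) effect + N(0, residual_var)``.
    DTS is generated as DTF + ASI with a genotype-level ASI deviation;
    haploid/total kernel counts are binomial around each genotype's true
    induction rate.  Genetic values and true HIRs are written back onto
    ``truth``.
    """
    for spec in cfg.traits:
        for idx, _eff in spec.qtl:
            if not 0 <= idx < dh_panel.n_markers:
                raise ValueError(f"{spec.name}: QTL marker index {idx} out of range")
    n = dh_panel.n_lines
    years = [f"Y{k + 1}" for k in range(len(cfg.traits[0].year_effects))]
    gvalues: dict[str, np.ndarray] = {}
    rows: list[dict] = []

    for spec in cfg.traits:
        g = np.full(n, spec.mean)
        for idx, eff in spec.qtl:
            g = g + eff * dh_panel.calls[:, idx].astype(float)
        g = g + rng.normal(0.0, np.sqrt(spec.polygenic_var), size=n)
        gvalues[spec.name] = g

    asi_g = rng.normal(cfg.asi_mean, np.sqrt(cfg.asi_genetic_var), size=n)
    true_hir = np.full(n, cfg.hir_base)
    for idx, eff in cfg.hir_qtl:
        true_hir = true_hir + eff * dh_panel.calls[:, idx].astype(float)
    true_hir = true_hir + rng.normal(0.0, cfg.hir_genetic_sd, size=n)
    true_hir = np.clip(true_hir, 1e-4, 1 - 1e-4)

    for i, gid in enumerate(dh_panel.line_ids):
        for k, year in enumerate(years):
            for j in range(len(cfg.traits[0].block_effects[k])):
                rec = {"genotype": gid, "year": year, "block": f"B{j + 1}"}
                for spec in cfg.traits:
                    rec[spec.name] = (
                        gvalues[spec.name][i]
                        + spec.year_effects[k]
                        + spec.block_effects[k][j]
                        + rng.normal(0.0, np.sqrt(spec.residual_var))
                    )
                rec["DTS"] = rec["DTF"] + asi_g[i] + rng.normal(
                    0.0, np.sqrt(cfg.asi_residual_var)
                )
                hap, tot = simulate_hir_counts(float(true_hir[i]), cfg.kernels_per_plot, rng)
                rec["haploid_kernels"] = hap
                rec["total_kernels"] = tot
                rows.append(rec)

    gv = pd.DataFrame(gvalues, index=pd.Index(dh_panel.line_ids, name="genotype"))
    gv["ASI"] = asi_g
    truth.genetic_values = gv
    truth.true_hir = pd.Series(true_hir, index=gv.index, name="true_hir")
    return pd.DataFrame(rows)


def simulate_hir_counts(
    true_hir: float, kernels: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Binomial haploid kernel count among ``kernels`` scored seeds."""
    if kernels <= 0:
        raise ValueError("kernels must be positive")
    if not 0.0 < true_hir < 1.0:
        raise ValueError("true_hir must be in (0, 1)")
    return int(rng.binomial(kernels, true_hir)), int(kernels)


def simulate_success_rates(
    f1_traits: pd.DataFrame,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-cross DH production success from F1 donor flowering traits.

    Success probability follows a logistic model centred on
    ``cfg.mean_success``:
    ``p = expit(logit(mean_success) + asi_slope * (ASI - mean ASI)
    + dtf_slope * (DTF - mean DTF))`` and each transplanted haploid succeeds
    independently with that probability.  ``f1_traits`` needs columns
    ``cross``, ``ASI``, ``DTF``.
    """
    from scipy.special import expit, logit

    required = {"cross", "ASI", "DTF"}
    if not required.issubset(f1_traits.columns):
        raise ValueError(f"f1_traits needs columns {sorted(required)}")
    asi = f1_traits["ASI"].to_numpy(float)
    dtf = f1_traits["DTF"].to_numpy(float)
    eta = (
        logit(cfg.mean_success)
        + cfg.asi_success_slope * (asi - asi.mean())
        + cfg.dtf_success_slope * (dtf - dtf.mean())
    )
    p = expit(eta)
    n_t = cfg.haploids_transplanted
    succ = rng.binomial(n_t, p)
    return pd.DataFrame(
        {
            "cross": f1_traits["cross"].to_numpy(),
            "ASI": asi,
            "DTF": dtf,
            "success_prob": p,
            "haploids_transplanted": n_t,
            "dh_lines_obtained": succ,
            "success_rate_pct": 100.0 * succ / n_t,
        }
    )


# ---------------------------------------------------------------------------
# Whole-study orchestration
# ---------------------------------------------------------------------------


@dataclass
class SimulatedStudy:
    """Everything one synthetic DH-inducer program produces."""

    config: SimConfig
    gmap: GeneticMap
    founders: GenotypeMatrix
    panel: GenotypeMatrix
    pedigree: Pedigree
    truth: DHSimTruth
    phenotypes: pd.DataFrame
    f1_traits: pd.DataFrame
    success: pd.DataFrame


def simulate_study(cfg: SimConfig | None = None, seed: int | None = None) -> SimulatedStudy:
    """Generate a complete synthetic study: founders -> half-diallel ->
    DH panels -> trial phenotypes -> induction counts -> success rates.

    The first three founders are designated reference lines for the nested
    (NAM-style) population partition, mirroring the practice of anchoring
    nested populations on phenotypically distinct parents.
    """
    cfg = cfg or SimConfig()
    if seed is not None:
        cfg = cfg.with_(seed=seed)
    rng = np.random.default_rng(cfg.seed)
    gmap = cfg.genetic_map()
    founders = make_founders(cfg, gmap, rng)
    crosses = build_diallel(founders.line_ids)

    panels, truths, pairs = [], [], {}
    for p1, p2 in crosses:
        pop, tr = make_dh_population(
            p1, founders.row(p1), p2, founders.row(p2), cfg.n_dh_per_cross, gmap, rng
        )
        panels.append(pop)
        truths.append(tr)
        for dhi in pop.line_ids:
            pairs[dhi] = (p1, p2)

    panel = GenotypeMatrix(
        [i for p in panels for i in p.line_ids],
        gmap.markers(),
        np.vstack([p.calls for p in panels]),
    )
    truth = DHSimTruth.concatenate(truths)
    reference = founders.line_ids[:3] if len(founders.line_ids) >= 3 else founders.line_ids[:1]
    pedigree = Pedigree.from_parent_pairs(pairs, reference_lines=reference)

    # Phenotype founders alongside the DH panel so parental ranges (and
    # transgressive segregation) are observable downstream.
    combined = GenotypeMatrix(
        founders.line_ids + panel.line_ids,
        gmap.markers(),
        np.vstack([founders.calls, panel.calls]),
    )
    phenotypes = simulate_phenotypes(combined, truth, cfg, rng)

    # F1 donor traits: midparent genetic values plus a cross-level deviation.
    dtf_spec = next(s for s in cfg.traits if s.name == "DTF")
    founder_dtf = {
        fid: dtf_spec.mean
        + sum(eff * float(founders.row(fid)[idx]) for idx, eff in dtf_spec.qtl)
        + rng.normal(0.0, np.sqrt(dtf_spec.polygenic_var))
        for fid in founders.line_ids
    }
    f1_rows = [
        {
            "cross": f"{p1}x{p2}",
            "DTF": 0.5 * (founder_dtf[p1] + founder_dtf[p2]) + rng.normal(0.0, 0.5),
            "ASI": rng.normal(cfg.asi_mean, np.sqrt(cfg.asi_genetic_var)),
        }
        for p1, p2 in crosses
    ]
    f1_traits = pd.DataFrame(f1_rows)
    success = simulate_success_rates(f1_traits, cfg, rng)
    truth.cross_success_prob = pd.Series(
        success["success_prob"].to_numpy(), index=success["cross"].to_numpy()
    )
    return SimulatedStudy(
        cfg, gmap, founders, panel, pedigree, truth, phenotypes, f1_traits, success
    )
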