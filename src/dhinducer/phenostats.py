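"""Field-trial statistics for inducer phenotypes.

Plot-level records follow the model

    y_ijk = mu + genotype_i + year_k + block(year)_j(k) + e_ijk

Genotype means (BLUEs) come from the all-fixed-effects least-squares fit,
reported as marginal means averaged over the year x block grid — on a
balanced design this reduces exactly to the per-genotype arithmetic mean.
Broad-sense heritability on a plot basis is

    H2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / r)

with genotype treated as random for the variance components and r the
harmonic mean of per-genotype replicate counts.  The REML fit exploits the
one-random-effect structure: the restricted likelihood is profiled down to a
one-dimensional search over lambda = sigma_g^2 / sigma_e^2.

Derived traits: HIR (haploid kernels / total kernels, %; plots under the
minimum kernel count are excluded), ASI = DTS - DTF (positive when silking
trails anthesis), and the DH production success rate (%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# Derived traits
# ---------------------------------------------------------------------------


def hir(haploid_kernels: int, total_kernels: int, min_kernels: int = 800) -> float | None:
    """Haploid induction rate in percent, or None when the plot is excluded.

    Plots with fewer than ``min_kernels`` scored seeds are excluded (strict:
    exactly ``min_kernels`` passes) to keep rate estimates stable.
    """
    if haploid_kernels < 0 or total_kernels < 0:
        raise ValueError("kernel counts must be non-negative")
    if haploid_kernels > total_kernels:
        raise ValueError(
            f"haploid kernels ({haploid_kernels}) exceed total ({total_kernels})"
        )
    if total_kernels < min_kernels:
        return None
    return 100.0 * haploid_kernels / total_kernels


def asi(dtf: float, dts: float) -> float:
    """Anthesis-silking interval: DTS - DTF (positive = silking after shed)."""
    return dts - dtf


def success_rate(dh_lines_obtained: int, haploids_transplanted: int) -> float:
    """Percent of transplanted haploids that yielded a DH line."""
    if haploids_transplanted <= 0:
        raise ValueError("haploids_transplanted must be positive")
    if dh_lines_obtained < 0 or dh_lines_obtained > haploids_transplanted:
        raise ValueError("obtained count must lie in [0, transplanted]")
    return 100.0 * dh_lines_obtained / haploids_transplanted


def add_derived_traits(records: pd.DataFrame, min_kernels: int = 800) -> pd.DataFrame:
    """Append HIR (%) and ASI (days) columns computed per plot."""
    out = records.copy()
    if {"haploid_kernels", "total_kernels"}.issubset(out.columns):
        out["HIR"] = [
            hir(int(h), int(t), min_kernels) if pd.notna(h) and pd.notna(t) else None
            for h, t in zip(out["haploid_kernels"], out["total_kernels"])
        ]
        out["HIR"] = out["HIR"].astype(float)
    if {"DTF", "DTS"}.issubset(out.columns):
        out["ASI"] = out["DTS"] - out["DTF"]
    return out


# ---------------------------------------------------------------------------
# BLUEs (all-fixed least squares, marginal means)
# ---------------------------------------------------------------------------


@dataclass
class BLUETable:
    """Per-genotype least-squares means with the residual fit behind them."""

    trait: str
    table: pd.DataFrame  # columns: genotype, estimate, se, n_plots
    residual_var: float
    residual_df: float

    def estimates(self) -> dict[str, float]:
        return dict(zip(self.table["genotype"], self.table["estimate"]))


def _design(df: pd.DataFrame) -> tuple[np.ndarray, list[str], dict]:
    """Dummy design: intercept + genotype + year + block(year), treatment coding."""
    genos = sorted(df["genotype"].unique())
    years = sorted(df["year"].unique())
    yb = sorted({(y, b) for y, b in zip(df["year"], df["block"])})
    cols: list[np.ndarray] = [np.ones(len(df))]
    for g in genos[1:]:
        cols.append((df["genotype"] == g).to_numpy(float))
    for y in years[1:]:
        cols.append((df["year"] == y).to_numpy(float))
    # block nested in year: drop the first block within each year
    nested = [(y, b) for (y, b) in yb if b != min(bb for (yy, bb) in yb if yy == y)]
    for y, b in nested:
        cols.append(((df["year"] == y) & (df["block"] == b)).to_numpy(float))
    X = np.column_stack(cols)
    meta = {"genos": genos, "years": years, "yb": yb, "nested": nested}
    return X, genos, meta


def _grid_rows(meta: dict) -> np.ndarray:
    """Prediction rows for every (year, block) cell, one block of rows per genotype."""
    genos, years, yb, nested = meta["genos"], meta["years"], meta["yb"], meta["nested"]
    p = 1 + (len(genos) - 1) + (len(years) - 1) + len(nested)
    rows = np.zeros((len(genos), len(yb), p))
    for gi, g in enumerate(genos):
        for ci, (y, b) in enumerate(yb):
            r = np.zeros(p)
            r[0] = 1.0
            if g != genos[0]:
                r[1 + genos.index(g) - 1] = 1.0
            off = 1 + len(genos) - 1
            if y != years[0]:
                r[off + years.index(y) - 1] = 1.0
            off += len(years) - 1
            if (y, b) in nested:
                r[off + nested.index((y, b))] = 1.0
            rows[gi, ci] = r
    return rows


def fit_blue(records: pd.DataFrame, trait: str) -> BLUETable:
    """Least-squares genotype means for one trait.

    Fits the all-fixed model by OLS and reports each genotype's marginal
    mean over the full year x block grid with equal cell weights (the
    estimated-marginal-means convention), with its standard error from the
    fitted residual variance.  Rank-deficient designs (e.g. a genotype
    observed in a single year) are solved by pseudoinverse and flagged with
    a warning; affected contrasts may not be estimable.
    """
    import statsmodels.api as sm

    df = records.dropna(subset=[trait]).copy()
    if df.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    df["year"] = df["year"].astype(str)
    df["block"] = df["block"].astype(str)
    X, genos, meta = _design(df)
    y = df[trait].to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(
            f"{trait}: design is rank deficient; estimates use the "
            "minimum-norm solution and some genotype means may be non-estimable"
        )
    fit = sm.OLS(y, X).fit()
    grid = _grid_rows(meta)  # genotypes x cells x params
    L = grid.mean(axis=1)  # average over the year x block grid
    est = L @ fit.params
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = fit.cov_params()  # saturated fits have no residual df: SE -> NaN/inf
        se = np.sqrt(np.einsum("ip,pq,iq->i", L, cov, L))
    n_plots = df.groupby("genotype").size()
    table = pd.DataFrame(
        {
            "genotype": genos,
            "estimate": est,
            "se": se,
            "n_plots": [int(n_plots[g]) for g in genos],
        }
    )
    resid_var = float(fit.mse_resid) if fit.df_resid > 0 else float("nan")
    return BLUETable(trait, table, resid_var, float(fit.df_resid))


# ---------------------------------------------------------------------------
# REML variance components and heritability
# ---------------------------------------------------------------------------


@dataclass
class VarianceComponents:
    trait: str
    sigma_g2: float
    sigma_e2: float
    r_harmonic: float
    H2: float  # NaN when undefined (both components zero)


def harmonic_mean(replicate_counts) -> float:
    """Harmonic mean of per-genotype replicate counts."""
    counts = np.asarray(list(replicate_counts), dtype=float)
    if counts.size == 0:
        raise ValueError("empty replicate count list")
    if (counts < 1).any():
        raise ValueError("replicate counts must be >= 1")
    return float(counts.size / (1.0 / counts).sum())


def heritability(vc: VarianceComponents) -> float:
    """Plot-basis broad-sense H2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / r)."""
    if vc.sigma_g2 == 0.0 and vc.sigma_e2 == 0.0:
        return float("nan")
    return vc.sigma_g2 / (vc.sigma_g2 + vc.sigma_e2 / vc.r_harmonic)


def variance_components(records: pd.DataFrame, trait: str) -> VarianceComponents:
    """REML variance components with genotype random, year/block fixed.

    The restricted likelihood of the single-random-effect model is profiled
    to a one-dimensional function of lambda = sigma_g^2 / sigma_e^2 and
    minimized by bracketed search (tolerance ~1e-10 on log lambda); the
    group structure keeps every step O(n) via the block form of
    (I + lambda Z Z')^{-1}.  Estimates are floored at zero.
    """
    df = records.dropna(subset=[trait]).copy()
    if df["genotype"].nunique() < 2 or len(df) < 3:
        raise ValueError("need >= 2 genotypes and >= 3 plots for REML")
    df["year"] = df["year"].astype(str)
    df["block"] = df["block"].astype(str)
    y = df[trait].to_numpy(float)

    # Fixed-effect design without genotype; genotype is the random term.
    years = sorted(df["year"].unique())
    yb = sorted({(yy, b) for yy, b in zip(df["year"], df["block"])})
    cols = [np.ones(len(df))]
    for yy in years[1:]:
        cols.append((df["year"] == yy).to_numpy(float))
    nested = [(yy, b) for (yy, b) in yb if b != min(bb for (y2, bb) in yb if y2 == yy)]
    for yy, b in nested:
        cols.append(((df["year"] == yy) & (df["block"] == b)).to_numpy(float))
    X = np.column_stack(cols)
    p = np.linalg.matrix_rank(X)
    n = len(y)

    geno_codes, geno_levels = pd.factorize(df["genotype"], sort=True)
    n_g = np.bincount(geno_codes).astype(float)

    if np.var(y) < 1e-300:
        return VarianceComponents(trait, 0.0, 0.0, harmonic_mean(n_g), float("nan"))

    def _hinv(lam: float, M: np.ndarray) -> np.ndarray:
        """(I + lam Z Z')^{-1} M via the block (Woodbury) identity."""
        M2 = M if M.ndim == 2 else M[:, None]
        gsum = np.zeros((len(n_g), M2.shape[1]))
        np.add.at(gsum, geno_codes, M2)
        shrink = (lam / (1.0 + lam * n_g))[:, None] * gsum
        out = M2 - shrink[geno_codes]
        return out if M.ndim == 2 else out[:, 0]

    def neg2_reml(log_lam: float) -> float:
        lam = np.exp(log_lam)
        HiX = _hinv(lam, X)
        Hiy = _hinv(lam, y)
        XtHiX = X.T @ HiX
        XtHiy = X.T @ Hiy
        beta = np.linalg.lstsq(XtHiX, XtHiy, rcond=None)[0]
        ypy = float(y @ Hiy - XtHiy @ beta)
        ypy = max(ypy, 1e-300)
        logdet_H = float(np.log1p(lam * n_g).sum())
        sign, logdet_X = np.linalg.slogdet(XtHiX)
        return logdet_H + logdet_X + (n - p) * np.log(ypy)

    res = optimize.minimize_scalar(
        neg2_reml, bounds=(-25.0, 25.0), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise RuntimeError(f"REML profile search failed to converge: {res.message}")
    # Compare against the lambda -> 0 boundary (sigma_g^2 = 0).
    lam = float(np.exp(res.x))
    if neg2_reml(-700.0) <= res.fun + 1e-12:
        lam = 0.0
    HiX = _hinv(lam, X)
    Hiy = _hinv(lam, y)
    XtHiy = X.T @ Hiy
    beta = np.linalg.lstsq(X.T @ HiX, XtHiy, rcond=None)[0]
    sigma_e2 = max(float(y @ Hiy - XtHiy @ beta) / (n - p), 0.0)
    sigma_g2 = max(lam * sigma_e2, 0.0)
    vc = VarianceComponents(trait, sigma_g2, sigma_e2, harmonic_mean(n_g), float("nan"))
    vc.H2 = heritability(vc)
    return vc


# ---------------------------------------------------------------------------
# Correlations and group tests
# ---------------------------------------------------------------------------


def pearson_test(x, y) -> tuple[float, float]:
    """Pearson r with its two-sided t-test p-value (pairwise complete)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least three complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class TransgressiveReport:
    trait: str
    parent_min: float
    parent_max: float
    dhi_min: float
    dhi_max: float
    high_transgressive: bool  # DH maximum strictly above the best parent
    low_transgressive: bool  # DH minimum strictly below the worst parent


def transgressive_summary(
    parent_blues: BLUETable, dhi_blues: BLUETable, trait: str | None = None
) -> TransgressiveReport:
    """Compare DH progeny extremes against the parental range.

    Progeny exceeding both parents signal transgressive segregation —
    recombination assembling complementary alleles beyond either parent.
    Flags use strict inequality (an equal extreme is not transgressive).
    """
    pv = parent_blues.table["estimate"].to_numpy(float)
    dv = dhi_blues.table["estimate"].to_numpy(float)
    if pv.size == 0 or dv.size == 0:
        raise ValueError("both BLUE tables must be non-empty")
    return TransgressiveReport(
        trait or dhi_blues.trait,
        float(pv.min()), float(pv.max()), float(dv.min()), float(dv.max()),
        high_transgressive=bool(dv.max() > pv.max()),
        low_transgressive=bool(dv.min() < pv.min()),
    )


def group_mean_test(superior, inferior) -> dict[str, float]:
    """Welch two-sample t-test between the superior and inferior groups.

    The difference is reported as inferior minus superior (negative when
    the superior group is higher).  If both groups are constant and equal
    the p-value is 1 by convention.
    """
    sup = np.asarray(superior, dtype=float)
    inf_ = np.asarray(inferior, dtype=float)
    if sup.size < 2 or inf_.size < 2:
        raise ValueError("both groups need at least two values")
    diff = float(inf_.mean() - sup.mean())
    if np.var(sup) == 0 and np.var(inf_) == 0:
        if diff == 0:
            return {
                "mean_superior": float(sup.mean()), "mean_inferior": float(inf_.mean()),
                "difference": 0.0, "t": 0.0, "p_value": 1.0,
            }
        t, p = (float("-inf") if diff < 0 else float("inf")), 0.0
    else:
        t, p = stats.ttest_ind(inf_, sup, equal_var=False)
        t, p = float(t), float(p)
    return {
        "mean_superior": float(sup.mean()),
        "mean_inferior": float(inf_.mean()),
        "difference": diff,
        "t": t,
        "p_value": p,
    }


# ---------------------------------------------------------------------------
# Tukey compact letter display
# ---------------------------------------------------------------------------


def tukey_groups(blues: BLUETable, alpha: float = 0.05) -> dict[str, str]:
    """Compact letter display from all pairwise Tukey comparisons.

    Two genotypes differ when |m_i - m_j| exceeds
    q(1-alpha; k, df) / sqrt(2) * sqrt(se_i^2 + se_j^2), with q the
    studentized-range quantile and df the residual degrees of freedom.
    Letters come from the insert-and-absorb algorithm: start with one
    letter covering everything, split it for each significant pair, drop
    letter sets contained in others, then label sets in order of their
    highest mean.  Genotypes not sharing any letter differ at level alpha.
    """
    tab = blues.table.sort_values("estimate", ascending=False).reset_index(drop=True)
    names = tab["genotype"].tolist()
    means = tab["estimate"].to_numpy(float)
    ses = tab["se"].to_numpy(float)
    k = len(names)
    if k == 1:
        return {names[0]: "a"}
    crit = stats.studentized_range.ppf(1 - alpha, k, max(blues.residual_df, 1.0))

    def differ(i: int, j: int) -> bool:
        return abs(means[i] - means[j]) > crit / np.sqrt(2) * np.sqrt(
            ses[i] ** 2 + ses[j] ** 2
        )

    letters: list[set[int]] = [set(range(k))]
    for i in range(k):
        for j in range(i + 1, k):
            if not differ(i, j):
                continue
            for s in [s for s in letters if i in s and j in s]:
                letters.remove(s)
                letters.extend(({x for x in s if x != j}, {x for x in s if x != i}))
            deduped: list[set[int]] = []
            for s in letters:
                if s not in deduped:
                    deduped.append(s)
            letters = [s for s in deduped if not any(s < t for t in deduped)]
    letters.sort(key=lambda s: min(s))  # order by highest contained mean
    labels = {i: "" for i in range(k)}
    for li, s in enumerate(letters):
        ch = chr(ord("a") + li)
        for i in s:
            labels[i] += ch
    return {names[i]: "".join(sorted(labels[i])) for i in range(k)}
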