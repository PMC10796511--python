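"""Derived traits, BLUEs, REML heritability, correlations and group tests."""

import numpy as np
import pandas as pd
import pytest

from dhinducer.phenostats import (
    BLUETable,
    VarianceComponents,
    add_derived_traits,
    asi,
    fit_blue,
    group_mean_test,
    harmonic_mean,
    heritability,
    hir,
    pearson_test,
    success_rate,
    transgressive_summary,
    tukey_groups,
    variance_components,
)


class TestDerivedTraits:
    @pytest.mark.parametrize(
        "h, t, expected",
        [(100, 1000, 10.0), (0, 800, 0.0), (50, 799, None)],
    )
    def test_hir(self, h, t, expected):
        assert hir(h, t) == expected

    def test_hir_exact_boundary_passes(self):
        assert hir(80, 800) == pytest.approx(10.0)

    def test_hir_invalid_counts(self):
        with pytest.raises(ValueError):
            hir(900, 800)

    @pytest.mark.parametrize("dtf, dts, expected", [(60, 62, 2), (61, 61, 0), (63, 61, -2)])
    def test_asi_sign_convention(self, dtf, dts, expected):
        assert asi(dtf, dts) == expected

    @pytest.mark.parametrize(
        "got, trans, expected", [(13, 100, 13.0), (0, 50, 0.0), (43, 200, 21.5)]
    )
    def test_success_rate(self, got, trans, expected):
        assert success_rate(got, trans) == pytest.approx(expected)

    def test_success_rate_undefined(self):
        with pytest.raises(ValueError):
            success_rate(1, 0)

    def test_add_derived_traits(self):
        df = pd.DataFrame(
            {
                "genotype": ["g1", "g2"],
                "year": ["Y1", "Y1"],
                "block": ["B1", "B1"],
                "DTF": [60.0, 62.0],
                "DTS": [61.0, 61.5],
                "haploid_kernels": [80, 10],
                "total_kernels": [800, 500],
            }
        )
        out = add_derived_traits(df)
        assert out["ASI"].tolist() == [1.0, -0.5]
        assert out["HIR"].iloc[0] == pytest.approx(10.0)
        assert np.isnan(out["HIR"].iloc[1])  # under the kernel minimum


def _records(rows):
    return pd.DataFrame(rows, columns=["genotype", "year", "block", "y"])


class TestFitBlue:
    def test_balanced_reduces_to_means(self):
        rows = []
        rng = np.random.default_rng(0)
        vals = {}
        for g in ["g1", "g2", "g3"]:
            for yr in ["Y1", "Y2"]:
                for b in ["B1", "B2"]:
                    v = float(rng.normal(10, 2))
                    rows.append((g, yr, b, v))
                    vals.setdefault(g, []).append(v)
        bt = fit_blue(_records(rows), "y")
        for g, est in bt.estimates().items():
            assert est == pytest.approx(np.mean(vals[g]), abs=1e-10)

    def test_unbalanced_worked_example(self):
        rows = [
            ("G1", "Y1", "B1", 10.0),
            ("G1", "Y1", "B2", 14.0),
            ("G2", "Y1", "B1", 20.0),
        ]
        bt = fit_blue(_records(rows), "y")
        est = bt.estimates()
        assert est["G1"] == pytest.approx(12.0, abs=1e-9)
        assert est["G2"] == pytest.approx(22.0, abs=1e-9)

    def test_constant_shift_equivariance(self):
        rows = [
            ("G1", "Y1", "B1", 10.0),
            ("G1", "Y1", "B2", 14.0),
            ("G2", "Y1", "B1", 20.0),
            ("G2", "Y1", "B2", 17.0),
            ("G3", "Y1", "B1", 11.0),
        ]
        base = fit_blue(_records(rows), "y").estimates()
        shifted_rows = [(g, yr, b, v + 5.0) for g, yr, b, v in rows]
        shifted = fit_blue(_records(shifted_rows), "y").estimates()
        for g in base:
            assert shifted[g] == pytest.approx(base[g] + 5.0, abs=1e-9)

    def test_n_plots_recorded(self):
        rows = [
            ("G1", "Y1", "B1", 10.0),
            ("G1", "Y1", "B2", 14.0),
            ("G2", "Y1", "B1", 20.0),
        ]
        bt = fit_blue(_records(rows), "y")
        tab = bt.table.set_index("genotype")
        assert tab.loc["G1", "n_plots"] == 2 and tab.loc["G2", "n_plots"] == 1


class TestVarianceComponents:
    @staticmethod
    def _one_way(n_geno, reps, sigma_g2, sigma_e2, seed):
        rng = np.random.default_rng(seed)
        g = rng.normal(0, np.sqrt(sigma_g2), n_geno)
        rows = []
        # single year and block level: intercept-only fixed part, matching
        # the one-way oracles below
        for i in range(n_geno):
            for _r in range(reps):
                rows.append(
                    (f"g{i:03d}", "Y1", "B1", 50 + g[i] + rng.normal(0, np.sqrt(sigma_e2)))
                )
        return _records(rows)

    def test_balanced_matches_anova_closed_form(self):
        df = self._one_way(40, 3, 4.0, 1.0, seed=2)
        vc = variance_components(df, "y")
        # balanced one-way oracle: sigma_g2 = (MS_g - MS_e) / r
        wide = df.pivot_table(index="genotype", values="y", aggfunc=["mean", "var", "count"])
        gm = df["y"].mean()
        r = 3
        ms_g = r * ((wide[("mean", "y")] - gm) ** 2).sum() / (len(wide) - 1)
        ms_e = wide[("var", "y")].mean()
        expect_g = (ms_g - ms_e) / r
        assert vc.sigma_e2 == pytest.approx(ms_e, rel=1e-6)
        assert vc.sigma_g2 == pytest.approx(expect_g, rel=1e-6)

    def test_matches_mixedlm_oracle(self):
        import statsmodels.formula.api as smf

        df = self._one_way(30, 2, 3.0, 1.5, seed=7)
        vc = variance_components(df, "y")
        md = smf.mixedlm("y ~ 1", df, groups=df["genotype"]).fit(reml=True)
        assert vc.sigma_g2 == pytest.approx(float(md.cov_re.iloc[0, 0]), rel=1e-4)
        assert vc.sigma_e2 == pytest.approx(float(md.scale), rel=1e-4)

    def test_constant_data_degenerates_cleanly(self):
        rows = [("g1", "Y1", "B1", 5.0), ("g1", "Y1", "B2", 5.0),
                ("g2", "Y1", "B1", 5.0), ("g2", "Y1", "B2", 5.0)]
        vc = variance_components(_records(rows), "y")
        assert vc.sigma_g2 == 0.0 and vc.sigma_e2 == 0.0
        assert np.isnan(vc.H2)

    def test_parameter_recovery(self):
        ests_g, ests_e = [], []
        for seed in range(8):
            df = self._one_way(200, 2, 3.0, 1.0, seed=seed)
            vc = variance_components(df, "y")
            ests_g.append(vc.sigma_g2)
            ests_e.append(vc.sigma_e2)
        assert abs(np.mean(ests_g) - 3.0) / 3.0 < 0.10
        assert abs(np.mean(ests_e) - 1.0) / 1.0 < 0.10

    def test_zero_genetic_variance_floors_at_zero(self):
        df = self._one_way(50, 2, 0.0, 1.0, seed=3)
        vc = variance_components(df, "y")
        assert vc.sigma_g2 >= 0.0
        assert vc.sigma_g2 < 0.5


class TestHeritability:
    @pytest.mark.parametrize(
        "sg, se, r, expected",
        [(0.0, 1.0, 2.0, 0.0), (3.0, 1.0, 1.0, 0.75), (1.0, 2.0, 2.0, 0.5)],
    )
    def test_closed_forms(self, sg, se, r, expected):
        vc = VarianceComponents("t", sg, se, r, float("nan"))
        assert heritability(vc) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        assert np.isnan(heritability(VarianceComponents("t", 0.0, 0.0, 2.0, np.nan)))

    def test_monotone_in_sigma_g_and_r(self):
        grid = [0.5, 1.0, 2.0, 4.0]
        h_g = [heritability(VarianceComponents("t", sg, 1.0, 2.0, np.nan)) for sg in grid]
        h_r = [heritability(VarianceComponents("t", 1.0, 1.0, r, np.nan)) for r in grid]
        assert all(np.diff(h_g) > 0) and all(np.diff(h_r) > 0)

    @pytest.mark.parametrize("counts, expected", [((2, 2, 2), 2.0), ((2, 2, 4), 2.4), ((1,), 1.0)])
    def test_harmonic_mean(self, counts, expected):
        assert harmonic_mean(counts) == pytest.approx(expected)

    def test_harmonic_mean_empty(self):
        with pytest.raises(ValueError):
            harmonic_mean([])


class TestPearson:
    def test_perfect_linear(self):
        r, p = pearson_test([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_t_transform_at_r048_n23(self):
        # construct x, y with sample correlation exactly 0.48
        rng = np.random.default_rng(0)
        n, target = 23, 0.48
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= x * (x @ z) / (x @ x)  # orthogonalize
        z /= z.std()
        y = target * x + np.sqrt(1 - target**2) * z
        r, p = pearson_test(x, y)
        assert r == pytest.approx(0.48, abs=1e-12)
        assert p == pytest.approx(0.0204, abs=5e-4)  # t = 2.507 on 21 df

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError):
            pearson_test([1, 1, 1], [1, 2, 3])

    def test_null_p_uniformity(self):
        from scipy import stats

        rng = np.random.default_rng(5)
        pvals = [
            pearson_test(rng.normal(size=30), rng.normal(size=30))[1]
            for _ in range(300)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


def _blue_table(trait, values, se=0.5, resid_var=1.0, resid_df=20.0):
    tab = pd.DataFrame(
        {
            "genotype": list(values),
            "estimate": list(values.values()),
            "se": se,
            "n_plots": 2,
        }
    )
    return BLUETable(trait, tab, resid_var, resid_df)


class TestTransgressive:
    def test_progeny_inside_parent_range(self):
        rep = transgressive_summary(
            _blue_table("t", {"p1": 1.0, "p2": 10.0}),
            _blue_table("t", {"d1": 3.0, "d2": 8.0}),
        )
        assert not rep.high_transgressive and not rep.low_transgressive

    def test_high_transgressive_flag(self):
        rep = transgressive_summary(
            _blue_table("HIR", {"p1": 3.5, "p2": 16.1}),
            _blue_table("HIR", {"d1": 0.4, "d2": 23.4}),
        )
        assert rep.high_transgressive and rep.low_transgressive

    def test_equal_extremes_not_flagged(self):
        rep = transgressive_summary(
            _blue_table("t", {"p1": 1.0, "p2": 10.0}),
            _blue_table("t", {"d1": 1.0, "d2": 10.0}),
        )
        assert not rep.high_transgressive and not rep.low_transgressive


class TestGroupMeanTest:
    def test_identical_groups(self):
        res = group_mean_test([5.0, 5.0], [5.0, 5.0])
        assert res["difference"] == 0.0 and res["p_value"] == 1.0

    def test_hand_welch(self):
        res = group_mean_test(superior=[10.0, 12.0], inferior=[4.0, 6.0])
        assert res["difference"] == pytest.approx(-6.0)
        assert res["t"] == pytest.approx(-4.2426, abs=1e-3)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(9)
        rejections = sum(
            group_mean_test(rng.normal(size=8), rng.normal(size=8))["p_value"] < 0.05
            for _ in range(1000)
        )
        # binomial 99.7% bounds around 50/1000
        assert 30 <= rejections <= 72


class TestTukey:
    def test_two_well_separated(self):
        bt = _blue_table("t", {"hi": 100.0, "lo": 1.0}, se=0.5)
        letters = tukey_groups(bt)
        assert letters["hi"] != letters["lo"]
        assert set(letters.values()) == {"a", "b"}

    def test_all_equal_share_letter(self):
        bt = _blue_table("t", {"a": 5.0, "b": 5.0, "c": 5.0}, se=1.0)
        letters = tukey_groups(bt)
        assert set(letters.values()) == {"a"}

    def test_single_genotype(self):
        bt = _blue_table("t", {"only": 5.0})
        assert tukey_groups(bt) == {"only": "a"}

    def test_chain_pattern_shares_middle(self):
        # A > B > C with adjacent pairs not separable but extremes separable
        bt = _blue_table("t", {"A": 10.0, "B": 8.6, "C": 7.2}, se=0.45, resid_df=10.0)
        letters = tukey_groups(bt)
        assert set(letters["A"]) & set(letters["B"])
        assert set(letters["B"]) & set(letters["C"])
        assert not set(letters["A"]) & set(letters["C"])
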