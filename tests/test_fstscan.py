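"""Fst statistic, outlier calling, group constructors, sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dhinducer.genodata import GenotypeMatrix, Marker, Pedigree
from dhinducer.fstscan import (
    FstScan,
    GroupPair,
    allele_freq,
    fst_scan,
    fst_snp,
    nam_partition,
    nam_pedigree_pair,
    pedigree_groups,
    phenotype_groups,
    q99_outliers,
    sensitivity,
    sensitivity_test,
)


def brute_force_fst(groups: list[np.ndarray]) -> float:
    """Independent oracle: recompute the heterozygosity partition from raw
    call vectors, scalar arithmetic only."""
    ps, ns = [], []
    for calls in groups:
        obs = [c for c in calls if c != 0]
        ps.append(sum(1 for c in obs if c == 1) / len(obs))
        ns.append(len(obs))
    total = sum(ns)
    cs = [n / total for n in ns]
    pbar = sum(c * p for c, p in zip(cs, ps))
    het_total = pbar * (1 - pbar)
    if het_total == 0:
        return float("nan")
    het_within = sum(c * p * (1 - p) for c, p in zip(cs, ps))
    return (het_total - het_within) / het_total


class TestAlleleFreq:
    @pytest.mark.parametrize(
        "calls, p, n",
        [
            ([1, 1, -1, 1], 0.75, 4),
            ([1, 1, 1], 1.0, 3),
            ([1, 0, -1], 0.5, 2),
        ],
    )
    def test_examples(self, calls, p, n):
        got_p, got_n = allele_freq(np.array(calls, np.int8))
        assert got_p == pytest.approx(p)
        assert got_n == n

    def test_all_missing(self):
        with pytest.raises(ValueError):
            allele_freq(np.zeros(3, np.int8))


class TestFstSnp:
    @pytest.mark.parametrize(
        "p, n, expected",
        [
            ((0.3, 0.3), (10, 10), 0.0),
            ((1.0, 0.0), (10, 10), 1.0),
            ((0.8, 0.2), (10, 10), 0.36),
            ((1.0, 0.5), (1, 3), 0.2),
        ],
    )
    def test_hand_values(self, p, n, expected):
        assert fst_snp(p, n) == pytest.approx(expected, abs=1e-12)

    def test_pooled_monomorphic_undefined(self):
        assert np.isnan(fst_snp((1.0, 1.0), (5, 5)))

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            fst_snp((0.5,), (5,))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            g1 = rng.choice([-1, 1, 0], rng.integers(2, 12), p=[0.4, 0.5, 0.1])
            g2 = rng.choice([-1, 1, 0], rng.integers(2, 12), p=[0.5, 0.4, 0.1])
            if (g1 != 0).sum() == 0 or (g2 != 0).sum() == 0:
                continue
            p1, n1 = allele_freq(g1)
            p2, n2 = allele_freq(g2)
            ours = fst_snp((p1, p2), (n1, n2))
            oracle = brute_force_fst([g1, g2])
            if np.isnan(oracle):
                assert np.isnan(ours)
            else:
                assert ours == pytest.approx(oracle, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=2, max_size=5),
        st.lists(st.integers(1, 50), min_size=5, max_size=5),
    )
    def test_within_unit_interval(self, freqs, sizes):
        v = fst_snp(freqs, sizes[: len(freqs)])
        if not np.isnan(v):
            assert -1e-12 <= v <= 1 + 1e-12


class TestFstScan:
    def _panel(self, calls, ids=None):
        calls = np.asarray(calls, np.int8)
        markers = [Marker(f"m{j}", "1", j + 1) for j in range(calls.shape[1])]
        ids = ids or [f"L{i}" for i in range(calls.shape[0])]
        return GenotypeMatrix(ids, markers, calls)

    def test_identical_groups_zero(self):
        panel = self._panel([[1, -1], [1, 1], [1, -1], [1, 1]])
        pair = GroupPair("x", frozenset(["L0", "L1"]), frozenset(["L2", "L3"]))
        scan = fst_scan(panel, pair)
        # marker 0 monomorphic in the pool -> undefined; marker 1 identical freqs -> 0
        assert np.isnan(scan.fst[0])
        assert scan.fst[1] == pytest.approx(0.0, abs=1e-12)

    def test_opposite_fixation_is_one(self):
        panel = self._panel([[1], [1], [-1], [-1]])
        pair = GroupPair("x", frozenset(["L0", "L1"]), frozenset(["L2", "L3"]))
        assert fst_scan(panel, pair).fst[0] == pytest.approx(1.0)

    def test_label_swap_invariance(self, small_study):
        panel = small_study.panel
        ids = panel.line_ids
        a, b = frozenset(ids[:40]), frozenset(ids[40:80])
        f_ab = fst_scan(panel, GroupPair("ab", a, b)).fst
        f_ba = fst_scan(panel, GroupPair("ba", b, a)).fst
        np.testing.assert_allclose(f_ab, f_ba, equal_nan=True, atol=1e-15)

    def test_random_split_near_null(self, small_study):
        panel = small_study.panel
        rng = np.random.default_rng(0)
        ids = np.array(panel.line_ids)
        rng.shuffle(ids)
        pair = GroupPair("null", frozenset(ids[:50]), frozenset(ids[50:100]))
        fst = fst_scan(panel, pair).fst
        assert np.nanmean(fst) < 0.05  # null expectation ~ 1/(2 n_per_group)

    def test_scan_matches_fst_snp_per_marker(self):
        rng = np.random.default_rng(7)
        calls = rng.choice([-1, 1, 0], (12, 30), p=[0.45, 0.45, 0.1]).astype(np.int8)
        panel = self._panel(calls)
        ids = panel.line_ids
        pair = GroupPair("x", frozenset(ids[:5]), frozenset(ids[5:]))
        scan = fst_scan(panel, pair)
        for j in range(30):
            oracle = brute_force_fst([calls[:5, j], calls[5:, j]])
            if np.isnan(oracle):
                assert np.isnan(scan.fst[j])
            else:
                assert scan.fst[j] == pytest.approx(oracle, abs=1e-12)


class TestQ99:
    def _scan(self, values):
        values = np.asarray(values, float)
        pair = GroupPair("t", frozenset(["a"]), frozenset(["b"]))
        return FstScan(pair, [f"m{i}" for i in range(len(values))], values)

    def test_all_equal_no_outliers(self):
        with pytest.warns(UserWarning):
            out = q99_outliers(self._scan(np.full(50, 0.3)))
        assert out == frozenset()

    def test_type7_threshold_1_to_1000(self):
        scan = self._scan(np.arange(1, 1001, dtype=float))
        out = q99_outliers(scan)
        assert scan.q99_threshold == pytest.approx(990.01)
        assert len(out) == 10

    def test_iid_null_outlier_count_calibrated(self):
        rng = np.random.default_rng(1)
        scan = self._scan(rng.random(6636))
        out = q99_outliers(scan)
        assert 54 <= len(out) <= 79  # 99% binomial interval around 66.36

    def test_undefined_excluded_from_quantile(self):
        vals = np.concatenate([np.arange(1, 201, dtype=float), [np.nan] * 50])
        scan = self._scan(vals)
        out = q99_outliers(scan)
        assert scan.q99_threshold == pytest.approx(np.quantile(np.arange(1, 201), 0.99))
        assert len(out) == 2


class TestGroups:
    def _pedigree(self):
        pairs = {}
        for i in range(1, 5):
            pairs[f"A_d{i}"] = ("PA", "PB")
        for i in range(1, 5):
            pairs[f"B_d{i}"] = ("PA", "PC")
        return Pedigree.from_parent_pairs(pairs, reference_lines=["PA"])

    def test_top_bottom_selection(self):
        ped = Pedigree.from_parent_pairs({f"d{i}": ("P", "Q") for i in range(1, 5)})
        blues = {"d1": 1.0, "d2": 2.0, "d3": 3.0, "d4": 4.0}
        pair = phenotype_groups(blues, ped, k=2)
        assert pair.group_a == frozenset(["d4", "d3"])
        assert pair.group_b == frozenset(["d1", "d2"])

    def test_tie_broken_lexicographically(self):
        ped = Pedigree.from_parent_pairs({f"d{i}": ("P", "Q") for i in range(1, 7)})
        blues = {"d1": 1.0, "d2": 5.0, "d3": 5.0, "d4": 5.0, "d5": 0.0, "d6": 2.0}
        pair = phenotype_groups(blues, ped, k=2)
        # three-way tie at the top: lexicographically smaller ids win
        assert pair.group_a == frozenset(["d2", "d3"])

    def test_small_family_skipped_with_warning(self):
        ped = Pedigree.from_parent_pairs(
            {"d1": ("P", "Q"), "d2": ("P", "Q"), "d3": ("P", "Q"),
             "e1": ("P", "R"), "e2": ("P", "R"), "e3": ("P", "R"), "e4": ("P", "R")}
        )
        blues = {k: float(i) for i, k in enumerate(["d1", "d2", "d3", "e1", "e2", "e3", "e4"])}
        with pytest.warns(UserWarning, match="P/Q"):
            pair = phenotype_groups(blues, ped, k=2)
        assert pair.group_a | pair.group_b <= {"e1", "e2", "e3", "e4"}

    def test_disjoint_under_total_tie(self):
        ped = Pedigree.from_parent_pairs({f"d{i}": ("P", "Q") for i in range(1, 5)})
        blues = {f"d{i}": 1.0 for i in range(1, 5)}
        pair = phenotype_groups(blues, ped, k=2)
        assert not pair.group_a & pair.group_b

    def test_pedigree_groups_overlap_rejected(self):
        ped = self._pedigree()
        with pytest.raises(ValueError):
            pedigree_groups(ped, {"PA", "PB"}, {"PA", "A_d1"})

    def test_nam_partition_families(self):
        ped = self._pedigree()
        pops = nam_partition(ped, ["PA"])
        assert pops == {"PA": ["PA/PB", "PA/PC"]}

    def test_nam_partition_half_diallel(self):
        from dhinducer.simulate import build_diallel

        founders = [f"P{i}" for i in range(1, 9)]
        pairs = {}
        for a, b in build_diallel(founders):
            pairs[f"{a}x{b}_d1"] = (a, b)
        ped = Pedigree.from_parent_pairs(pairs, reference_lines=founders[:3])
        pops = nam_partition(ped)
        assert set(pops) == {"P1", "P2", "P3"}
        assert all(len(f) == 7 for f in pops.values())
        # family shared by two reference parents appears in both populations
        assert "P1/P2" in pops["P1"] and "P1/P2" in pops["P2"]

    def test_nam_pedigree_pair_unions_parents(self):
        ped = self._pedigree()
        pair = nam_pedigree_pair(ped, "PA", ["PA/PB", "PA/PC"])
        assert pair.group_a == frozenset(["PA", "PB", "PC"])
        assert len(pair.group_b) == 8

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            nam_partition(self._pedigree(), ["PZ"])


class TestSensitivity:
    @pytest.mark.parametrize(
        "ped, phe, expected",
        [
            ({"a", "b"}, {"a", "b"}, 1.0),
            ({"a", "b"}, {"c", "d"}, 0.0),
            ({"a", "b", "c", "d"}, {"c", "d", "e", "f", "g"}, 0.4),
        ],
    )
    def test_ratio(self, ped, phe, expected):
        assert sensitivity(ped, phe) == pytest.approx(expected)

    def test_empty_phenotype_set_flagged(self):
        with pytest.raises(ValueError):
            sensitivity({"a"}, set())

    def test_all_zero_not_rejected(self):
        res = sensitivity_test([0.0, 0.0, 0.0])
        assert res.mean_sensitivity == 0.0
        assert res.p_value > 0.05

    def test_zero_variance_degenerate_limit(self):
        res = sensitivity_test([0.4, 0.4, 0.4])
        assert res.mean_sensitivity == pytest.approx(0.4)
        assert res.p_value == 0.0  # degenerate limit, documented

    def test_hand_t_statistic(self):
        res = sensitivity_test([0.02, 0.04, 0.06])
        assert res.t_statistic == pytest.approx(3.4641, abs=1e-3)
        assert res.p_value == pytest.approx(0.0371, abs=2e-3)

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            sensitivity_test([0.5])
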