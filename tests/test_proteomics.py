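"""Spectral-count normalization, correlation, signed-rank test, two-way ANOVA."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, wilcoxon

from rnpfootprint.proteomics import (
    UnbalancedDesignError,
    normalize_counts,
    paired_class_test,
    per_protein_class_anova,
    signed_rank_test,
    size_correlation,
)


def make_table(counts, lengths=None, classes=("exomere",), n_rep=1):
    """counts: dict protein -> per-(class,rep) count or scalar."""
    rows = []
    for i, (prot, c) in enumerate(counts.items()):
        length = lengths[prot] if lengths else 100 + 10 * i
        for ci, cls in enumerate(classes):
            for r in range(1, n_rep + 1):
                if np.isscalar(c):
                    val = c
                else:
                    val = c[(cls, r)] if isinstance(c, dict) else c[ci]
                rows.append((prot, length, cls, r, val))
    return pd.DataFrame(
        rows, columns=["protein_id", "length_aa", "class", "replicate", "raw_count"]
    )


class TestNormalizeCounts:
    def test_stated_arithmetic(self):
        df = make_table({"P1": 20, "P2": 1980})
        out = normalize_counts(df, scale=1e4)
        row = out[out.protein_id == "P1"].iloc[0]
        assert row["norm"] == pytest.approx(100.0)
        assert row["norm_log2"] == pytest.approx(math.log2(101), abs=1e-9)

    def test_zero_count_maps_to_zero_log(self):
        df = make_table({"P1": 0, "P2": 50})
        out = normalize_counts(df)
        assert out.loc[out.protein_id == "P1", "norm_log2"].iloc[0] == 0.0

    def test_equal_raw_equal_norm(self):
        df = make_table({f"P{i}": 7 for i in range(5)})
        out = normalize_counts(df)
        assert out["norm_log2"].nunique() == 1

    def test_norm_sums_to_scale_per_sample(self):
        rng = np.random.default_rng(0)
        df = make_table(
            {f"P{i}": list(rng.integers(0, 50, 2)) for i in range(8)},
            classes=("exomere", "supermere"),
        )
        out = normalize_counts(df, scale=1e4)
        sums = out.groupby(["class", "replicate"])["norm"].sum()
        assert np.allclose(sums, 1e4)

    def test_zero_total_sample_rejected(self):
        df = make_table({"P1": [5, 0], "P2": [3, 0]}, classes=("a", "b"))
        with pytest.raises(ValueError):
            normalize_counts(df)


class TestSizeCorrelation:
    def test_monotone_increasing(self):
        df = make_table({f"P{i}": 10 * (i + 1) for i in range(5)})
        res = size_correlation(df, sample_class="exomere")
        assert res.rho == pytest.approx(1.0)
        # only the two perfectly monotone rank orders reach |rho| = 1
        assert res.pvalue == pytest.approx(2 / math.factorial(5))
        assert res.method == "exact-permutation"

    def test_monotone_decreasing(self):
        df = make_table({f"P{i}": 10 * (5 - i) for i in range(5)})
        res = size_correlation(df, sample_class="exomere")
        assert res.rho == pytest.approx(-1.0)

    def test_tie_fixture_matches_rank_formula_oracle(self):
        counts = {"P0": 5, "P1": 5, "P2": 9, "P3": 30, "P4": 12, "P5": 21}
        df = make_table(counts)
        res = size_correlation(df, sample_class="exomere")
        # independent oracle: Pearson on midranks computed from scratch
        x = normalize_counts(df).groupby("protein_id")["norm_log2"].mean()
        y = df.groupby("protein_id")["length_aa"].first()
        rx, ry = rankdata(x[y.index]), rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_warns_nan(self):
        df = make_table({f"P{i}": 4 for i in range(6)})
        with pytest.warns(UserWarning):
            res = size_correlation(df, sample_class="exomere")
        assert math.isnan(res.rho)

    def test_too_few_proteins(self):
        df = make_table({"P1": 1, "P2": 2, "P3": 3})
        with pytest.raises(ValueError):
            size_correlation(df, sample_class="exomere")

    def test_t_approximation_matches_scipy(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(4)
        df = make_table({f"P{i:02d}": int(c) for i, c in
                         enumerate(rng.integers(1, 200, 20))})
        res = size_correlation(df, sample_class="exomere")
        x = normalize_counts(df).groupby("protein_id")["norm_log2"].mean()
        y = df.groupby("protein_id")["length_aa"].first()
        ref = spearmanr(x[y.index], y)
        assert res.rho == pytest.approx(ref.statistic)
        assert res.pvalue == pytest.approx(ref.pvalue)


def enumeration_p(diffs):
    """Full 2^n sign enumeration oracle for the signed-rank two-sided p."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = [np.dot(signs, ranks) for signs in
            itertools.product([0, 1], repeat=len(d))]
    dist = np.asarray(dist)
    p_le = (dist <= w_obs + 1e-9).mean()
    p_ge = (dist >= w_obs - 1e-9).mean()
    return min(1.0, 2 * min(p_le, p_ge))


class TestSignedRank:
    def test_six_positive_differences(self):
        res = signed_rank_test([0.3, 1.2, 0.7, 2.0, 0.1, 0.5])
        assert res.statistic == 21.0
        assert res.pvalue == pytest.approx(0.03125)
        assert res.method == "exact"

    def test_symmetric_pairs_give_p_one(self):
        res = signed_rank_test([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        assert res.pvalue == pytest.approx(1.0)

    def test_matches_full_enumeration_n10(self, rng):
        for _ in range(10):
            d = rng.normal(size=10)
            res = signed_rank_test(d)
            assert res.pvalue == pytest.approx(enumeration_p(d), abs=1e-12)

    def test_matches_scipy_exact_no_ties(self, rng):
        d = rng.normal(size=12)
        res = signed_rank_test(d)
        ref = wilcoxon(d, alternative="two-sided", method="exact")
        assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_beyond_25(self, rng):
        d = rng.normal(loc=0.3, size=40)
        res = signed_rank_test(d)
        assert res.method == "normal-approximation"
        ref = wilcoxon(d, alternative="two-sided", method="approx", correction=True)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)

    def test_zeros_dropped_and_reported(self):
        res = signed_rank_test([0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        assert res.n_zero_dropped == 2 and res.n_used == 5

    def test_all_zero_is_missing_value(self):
        res = signed_rank_test([0.0, 0.0, 0.0])
        assert math.isnan(res.pvalue)

    def test_fewer_than_five_nonzero_rejected(self):
        with pytest.raises(ValueError):
            signed_rank_test([1.0, 2.0, 3.0, 0.0])


class TestPairedClassTest:
    def test_undetected_proteins_enter_as_zero(self):
        # P9 detected only in exomere: pairing keeps it at norm_log2 = 0
        counts = {f"P{i}": {("exomere", 1): 10 + i, ("supermere", 1): 5}
                  for i in range(9)}
        counts["P9"] = {("exomere", 1): 50, ("supermere", 1): 0}
        df = make_table(counts, classes=("exomere", "supermere"))
        res = paired_class_test(df, "exomere", "supermere")
        assert res.n_used == 10

    def test_group_enrichment_detected(self):
        # six proteins at 4x relative share in exomere, six at parity; the
        # paired test on the enriched group alone is one-sided-extreme
        counts = {f"P{i}": {("exomere", 1): 80, ("supermere", 1): 20}
                  for i in range(6)}
        counts.update({f"B{i}": {("exomere", 1): 20, ("supermere", 1): 20}
                       for i in range(6)})
        df = make_table(counts, classes=("exomere", "supermere"))
        group = [f"P{i}" for i in range(6)]
        res = paired_class_test(df, "exomere", "supermere", protein_subset=group)
        assert res.pvalue == pytest.approx(0.03125)
        assert res.statistic == 21.0  # every difference positive


def brute_force_two_way_ss(df):
    """Direct sums-of-squares partition for a balanced protein x class design."""
    y = df["norm_log2"].to_numpy()
    grand = y.mean()
    ss_total = ((y - grand) ** 2).sum()
    gp = df.groupby("protein_id")["norm_log2"].mean()
    gc = df.groupby("class")["norm_log2"].mean()
    gpc = df.groupby(["protein_id", "class"])["norm_log2"].mean()
    n_p, n_c = len(gp), len(gc)
    r = len(df) // (n_p * n_c)
    ss_p = n_c * r * ((gp - grand) ** 2).sum()
    ss_c = n_p * r * ((gc - grand) ** 2).sum()
    ss_cells = r * ((gpc - grand) ** 2).sum()
    ss_int = ss_cells - ss_p - ss_c
    ss_resid = ss_total - ss_cells
    return ss_p, ss_c, ss_int, ss_resid


class TestTwoWayAnova:
    def test_all_cells_equal(self):
        df = make_table({f"P{i}": 5 for i in range(3)},
                        classes=("a", "b"), n_rep=2)
        res = per_protein_class_anova(df)
        assert res.anova_table.loc["class", "F"] == 0.0
        assert (res.comparisons["p_adj"] == 1.0).all()

    def test_sums_of_squares_match_brute_force(self):
        rng = np.random.default_rng(9)
        counts = {
            f"P{i}": {(c, r): int(rng.integers(1, 60))
                      for c in ("a", "b") for r in (1, 2)}
            for i in range(2)
        }
        df = normalize_counts(make_table(counts, classes=("a", "b"), n_rep=2))
        res = per_protein_class_anova(df)
        ss_p, ss_c, ss_int, ss_resid = brute_force_two_way_ss(df)
        assert res.anova_table.loc["protein", "sum_sq"] == pytest.approx(ss_p)
        assert res.anova_table.loc["class", "sum_sq"] == pytest.approx(ss_c)
        assert res.anova_table.loc["protein:class", "sum_sq"] == pytest.approx(ss_int)
        assert res.anova_table.loc["residual", "sum_sq"] == pytest.approx(ss_resid)

    def test_shifted_protein_flagged_alone(self):
        rng = np.random.default_rng(7)
        rows = []
        for i in range(5):
            for cls in ("a", "b", "c"):
                for r in (1, 2, 3):
                    val = 5.0 + rng.normal(0, 0.05)
                    if i == 2 and cls == "b":
                        val += 3.0
                    rows.append((f"P{i}", 100, cls, r, val))
        df = pd.DataFrame(rows, columns=["protein_id", "length_aa", "class",
                                         "replicate", "norm_log2"])
        df["raw_count"] = 1
        res = per_protein_class_anova(df)
        sig = res.comparisons[res.comparisons["p_adj"] < 0.05]
        assert set(sig["protein_id"]) == {"P2"}
        assert all("b" in (row.class_a, row.class_b) for row in sig.itertuples())

    def test_tukey_quantiles_against_tabulated(self):
        # studentized range upper tail: q_{0.05}(k=3, df=12) = 3.773
        from scipy.stats import studentized_range

        assert studentized_range.sf(3.773, 3, 12) == pytest.approx(0.05, abs=1e-3)

    def test_unbalanced_rejected(self):
        df = make_table({"P1": 5, "P2": 6}, classes=("a", "b"), n_rep=2)
        df = df.drop(df.index[-1])
        with pytest.raises(UnbalancedDesignError):
            per_protein_class_anova(df)
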