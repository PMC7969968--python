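"""Normalization, the Wald test, BH adjustment, and DEG-set construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import matrix_from_arrays, nb_counts
from regulonpulse.diffexpr import (
    DEGSet,
    DEResult,
    bh_adjust,
    call_degs,
    de_test,
    read_de_table,
    size_factors,
    unique_degs,
    write_de_table,
)
from regulonpulse.errors import ComputationError, UsageError


class TestSizeFactors:
    def test_hand_example(self, tiny_counts):
        # every gene doubles between columns -> factors (1/sqrt 2, sqrt 2)
        np.testing.assert_allclose(
            size_factors(tiny_counts), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_identical_columns_get_equal_factors(self):
        arr = np.array([[5, 5, 5], [80, 80, 80], [300, 300, 300]])
        np.testing.assert_allclose(size_factors(arr), np.ones(3), rtol=1e-12)

    def test_scaling_a_column_scales_its_relative_factor(self):
        # only factor ratios are identified (the geometric-mean denominator
        # absorbs a common c**(1/n)); the scaled column's ratio to any other
        # column scales by exactly c
        rng = np.random.default_rng(0)
        arr = rng.integers(1, 500, size=(50, 4)).astype(float)
        base = size_factors(arr)
        scaled = arr.copy()
        scaled[:, 2] *= 3
        after = size_factors(scaled)
        np.testing.assert_allclose(
            after[2] / after[0], 3 * base[2] / base[0], rtol=1e-12
        )

    def test_no_universally_expressed_gene_is_an_error(self):
        with pytest.raises(ComputationError, match="filter"):
            size_factors(np.array([[0, 5], [5, 0]]))


class TestBH:
    def test_step_up_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], rtol=1e-12
        )

    def test_single_p_unchanged_and_all_ones_stay_one(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_missing_values_excluded_from_m_and_preserved(self):
        out = bh_adjust([0.01, np.nan, 0.02, 0.03])
        assert np.isnan(out[1])
        np.testing.assert_allclose(out[[0, 2, 3]], [0.03, 0.03, 0.03], rtol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(UsageError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_statsmodels_step_up(self, pvals):
        from statsmodels.stats.multitest import multipletests

        expected = multipletests(pvals, method="fdr_bh")[1]
        np.testing.assert_allclose(bh_adjust(pvals), expected, atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_monotone_and_dominates_raw_p(self, pvals):
        out = bh_adjust(pvals)
        assert (out >= np.asarray(pvals) - 1e-15).all()
        order = np.argsort(pvals)
        assert (np.diff(out[order]) >= -1e-15).all()


class TestDeTest:
    def test_null_gene_has_small_statistic_and_planted_fold_recovered(self):
        rng = np.random.default_rng(42)
        G = 1600
        mu = 10 ** rng.uniform(2, 3, G)
        mean = np.tile(mu[:, None], (1, 6)).astype(float)
        mean[:200, 3:] *= 4.0  # four-fold planted in a mostly-null background
        counts = nb_counts(rng, mean, 0.1)
        matrix = matrix_from_arrays(counts, ["a"] * 3 + ["b"] * 3)
        res = de_test(matrix, "a", "b")
        planted = res.table["log2fc"][:200]
        assert abs(np.median(planted) - 2.0) < 0.5
        assert abs(np.median(res.table["log2fc"][200:])) < 0.2

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(7)
        G = 2000
        mu = 10 ** rng.uniform(1, 3, G)
        counts = nb_counts(rng, np.tile(mu[:, None], (1, 6)), 0.1)
        matrix = matrix_from_arrays(counts, ["a"] * 3 + ["b"] * 3)
        res = de_test(matrix, "a", "b")
        frac = np.nanmean(res.table["pvalue"] < 0.05)
        assert 0.02 < frac < 0.08

    def test_all_zero_gene_gets_missing_p(self):
        counts = np.array([[0, 0, 0, 0], [10, 12, 11, 9], [100, 90, 110, 95]])
        matrix = matrix_from_arrays(counts, ["a", "a", "b", "b"])
        res = de_test(matrix, "a", "b")
        assert np.isnan(res.table["pvalue"].iloc[0])
        assert np.isnan(res.table["padj"].iloc[0])

    def test_padj_never_below_pvalue(self):
        rng = np.random.default_rng(3)
        counts = nb_counts(rng, np.full((300, 6), 50.0), 0.2)
        matrix = matrix_from_arrays(counts, ["a"] * 3 + ["b"] * 3)
        t = de_test(matrix, "a", "b").table
        ok = t["pvalue"].notna()
        assert (t.loc[ok, "padj"] >= t.loc[ok, "pvalue"] - 1e-15).all()

    def test_unknown_condition_and_single_replicate_rejected(self):
        counts = np.array([[5, 6, 7]])
        matrix = matrix_from_arrays(counts, ["a", "a", "b"])
        with pytest.raises(UsageError):
            de_test(matrix, "a", "c")
        with pytest.raises(UsageError, match="replicates"):
            de_test(matrix, "a", "b")

    def test_de_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        counts = nb_counts(rng, np.full((50, 4), 80.0), 0.1)
        matrix = matrix_from_arrays(counts, ["a", "a", "b", "b"])
        res = de_test(matrix, "a", "b")
        write_de_table(res, tmp_path / "de.tsv")
        back = read_de_table(tmp_path / "de.tsv", "b", "a")
        pd.testing.assert_frame_equal(
            back.table, res.table.rename_axis("gene"), check_exact=False
        )


def _result(genes: dict[str, tuple[float, float]]) -> DEResult:
    table = pd.DataFrame(
        {"base_mean": 100.0,
         "log2fc": [v[0] for v in genes.values()],
         "pvalue": [v[1] for v in genes.values()],
         "padj": [v[1] for v in genes.values()]},
        index=list(genes),
    )
    return DEResult("amp", "stat", table)


class TestCallDegs:
    def test_threshold_decision_table(self):
        res = _result(
            {
                "clear_up": (1.5, 0.05),
                "exactly_twofold": (1.0, 0.05),   # strict inequality: excluded
                "not_significant": (3.0, 0.15),
                "clear_down": (-2.0, 0.01),
                "alpha_boundary": (2.0, 0.1),     # padj == alpha: excluded
            }
        )
        degs = call_degs(res, 2.0, 0.1)
        assert degs.up == {"clear_up"}
        assert degs.down == {"clear_down"}

    def test_invalid_thresholds_rejected(self):
        res = _result({"g": (1.0, 0.5)})
        with pytest.raises(UsageError):
            call_degs(res, fold_cutoff=1.0)
        with pytest.raises(UsageError):
            call_degs(res, alpha=0.0)


class TestUniqueDegs:
    def test_set_difference_within_direction(self):
        treated = DEGSet("amp", "stat", frozenset("abc"), frozenset(), 2.0, 0.1)
        untreated = DEGSet("unt", "stat", frozenset("b"), frozenset(), 2.0, 0.1)
        assert unique_degs(treated, untreated).up == {"a", "c"}

    def test_removal_is_by_gene_id_across_directions(self):
        treated = DEGSet("amp", "stat", frozenset("ab"), frozenset(), 2.0, 0.1)
        untreated = DEGSet("unt", "stat", frozenset(), frozenset("a"), 2.0, 0.1)
        uniq = unique_degs(treated, untreated)
        assert uniq.up == {"b"} and uniq.down == frozenset()

    def test_empty_untreated_returns_treated(self):
        treated = DEGSet("amp", "stat", frozenset("ab"), frozenset("c"), 2.0, 0.1)
        untreated = DEGSet("unt", "stat", frozenset(), frozenset(), 2.0, 0.1)
        uniq = unique_degs(treated, untreated)
        assert uniq.up == treated.up and uniq.down == treated.down

    def test_mismatched_reference_rejected(self):
        treated = DEGSet("amp", "stat", frozenset(), frozenset(), 2.0, 0.1)
        untreated = DEGSet("unt", "exp", frozenset(), frozenset(), 2.0, 0.1)
        with pytest.raises(UsageError, match="reference"):
            unique_degs(treated, untreated)
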