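import numpy as np
import pandas as pd
import pytest
from scipy.stats import fisher_exact as scipy_fisher

import methtile as mt
from methtile.dmr import call_dmr_stats

from conftest import make_methylome
from oracles import fisher_two_sided_oracle


class TestFisher:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ((8, 2, 2, 8), 0.023013),
            ((5, 5, 5, 5), 1.0),
            ((10, 0, 0, 10), 2 / 184756),
        ],
    )
    def test_reference_values(self, table, expected):
        assert mt.fisher_exact_two_sided(*table) == pytest.approx(expected, rel=1e-4)

    def test_zero_margin_convention(self):
        assert mt.fisher_exact_two_sided(0, 0, 5, 5) == 1.0
        assert mt.fisher_exact_two_sided(0, 5, 0, 5) == 1.0

    def test_matches_enumeration_oracle_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(300):
            n1, n2 = rng.integers(1, 31, 2)
            a = rng.integers(0, n1 + 1)
            c = rng.integers(0, n2 + 1)
            got = mt.fisher_exact_two_sided(a, n1 - a, c, n2 - c)
            assert got == pytest.approx(
                fisher_two_sided_oracle(a, n1 - a, c, n2 - c), abs=1e-12
            )

    def test_matches_scipy_cross_check(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            a, b, c, d = rng.integers(0, 40, 4)
            got = mt.fisher_exact_two_sided(a, b, c, d)
            assert got == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], rel=1e-9, abs=1e-12)

    def test_large_table_path_agrees_with_scipy(self):
        # pooled bins exceed the exact-integer limit
        for table in ((400, 150, 180, 350), (900, 100, 860, 140)):
            got = mt.fisher_exact_two_sided(*table)
            a, b, c, d = table
            assert got == pytest.approx(scipy_fisher([[a, b], [c, d]])[1], rel=1e-6)

    def test_symmetry_invariances(self):
        p = mt.fisher_exact_two_sided(7, 3, 2, 9)
        assert mt.fisher_exact_two_sided(2, 9, 7, 3) == p  # row swap
        assert mt.fisher_exact_two_sided(3, 7, 9, 2) == p  # column swap
        assert mt.fisher_exact_two_sided(7, 2, 3, 9) == p  # transpose


class TestTileAndPool:
    def _pair(self, rows_t, rows_c):
        return (
            make_methylome(rows_t, "t", "stress"),
            make_methylome(rows_c, "c", "control"),
        )

    def test_bin_boundaries(self):
        t, c = self._pair(
            [("chr1", 99, "+", "CG", 5, 10), ("chr1", 100, "+", "CG", 5, 10)],
            [("chr1", 99, "+", "CG", 1, 10), ("chr1", 100, "+", "CG", 1, 10)],
        )
        bins = mt.tile_and_pool(t, c, "CG")
        assert sorted(bins["start"]) == [0, 100]

    def test_site_missing_in_one_sample_excluded(self):
        t, c = self._pair(
            [("chr1", 10, "+", "CG", 5, 10), ("chr1", 20, "+", "CG", 5, 10)],
            [("chr1", 10, "+", "CG", 1, 10)],
        )
        bins = mt.tile_and_pool(t, c, "CG")
        assert bins.iloc[0]["n_cytosines"] == 1
        assert bins.iloc[0]["meth_t"] == 5

    def test_pooled_levels_are_weighted(self):
        t, c = self._pair(
            [("chr1", 10, "+", "CG", 10, 10), ("chr1", 20, "+", "CG", 0, 30)],
            [("chr1", 10, "+", "CG", 5, 10), ("chr1", 20, "+", "CG", 15, 30)],
        )
        bins = mt.tile_and_pool(t, c, "CG")
        assert bins.iloc[0]["level_t"] == pytest.approx(10 / 40)
        assert bins.iloc[0]["level_c"] == pytest.approx(20 / 40)


class TestFilterBins:
    def _bins(self, n_cyt, depth_t, depth_c):
        return pd.DataFrame(
            [{
                "chrom": "chr1", "start": 0, "end": 100, "context": "CG",
                "n_cytosines": n_cyt,
                "meth_t": 1, "unmeth_t": 1, "meth_c": 1, "unmeth_c": 1,
                "level_t": 0.5, "level_c": 0.5,
                "mean_depth_t": depth_t, "mean_depth_c": depth_c,
            }]
        )

    def test_too_few_cytosines_excluded(self):
        assert len(mt.filter_bins(self._bins(2, 25, 25))) == 0

    def test_low_depth_in_either_sample_excluded(self):
        assert len(mt.filter_bins(self._bins(3, 25, 4.9))) == 0
        assert len(mt.filter_bins(self._bins(3, 4.9, 25))) == 0

    def test_passing_bin_retained(self):
        assert len(mt.filter_bins(self._bins(3, 25, 25))) == 1


def _bin_row(meth_t, total_t, meth_c, total_c, start=0, context="CG", n_cyt=5):
    return {
        "chrom": "chr1", "start": start, "end": start + 100, "context": context,
        "n_cytosines": n_cyt,
        "meth_t": meth_t, "unmeth_t": total_t - meth_t,
        "meth_c": meth_c, "unmeth_c": total_c - meth_c,
        "level_t": meth_t / total_t, "level_c": meth_c / total_c,
        "mean_depth_t": total_t / n_cyt, "mean_depth_c": total_c / n_cyt,
    }


def _dmc_rows(start, n, context="CG"):
    return pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(start, start + n),
            "strand": "+",
            "context": context,
            "level_t": 0.9,
            "level_c": 0.1,
            "p_value": 1e-6,
            "q_value": 1e-4,
            "direction": "hyper",
        }
    )


class TestCallDmrs:
    def test_passing_bin_is_hyper_dmr(self):
        bins = mt.add_bin_pvalues(pd.DataFrame([_bin_row(80, 100, 20, 100)]))
        dmrs = mt.call_dmrs(bins, _dmc_rows(0, 3))
        assert len(dmrs) == 1
        row = dmrs.iloc[0]
        assert row["direction"] == "hyper"
        assert row["level_diff"] == pytest.approx(0.6)
        assert row["fold"] == pytest.approx(4.0)

    def test_small_difference_rejected(self):
        bins = mt.add_bin_pvalues(pd.DataFrame([_bin_row(45, 100, 30, 100)]))
        assert len(mt.call_dmrs(bins, _dmc_rows(0, 5))) == 0

    def test_small_fold_rejected(self):
        # diff 0.22 >= 0.2 but fold 1.79 < 2
        bins = mt.add_bin_pvalues(pd.DataFrame([_bin_row(250, 500, 140, 500)]))
        row = mt.call_dmrs(bins, _dmc_rows(0, 5))
        assert len(row) == 0

    def test_too_few_dmcs_rejected(self):
        bins = mt.add_bin_pvalues(pd.DataFrame([_bin_row(80, 100, 20, 100)]))
        assert len(mt.call_dmrs(bins, _dmc_rows(0, 2))) == 0

    def test_dmcs_counted_within_matching_bin_and_context(self):
        bins = mt.add_bin_pvalues(pd.DataFrame([_bin_row(80, 100, 20, 100)]))
        other_bin = _dmc_rows(500, 3)
        other_ctx = _dmc_rows(0, 3, context="CHH")
        assert len(mt.call_dmrs(bins, other_bin)) == 0
        assert len(mt.call_dmrs(bins, other_ctx)) == 0

    def test_empty_input(self):
        from methtile.dmr import _empty_bins

        out = mt.call_dmrs(_empty_bins("CG", 100), _dmc_rows(0, 3))
        assert len(out) == 0


class TestCallDmcs:
    def test_identical_counts_not_dmc(self):
        t = make_methylome([("chr1", 1, "+", "CG", 5, 10)], "t")
        c = make_methylome([("chr1", 1, "+", "CG", 5, 10)], "c")
        assert len(mt.call_dmcs(t, c)) == 0

    def test_extreme_difference_is_hyper_dmc(self):
        t = make_methylome([("chr1", 1, "+", "CG", 20, 20)], "t")
        c = make_methylome([("chr1", 1, "+", "CG", 0, 20)], "c")
        dmcs = mt.call_dmcs(t, c)
        assert len(dmcs) == 1
        assert dmcs.iloc[0]["direction"] == "hyper"
        # single test: q equals the enumeration p-value 2/C(40,20)
        assert dmcs.iloc[0]["q_value"] == pytest.approx(
            fisher_two_sided_oracle(20, 0, 0, 20), abs=1e-15
        )

    def test_low_depth_site_skipped(self):
        t = make_methylome([("chr1", 1, "+", "CG", 20, 20)], "t")
        c = make_methylome([("chr1", 1, "+", "CG", 0, 3)], "c")
        assert len(mt.call_dmcs(t, c, min_depth=5)) == 0


class TestBhQvalues:
    def test_q_at_least_p_and_single_test_identity(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(size=200)
        q = mt.bh_qvalues(p)
        assert (q >= p - 1e-15).all()
        assert mt.bh_qvalues(np.array([0.037]))[0] == pytest.approx(0.037, abs=0)

    def test_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=500)
        q = mt.bh_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestFourway:
    def test_overlap_counts(self):
        out = mt.fourway_partition({"A": {1, 2}, "B": {2, 3}, "C": set(), "D": set()})
        assert out[("A",)] == 1 and out[("B",)] == 1 and out[("A", "B")] == 1
        assert sum(out.values()) == 3

    def test_identical_sets_all_in_four_way_class(self):
        s = {1, 2, 3}
        out = mt.fourway_partition({"A": s, "B": s, "C": s, "D": s})
        assert out[("A", "B", "C", "D")] == 3
        assert sum(out.values()) == 3

    def test_disjoint_sets(self):
        sets = {
            "A": {f"a{i}" for i in range(2)},
            "B": {f"b{i}" for i in range(3)},
            "C": {f"c{i}" for i in range(4)},
            "D": {f"d{i}" for i in range(5)},
        }
        out = mt.fourway_partition(sets)
        assert [out[(k,)] for k in "ABCD"] == [2, 3, 4, 5]
        assert sum(out.values()) == 14


class TestPipelineProperties:
    def test_swapping_samples_inverts_direction_with_identical_stats(self, small_dataset):
        ds = small_dataset
        fwd, _, _ = mt.detect_dmrs(ds.treatment, ds.control)
        rev, _, _ = mt.detect_dmrs(ds.control, ds.treatment)
        key = ["chrom", "start", "context"]
        merged = fwd.merge(rev, on=key, suffixes=("_f", "_r"))
        assert len(merged) == len(fwd) == len(rev)
        assert (merged["p_value_f"] == merged["p_value_r"]).all()
        assert (merged["q_value_f"] == merged["q_value_r"]).all()
        flip = {"hyper": "hypo", "hypo": "hyper"}
        assert (merged["direction_f"].map(flip) == merged["direction_r"]).all()

    def test_hyper_plus_hypo_equals_total_and_contexts_disjoint(self, small_dataset):
        ds = small_dataset
        dmrs, _, _ = mt.detect_dmrs(ds.treatment, ds.control)
        n_hyper = (dmrs["direction"] == "hyper").sum()
        n_hypo = (dmrs["direction"] == "hypo").sum()
        assert n_hyper + n_hypo == len(dmrs)
        assert not dmrs.duplicated(["chrom", "start", "context"]).any()
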