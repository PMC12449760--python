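"""Count-matrix I/O, compositional transforms, rarefaction, diversity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paleonet import (
    CountMatrix, InputError, UsageError, bin_intervals, classify_hii,
    hellinger, rarefy, read_count_matrix, shannon, to_relative_abundance,
    write_count_matrix,
)


class TestReadWrite:
    def test_round_trip(self, tmp_path, tiny_counts):
        path = tmp_path / "c.csv"
        write_count_matrix(tiny_counts, path)
        back = read_count_matrix(path)
        pd.testing.assert_frame_equal(back.counts, tiny_counts.counts,
                                      check_names=False)

    def test_metadata_columns_recognised(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "sample_id,hii,time_slice,ta,tb\nL1,0.3,top,5,1\nL2,0.05,bottom,2,8\n"
        )
        cm = read_count_matrix(path)
        assert cm.taxa == ["ta", "tb"]
        assert list(cm.meta.columns) == ["hii", "time_slice"]

    def test_tab_delimiter_inferred(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("sample_id\tta\ttb\ns1\t5\t0\ns2\t1\t4\n")
        cm = read_count_matrix(path)
        assert cm.counts.loc["s2", "tb"] == 4

    def test_negative_cell_names_offender(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("sample_id,ta,tb\ns1,5,-3\n")
        with pytest.raises(InputError, match="ta|tb"):
            read_count_matrix(path)

    def test_non_numeric_cell(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("sample_id,ta,tb\ns1,5,x\n")
        with pytest.raises(InputError, match="non-numeric"):
            read_count_matrix(path)

    def test_duplicate_taxon_header(self):
        counts = pd.DataFrame([[1, 2]], index=["s1"], columns=["ta", "ta"])
        with pytest.raises(InputError, match="duplicate"):
            CountMatrix(counts)


class TestTransforms:
    @pytest.mark.parametrize(
        "row,expected",
        [([4, 0], [1.0, 0.0]),
         ([1, 1, 1, 1], [0.25] * 4),
         ([3, 1], [0.75, 0.25])],
    )
    def test_relative_abundance_rows(self, row, expected):
        cm = CountMatrix(pd.DataFrame([row]))
        am = to_relative_abundance(cm)
        np.testing.assert_allclose(am.values.iloc[0], expected)

    def test_zero_row_flagged_not_fatal(self):
        cm = CountMatrix(pd.DataFrame([[2, 2], [0, 0]], index=["a", "b"]))
        am = to_relative_abundance(cm)
        assert am.empty_rows == ["b"]
        np.testing.assert_allclose(am.values.loc["b"], [0, 0])

    @pytest.mark.parametrize(
        "rel,expected",
        [([1.0, 0.0], [1.0, 0.0]),
         ([0.25] * 4, [0.5] * 4),
         ([0.75, 0.25], [np.sqrt(0.75), 0.5])],
    )
    def test_hellinger_values(self, rel, expected):
        cm = CountMatrix(pd.DataFrame([[int(400 * v) for v in rel]]))
        am = hellinger(to_relative_abundance(cm))
        np.testing.assert_allclose(am.values.iloc[0], expected)

    def test_hellinger_rejects_wrong_tag(self, tiny_counts):
        h = hellinger(to_relative_abundance(tiny_counts))
        with pytest.raises(UsageError):
            hellinger(h)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 500), min_size=3, max_size=3),
                    min_size=1, max_size=6))
    def test_row_norm_invariants(self, rows):
        cm = CountMatrix(pd.DataFrame(rows))
        if not (cm.row_totals() > 0).any():
            return
        rel = to_relative_abundance(cm)
        hel = hellinger(rel)
        totals = cm.row_totals().to_numpy()
        sums = rel.values.sum(axis=1).to_numpy()
        sq = (hel.values ** 2).sum(axis=1).to_numpy()
        np.testing.assert_allclose(sums[totals > 0], 1.0, atol=1e-12)
        np.testing.assert_allclose(sq[totals > 0], 1.0, atol=1e-12)


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self, tiny_counts):
        sub = CountMatrix(tiny_counts.counts.iloc[[0]].copy())
        out = rarefy(sub, int(sub.row_totals().iloc[0]), seed=0)
        pd.testing.assert_frame_equal(out.counts, sub.counts)

    def test_depth_one_single_individual(self, tiny_counts):
        out = rarefy(tiny_counts, 1, seed=3)
        assert (out.row_totals() == 1).all()
        assert ((out.counts > 0).sum(axis=1) == 1).all()

    def test_totals_and_dominance_bound(self, tiny_counts):
        out = rarefy(tiny_counts, 5, seed=1)
        assert (out.row_totals() == 5).all()
        assert (out.counts.to_numpy()
                <= tiny_counts.counts.loc[out.samples].to_numpy()).all()

    def test_shallow_samples_dropped(self, tiny_counts):
        # totals are s1=8, s2=5, s3=6, s4=8: depth 7 retains only s1 and s4
        out = rarefy(tiny_counts, 7, seed=0)
        assert set(out.samples) == {"s1", "s4"}

    def test_depth_beyond_all_samples_errors(self, tiny_counts):
        with pytest.raises(UsageError):
            rarefy(tiny_counts, 10_000, seed=0)

    def test_hypergeometric_expectation(self):
        # mean rarefied count of a taxon ~ depth * p_j, within 3 SE
        row = np.array([60, 30, 10])
        depth, reps = 50, 2000
        cm = CountMatrix(pd.DataFrame([row] * 1, index=["s"]))
        draws = np.array(
            [rarefy(cm, depth, seed=k).counts.iloc[0].to_numpy()
             for k in range(reps)]
        )
        n = row.sum()
        for j in range(3):
            p = row[j] / n
            expect = depth * p
            var = depth * p * (1 - p) * (n - depth) / (n - 1)
            se = np.sqrt(var / reps)
            assert abs(draws[:, j].mean() - expect) < 3 * se

    def test_seeded_reproducibility(self, tiny_counts):
        a = rarefy(tiny_counts, 5, seed=7).counts
        b = rarefy(tiny_counts, 5, seed=7).counts
        pd.testing.assert_frame_equal(a, b)


class TestShannon:
    @pytest.mark.parametrize(
        "row,expected",
        [([50, 50], np.log(2)),
         ([100, 0, 0], 0.0),
         ([1, 1, 1, 1, 1], np.log(5))],
    )
    def test_known_values(self, row, expected):
        assert shannon(row) == pytest.approx(expected)

    def test_permutation_invariant_and_uniform_max(self):
        rng = np.random.default_rng(0)
        row = rng.integers(1, 50, size=8)
        assert shannon(row) == pytest.approx(shannon(row[::-1]))
        assert shannon(row) <= np.log(8) + 1e-12
        assert shannon([7] * 8) == pytest.approx(np.log(8))

    def test_all_zero_errors(self):
        with pytest.raises(UsageError):
            shannon([0, 0])

    def test_base_conversion(self):
        assert shannon([50, 50], base=2) == pytest.approx(1.0)


class TestBinIntervals:
    def _core(self):
        counts = pd.DataFrame(
            [[1, 2], [3, 4], [5, 6], [7, 8]],
            index=["i0", "i1", "i2", "i3"],
        )
        meta = pd.DataFrame(
            {"depth_cm": [3.5, 2.5, 1.5, 0.5], "age_ce": [1900., 1940., 1980., 2010.]},
            index=counts.index,
        )
        return CountMatrix(counts, meta)

    def test_singleton_bin_unchanged(self):
        cm = self._core()
        out = bin_intervals(cm, [[0]])
        np.testing.assert_array_equal(out.counts.iloc[0], cm.counts.iloc[0])

    def test_pooling_sums_counts_and_midpoints_age(self):
        cm = self._core()
        out = bin_intervals(cm, [[0, 1]])
        np.testing.assert_array_equal(out.counts.iloc[0], [4, 6])
        assert out.meta["age_ce"].iloc[0] == pytest.approx((1900 + 1940) / 2)
        assert out.row_totals().sum() == cm.row_totals().sum()

    def test_non_contiguous_bin_rejected(self):
        with pytest.raises(UsageError, match="contiguous"):
            bin_intervals(self._core(), [[0, 2]])


class TestClassifyHii:
    @pytest.mark.parametrize(
        "hii,expected",
        [(0.21, "moderate"), (0.05, "low"), (0.5, "high"),
         (0.1, "low"), (0.0, "low"), (1.0, "high"), (0.49, "moderate")],
    )
    def test_thresholds(self, hii, expected):
        assert classify_hii(hii) == expected

    def test_out_of_range(self):
        with pytest.raises(InputError):
            classify_hii(1.2)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    def test_total_and_monotone(self, a, b):
        order = {"low": 0, "moderate": 1, "high": 2}
        lo, hi = sorted([a, b])
        assert order[classify_hii(lo)] <= order[classify_hii(hi)]
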