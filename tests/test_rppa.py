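"""Blank filter, median-centering, HCL clustering and pathway panels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pdmkit.rppa import (
    CENTERED_LOG2,
    DomainError,
    EmptyMatrixError,
    NFIMatrix,
    RAW_LINEAR,
    apply_blank_filter,
    center_log2,
    hcl_cluster,
    pathway_summarize,
)


def matrix_from(values: dict, pathways=None) -> NFIMatrix:
    df = pd.DataFrame(values).T  # keys are proteins, rows are sample vectors
    df.columns = [f"S{i + 1}" for i in range(df.shape[1])]
    pw = pd.Series(pathways or {}, dtype=object)
    return NFIMatrix(df, pw, RAW_LINEAR)


class TestBlankFilter:
    @pytest.mark.parametrize(
        "row, excluded",
        [
            ([0.01, 0.01, 0.01], True),  # at blank level
            ([1.0, 1.0, 1.0], False),
            ([0.01, 0.01, 5.0], True),  # median rule, not max
            ([0.021, 0.021, 0.021], False),  # just above
        ],
    )
    def test_median_rule(self, row, excluded):
        m = matrix_from({"target": row, "keep": [1.0, 1.0, 1.0]})
        filtered, out = apply_blank_filter(m, blank=0.02)
        assert ("target" in out) is excluded
        assert "keep" in filtered.values.index

    def test_retained_values_pass_through_unchanged(self, small_matrix):
        filtered, out = apply_blank_filter(small_matrix)
        assert out == ["P3"]
        pd.testing.assert_frame_equal(
            filtered.values, small_matrix.values.drop(index=["P3"])
        )

    def test_all_proteins_excluded_raises(self):
        m = matrix_from({"a": [0.01, 0.01, 0.01], "b": [0.0, 0.0, 0.0]})
        with pytest.raises(EmptyMatrixError):
            apply_blank_filter(m)


class TestCenterLog2:
    @pytest.mark.parametrize(
        "row, expected",
        [
            ([3.7, 3.7, 3.7], [0.0, 0.0, 0.0]),
            ([1.0, 2.0, 4.0], [-1.0, 0.0, 1.0]),
        ],
    )
    def test_known_rows(self, row, expected):
        m = matrix_from({"p": row})
        out = center_log2(m)
        assert out.scale_tag == CENTERED_LOG2
        np.testing.assert_allclose(out.values.loc["p"].to_numpy(), expected)

    @given(
        st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=3, max_size=9)
    )
    def test_every_centered_row_has_zero_median(self, row):
        out = center_log2(matrix_from({"p": row}))
        assert abs(np.median(out.values.loc["p"])) < 1e-9

    def test_recentering_is_a_no_op(self):
        rng = np.random.default_rng(0)
        m = matrix_from({f"p{i}": rng.lognormal(0, 1, 5) for i in range(10)})
        once = center_log2(m)
        again = center_log2(
            NFIMatrix(np.power(2.0, once.values), once.pathway_of, RAW_LINEAR)
        )
        np.testing.assert_allclose(
            once.values.to_numpy(), again.values.to_numpy(), atol=1e-9
        )

    def test_nonpositive_value_names_protein_and_sample(self):
        m = matrix_from({"good": [1, 2, 3], "bad": [1.0, 0.0, 2.0]})
        with pytest.raises(DomainError, match=r"'bad'.*'S2'"):
            center_log2(m)


class TestHclCluster:
    def test_duplicated_profiles_merge_at_height_zero(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 20)
        df = pd.DataFrame({"A": base, "B": base, "C": rng.normal(0, 1, 20)})
        m = NFIMatrix(df, pd.Series(dtype=object), CENTERED_LOG2)
        result = hcl_cluster(m, k=2)
        assert result.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert result.labels["A"] == result.labels["B"] != result.labels["C"]

    def test_three_sample_merge_order_matches_bruteforce_nearest_pair(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(0, 1, (30, 3)), columns=["A", "B", "C"])
        m = NFIMatrix(df, pd.Series(dtype=object), CENTERED_LOG2)
        result = hcl_cluster(m, k=2)
        # brute-force oracle: pairwise 1 - r, nearest pair merges first,
        # then joins the remaining sample at the average of its distances.
        d = {}
        for i, a in enumerate("ABC"):
            for b in "ABC"[i + 1:]:
                d[(a, b)] = 1.0 - np.corrcoef(df[a], df[b])[0, 1]
        (a, b), h0 = min(d.items(), key=lambda kv: kv[1])
        c = ({"A", "B", "C"} - {a, b}).pop()
        h1 = np.mean(
            [d.get((min(a, c), max(a, c))), d.get((min(b, c), max(b, c)))]
        )
        idx = {s: i for i, s in enumerate("ABC")}
        assert sorted(result.linkage[0, :2]) == sorted([idx[a], idx[b]])
        assert result.linkage[0, 2] == pytest.approx(h0)
        assert result.linkage[1, 2] == pytest.approx(h1)
        assert result.labels[c] != result.labels[a]

    def test_partition_invariant_to_sample_order(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.normal(0, 1, (25, 6)),
                          columns=list("ABCDEF"))
        df[["D", "E", "F"]] += rng.normal(2, 0.1, (25, 3))
        m1 = NFIMatrix(df, pd.Series(dtype=object), CENTERED_LOG2)
        m2 = NFIMatrix(df[list("FDBECA")], pd.Series(dtype=object), CENTERED_LOG2)
        p1 = hcl_cluster(m1, k=2).partition()
        p2 = hcl_cluster(m2, k=2).partition()
        assert sorted(map(tuple, p1.values())) == sorted(map(tuple, p2.values()))

    def test_k_larger_than_sample_count_rejected(self, small_matrix):
        centered = center_log2(apply_blank_filter(small_matrix)[0])
        with pytest.raises(ValueError, match="k="):
            hcl_cluster(centered, k=5)


class TestPathwaySummarize:
    def test_single_protein_panel_median_is_that_protein(self):
        df = pd.DataFrame([[0.5, -0.5, 0.1]], index=["p"], columns=["S1", "S2", "S3"])
        m = NFIMatrix(df, pd.Series({"p": "apoptosis"}), CENTERED_LOG2)
        medians, sets = pathway_summarize(m, panels=("apoptosis",))
        np.testing.assert_allclose(
            medians.loc["apoptosis"].to_numpy(), [0.5, -0.5, 0.1]
        )
        assert list(sets["apoptosis"].index) == ["p"]

    def test_medians_match_sort_based_oracle_and_ignore_protein_order(self):
        rng = np.random.default_rng(4)
        names = [f"p{i}" for i in range(9)]
        df = pd.DataFrame(rng.normal(0, 1, (9, 4)), index=names,
                          columns=list("WXYZ"))
        pw = pd.Series("cell cycle", index=names)
        m = NFIMatrix(df, pw, CENTERED_LOG2)
        shuffled = NFIMatrix(df.loc[names[::-1]], pw, CENTERED_LOG2)
        med1, _ = pathway_summarize(m, panels=("cell cycle",))
        med2, _ = pathway_summarize(shuffled, panels=("cell cycle",))
        for col in "WXYZ":
            oracle = sorted(df[col])[4]  # middle of 9 values
            assert med1.loc["cell cycle", col] == pytest.approx(oracle)
        pd.testing.assert_frame_equal(med1, med2)

    def test_empty_panel_warns_and_is_skipped(self, small_matrix):
        with pytest.warns(UserWarning, match="no member proteins"):
            medians, _ = pathway_summarize(
                center_log2(apply_blank_filter(small_matrix)[0]),
                panels=("cell cycle", "DNA damage response"),
            )
        assert list(medians.index) == ["cell cycle"]
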