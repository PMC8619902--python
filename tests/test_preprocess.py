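"""Typing, collapsing, merging, filtering and imputation contracts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from corrscan.preprocess import (
    DROP,
    NOMINAL,
    NUMERIC,
    DomainTable,
    assemble,
    collapse_longitudinal,
    combined_feature_count,
    filter_features,
    impute,
    infer_feature_kind,
    infer_kinds,
    merge_tables,
    shape_expression,
)
from corrscan.synthetic import generate_expression_domain


class TestInferFeatureKind:
    @pytest.mark.parametrize(
        "values, expected",
        [
            (list(range(9)) + [8] * 10, NOMINAL),  # 9 distinct numbers
            (list(range(10)) + [9] * 10, NUMERIC),  # 10 distinct numbers
            ([f"c{i}" for i in range(20)], NOMINAL),  # 20 distinct texts
            ([f"c{i}" for i in range(21)], DROP),  # 21 distinct texts
            (["a", "b", 1, 2], NOMINAL),  # mixed -> treated as text
            (["1", "2.5", "3"] * 5 + list("abcdefg") * 2, NOMINAL),
        ],
    )
    def test_typing_rules(self, values, expected):
        assert infer_feature_kind(pd.Series(values, dtype=object)) == expected

    def test_unknowns_excluded_from_distinct_count(self):
        # 9 distinct known numbers + NaN: still nominal (NaN is not a value)
        vals = pd.Series(list(range(9)) + [np.nan] * 5, dtype=object)
        assert infer_feature_kind(vals) == NOMINAL

    def test_numeric_strings_count_as_numbers(self):
        vals = pd.Series([str(i) for i in range(15)])
        assert infer_feature_kind(vals) == NUMERIC


class TestCollapseLongitudinal:
    def test_latest_dated_value_wins(self):
        df = pd.DataFrame(
            {"RID": ["p", "p"], "EXAMDATE": [10, 20], "A": [1.0, 2.0]}
        )
        out, last = collapse_longitudinal(df, "RID", "EXAMDATE")
        assert out.loc["p", "A"] == 2.0
        assert last["p"] == 20

    def test_single_visit_identity(self):
        df = pd.DataFrame({"RID": ["p"], "EXAMDATE": [5], "A": [3.0], "B": ["x"]})
        out, _ = collapse_longitudinal(df, "RID", "EXAMDATE")
        assert out.loc["p", "A"] == 3.0
        assert out.loc["p", "B"] == "x"

    def test_known_earlier_value_beats_unknown_later(self):
        # per-feature scan for the latest non-unknown entry
        df = pd.DataFrame(
            {"RID": ["p", "p"], "EXAMDATE": [10, 20], "A": [1.5, np.nan]}
        )
        out, _ = collapse_longitudinal(df, "RID", "EXAMDATE")
        assert out.loc["p", "A"] == 1.5

    def test_undated_rows_keep_first_occurrence(self):
        df = pd.DataFrame({"RID": ["p", "p", "p"], "A": [1.0, 2.0, 3.0]})
        out, last = collapse_longitudinal(df, "RID")
        assert out.loc["p", "A"] == 1.0
        assert last["p"] == -np.inf

    def test_date_ties_keep_first_occurrence(self):
        df = pd.DataFrame(
            {"RID": ["p", "p"], "EXAMDATE": [10, 10], "A": [1.0, 2.0]}
        )
        out, _ = collapse_longitudinal(df, "RID", "EXAMDATE")
        assert out.loc["p", "A"] == 1.0

    def test_dated_row_beats_undated_row(self):
        df = pd.DataFrame(
            {"RID": ["p", "p"], "EXAMDATE": [np.nan, 3], "A": [1.0, 2.0]}
        )
        out, _ = collapse_longitudinal(df, "RID", "EXAMDATE")
        assert out.loc["p", "A"] == 2.0

    def test_iso_dates_parse(self):
        df = pd.DataFrame(
            {
                "RID": ["p", "p"],
                "EXAMDATE": ["2019-01-01", "2019-06-01"],
                "A": [1.0, 2.0],
            }
        )
        out, _ = collapse_longitudinal(df, "RID", "EXAMDATE")
        assert out.loc["p", "A"] == 2.0

    def test_missing_id_column_raises(self):
        with pytest.raises(KeyError):
            collapse_longitudinal(pd.DataFrame({"A": [1]}), "RID")


class TestMergeTables:
    def test_disjoint_columns_union(self):
        t1 = pd.DataFrame({"RID": ["a", "b"], "X": [1.0, 2.0]})
        t2 = pd.DataFrame({"RID": ["a", "b"], "Y": [3.0, 4.0]})
        merged, skipped = merge_tables([t1, t2])
        assert sorted(merged.columns) == ["X", "Y"]
        assert skipped == []

    def test_headers_uppercased(self):
        t = pd.DataFrame({"rid": ["a"], "icv": [1.0]})
        merged, _ = merge_tables([t])
        assert "ICV" in merged.columns

    def test_table_without_patient_id_skipped_with_warning(self):
        good = pd.DataFrame({"RID": ["a"], "X": [1.0]})
        bad = pd.DataFrame({"FLDNAME": ["x"], "TEXT": ["dictionary row"]})
        with pytest.warns(UserWarning, match="no patient-ID column"):
            merged, skipped = merge_tables([good, bad])
        assert list(merged.columns) == ["X"]
        assert len(skipped) == 1

    def test_no_mergeable_tables_raises(self):
        bad = pd.DataFrame({"A": [1]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                merge_tables([bad])

    def test_collision_resolved_by_recency(self):
        older = pd.DataFrame({"RID": ["a"], "EXAMDATE": [10], "X": [1.0]})
        newer = pd.DataFrame({"RID": ["a"], "EXAMDATE": [99], "X": [2.0]})
        merged, _ = merge_tables([older, newer])
        assert merged.loc["a", "X"] == 2.0
        merged_rev, _ = merge_tables([newer, older])
        assert merged_rev.loc["a", "X"] == 2.0

    def test_undated_collision_first_table_wins(self):
        t1 = pd.DataFrame({"RID": ["a"], "X": [1.0]})
        t2 = pd.DataFrame({"RID": ["a"], "X": [2.0]})
        merged, _ = merge_tables([t1, t2])
        assert merged.loc["a", "X"] == 1.0

    def test_known_value_beats_missing_regardless_of_date(self):
        t1 = pd.DataFrame({"RID": ["a"], "EXAMDATE": [99], "X": [np.nan]})
        t2 = pd.DataFrame({"RID": ["a"], "EXAMDATE": [1], "X": [7.0]})
        merged, _ = merge_tables([t1, t2])
        assert merged.loc["a", "X"] == 7.0

    def test_patient_union_across_tables(self):
        t1 = pd.DataFrame({"RID": ["a"], "X": [1.0]})
        t2 = pd.DataFrame({"RID": ["b"], "Y": [2.0]})
        merged, _ = merge_tables([t1, t2])
        assert sorted(merged.index) == ["a", "b"]
        assert np.isnan(merged.loc["b", "X"])

    @given(st.permutations([0, 1, 2]))
    def test_merge_order_insensitive_for_disjoint_columns(self, order):
        tables = [
            pd.DataFrame({"RID": ["a", "b"], f"C{i}": [float(i), float(i + 1)]})
            for i in range(3)
        ]
        base, _ = merge_tables(tables)
        permuted, _ = merge_tables([tables[i] for i in order])
        pd.testing.assert_frame_equal(
            base.sort_index(axis=1), permuted.sort_index(axis=1)
        )


def _typed_table(data: dict, kinds: dict, n: int) -> DomainTable:
    ids = [f"P{i:03d}" for i in range(n)]
    return DomainTable(
        data=pd.DataFrame(data, index=ids), kinds=kinds, domain="clinical"
    )


class TestFilterFeatures:
    def test_drop_reasons_and_order(self):
        n = 100
        rng = np.random.default_rng(0)
        const = np.full(n, 7.0)
        low_known = rng.standard_normal(n)
        low_known[: n - 79] = np.nan  # 79% known
        at_threshold = rng.standard_normal(n).astype(object)
        at_threshold[: n - 80] = np.nan  # exactly 80% known
        small_cat = np.array(["A"] * 81 + ["B"] * 19, dtype=object)
        ok_cat = np.array(["A"] * 75 + ["B"] * 25, dtype=object)
        table = _typed_table(
            {
                "CONST": const,
                "LOWKNOWN": low_known,
                "ATTHRESH": at_threshold,
                "SMALLCAT": small_cat,
                "OKCAT": ok_cat,
            },
            {
                "CONST": NUMERIC,
                "LOWKNOWN": NUMERIC,
                "ATTHRESH": NUMERIC,
                "SMALLCAT": NOMINAL,
                "OKCAT": NOMINAL,
            },
            n,
        )
        out, log = filter_features(table)
        reasons = dict(zip(log["feature"], log["reason"]))
        assert reasons == {
            "CONST": "constant",
            "LOWKNOWN": "low_known_fraction",
            "SMALLCAT": "small_category",
        }
        assert sorted(out.data.columns) == ["ATTHRESH", "OKCAT"]

    def test_count_conservation_one_reason_each(self):
        n = 50
        rng = np.random.default_rng(1)
        table = _typed_table(
            {
                "A": rng.standard_normal(n),
                "B": np.full(n, 1.0),
                "C": np.array(["x"] * 40 + ["y"] * 10, dtype=object),
            },
            {"A": NUMERIC, "B": NUMERIC, "C": NOMINAL},
            n,
        )
        out, log = filter_features(table)
        assert table.n_features == out.n_features + len(log)
        assert log["feature"].is_unique

    def test_idempotent(self):
        n = 60
        rng = np.random.default_rng(2)
        table = _typed_table(
            {
                "A": rng.standard_normal(n),
                "B": np.array(["x"] * 30 + ["y"] * 30, dtype=object),
            },
            {"A": NUMERIC, "B": NOMINAL},
            n,
        )
        once, log1 = filter_features(table)
        twice, log2 = filter_features(once)
        pd.testing.assert_frame_equal(once.data, twice.data)
        assert log2.empty


class TestImpute:
    def test_no_unknowns_identity(self):
        n = 30
        rng = np.random.default_rng(3)
        table = _typed_table(
            {"A": rng.standard_normal(n), "B": rng.standard_normal(n)},
            {"A": NUMERIC, "B": NUMERIC},
            n,
        )
        out = impute(table, seed=0)
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_nominal_modal_fill(self):
        vals = np.array(["A"] * 30 + ["B"] * 10 + [np.nan] * 5, dtype=object)
        table = _typed_table({"C": vals}, {"C": NOMINAL}, 45)
        out = impute(table, seed=0)
        assert (out.data["C"].iloc[-5:] == "A").all()

    def test_nominal_tie_broken_lexicographically(self):
        vals = np.array(["B"] * 10 + ["A"] * 10 + [np.nan] * 3, dtype=object)
        table = _typed_table({"C": vals}, {"C": NOMINAL}, 23)
        out = impute(table, seed=0)
        assert (out.data["C"].iloc[-3:] == "A").all()

    def test_numeric_imputation_deterministic_and_preserves_known(self):
        n = 80
        rng = np.random.default_rng(4)
        a = rng.standard_normal(n)
        b = a * 2.0 + rng.standard_normal(n) * 0.1
        b_missing = b.copy()
        b_missing[::7] = np.nan
        table = _typed_table(
            {"A": a, "B": b_missing}, {"A": NUMERIC, "B": NUMERIC}, n
        )
        out1 = impute(table, seed=9)
        out2 = impute(table, seed=9)
        pd.testing.assert_frame_equal(out1.data, out2.data)
        known = ~np.isnan(b_missing)
        np.testing.assert_array_equal(out1.data["B"].to_numpy()[known], b[known])
        assert not out1.data["B"].isna().any()
        # the regression imputer should exploit A to land near the true B
        assert np.abs(out1.data["B"].to_numpy()[~known] - b[~known]).max() < 1.0


class TestShapeExpression:
    def test_transpose_shape_and_stripping(self):
        raw, _ = generate_expression_domain(10, 5, 0, seed=0)
        table = shape_expression(raw)
        assert table.data.shape == (5, 10)  # patients x probes
        assert all(k == NUMERIC for k in table.kinds.values())
        assert "SAMPLE_BARCODE" not in table.data.columns
        assert "" not in table.data.columns

    def test_values_unchanged_by_shaping(self):
        raw, _ = generate_expression_domain(6, 4, 0, seed=1)
        table = shape_expression(raw)
        # direct index lookup in the raw matrix
        assert table.data.loc["P0002", "PROBE00003_at"] == raw.loc[
            "PROBE00003_at", "P0002"
        ]

    def test_missing_patient_header_raises(self):
        raw = pd.DataFrame(np.ones((3, 2)), index=["a", "b", "c"], columns=["", "p1"])
        with pytest.raises(ValueError, match="patient-ID header"):
            shape_expression(raw)


class TestAssemble:
    def _table(self, ids, cols, domain):
        data = pd.DataFrame(
            {c: np.arange(len(ids), dtype=float) for c in cols}, index=ids
        )
        return DomainTable(data, {c: NUMERIC for c in cols}, domain)

    def test_patient_intersection(self):
        ds = assemble(
            self._table(["A", "B", "C"], ["X1"], "clinical"),
            self._table(["B", "C"], ["X2"], "expression"),
            self._table(["C"], ["X3"], "image"),
        )
        assert list(ds.data.index) == ["C"]
        assert ds.counts == {"clinical": 1, "expression": 1, "image": 1}
        assert ds.total_features == 3

    def test_counts_additive(self):
        ds = assemble(
            self._table(["A"], ["C1", "C2"], "clinical"),
            self._table(["A"], ["E1", "E2", "E3"], "expression"),
            self._table(["A"], ["I1"], "image"),
        )
        assert ds.total_features == 2 + 3 + 1 == ds.data.shape[1]

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="no patients"):
            assemble(
                self._table(["A"], ["X"], "clinical"),
                self._table(["B"], ["Y"], "expression"),
                self._table(["A"], ["Z"], "image"),
            )

    def test_combined_feature_count(self):
        assert combined_feature_count(2, 0, 3) == 5
        with pytest.raises(ValueError):
            combined_feature_count(-1, 2)


def test_infer_kinds_partitions_columns():
    df = pd.DataFrame(
        {
            "NUM": np.arange(30, dtype=float),
            "NOM": ["a", "b", "c"] * 10,
            "ID": [f"id{i}" for i in range(30)],
        }
    )
    kinds, dropped = infer_kinds(df)
    assert kinds == {"NUM": NUMERIC, "NOM": NOMINAL}
    assert dropped == ["ID"]
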