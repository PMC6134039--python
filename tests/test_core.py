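"""Domain types, table I/O, normalization and branch numbering."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metaboflow.core import (
    AbundanceTable,
    MetaboliteId,
    MissingStandardError,
    NegativeAreaError,
    SampleKey,
    UnknownLabelError,
    assign_branch_numbers,
    canonical_name,
    read_abundance_table,
    write_table,
)

from conftest import make_table


class TestMetaboliteId:
    def test_display_with_and_without_branch(self):
        assert MetaboliteId("citrulline").display() == "citrulline"
        assert MetaboliteId("glucuronic acid", 1).display() == "glucuronic acid-1"

    def test_rejects_empty_name_and_bad_branch(self):
        with pytest.raises(ValueError):
            MetaboliteId("  ")
        with pytest.raises(ValueError):
            MetaboliteId("x", 0)

    def test_canonical_identity_ignores_case_and_whitespace(self):
        assert canonical_name(" Glucuronic  Acid ") == "glucuronic acid"


class TestBranchNumbers:
    @pytest.mark.parametrize(
        "names,expected",
        [
            (["citrulline"], ["citrulline"]),
            (
                ["glucuronic acid", "glucuronic acid"],
                ["glucuronic acid-1", "glucuronic acid-2"],
            ),
            (["a", "b", "a", "a"], ["a-1", "b", "a-2", "a-3"]),
        ],
    )
    def test_examples(self, names, expected):
        ids = assign_branch_numbers([(n, i) for i, n in enumerate(names)])
        assert [m.display() for m in ids] == expected

    def test_duplicate_peaks_rejected(self):
        with pytest.raises(ValueError):
            assign_branch_numbers([("a", 1), ("b", 1)])

    @given(st.lists(st.sampled_from("abcd"), min_size=1, max_size=12),
           st.randoms(use_true_random=False))
    @settings(max_examples=50, deadline=None)
    def test_branch_assignment_stable_under_singleton_permutation(self, names, rnd):
        """Moving non-duplicate rows around never changes the branch
        numbers of duplicated names relative to their own order."""
        pairs = [(n, i) for i, n in enumerate(names)]
        base = {p: m.display() for (n, p), m in
                zip(pairs, assign_branch_numbers(pairs))}
        dup_names = {n for n in names if names.count(n) >= 2}
        singletons = [p for p in pairs if p[0] not in dup_names]
        dups = [p for p in pairs if p[0] in dup_names]
        rnd.shuffle(singletons)
        merged = dups + singletons
        new = {p: m.display() for p, m in
               zip((pk for _, pk in merged), assign_branch_numbers(merged))}
        for _, peak in dups:
            assert new[peak] == base[peak]


class TestSampleKey:
    def test_round_trip_and_validation(self):
        key = SampleKey("intestine", "probiotic", 2)
        assert SampleKey.parse(key.column()) == key
        with pytest.raises(UnknownLabelError):
            SampleKey("intestine", "treated", 1)
        with pytest.raises(UnknownLabelError):
            SampleKey.parse("intestine_probiotic")


class TestNormalization:
    def test_division_by_sample_standard(self):
        table = make_table([[10, 10, 10, 8, 8, 8]],
                           standards=[2, 2, 2, 4, 4, 4])
        norm = table.normalize()
        np.testing.assert_allclose(norm.data.to_numpy()[0], [5, 5, 5, 2, 2, 2])
        assert (norm.internal_standard == 1).all()

    def test_unit_standards_are_identity_and_idempotent(self):
        table = make_table(np.arange(12.0).reshape(2, 6) + 1)
        norm = table.normalize()
        assert norm.equals(table)
        assert norm.normalize().equals(norm)

    def test_two_sample_hand_computation(self):
        table = make_table([[8.0, 8.0]], standards=[2.0, 4.0], replicates=1)
        np.testing.assert_allclose(
            table.normalize().data.to_numpy()[0], [4.0, 2.0]
        )

    def test_nd_preserved(self):
        table = make_table([[np.nan, 3, 4, 5, 6, 7]], standards=[2] * 6)
        norm = table.normalize()
        assert math.isnan(norm.data.iloc[0, 0])
        assert norm.data.iloc[0, 1] == 1.5

    @given(st.floats(min_value=0.1, max_value=100), st.integers(0, 5))
    @settings(max_examples=30, deadline=None)
    def test_scale_equivariance(self, c, col):
        """Multiplying all areas and the standard of one sample by c > 0
        leaves the normalized table unchanged."""
        rng = np.random.default_rng(7)
        values = rng.lognormal(1, 0.5, size=(3, 6))
        standards = rng.lognormal(0, 0.2, size=6)
        base = make_table(values, standards=standards)
        scaled_v, scaled_s = values.copy(), standards.copy()
        scaled_v[:, col] *= c
        scaled_s[col] *= c
        scaled = make_table(scaled_v, standards=scaled_s)
        assert scaled.normalize().equals(base.normalize(), rtol=1e-12)

    def test_nonpositive_standard_rejected(self):
        with pytest.raises(MissingStandardError):
            make_table([[1.0, 2.0]], standards=[1.0, 0.0], replicates=1)

    def test_negative_area_rejected(self):
        with pytest.raises(NegativeAreaError):
            make_table([[1.0, -2.0]], replicates=1)


class TestTableIO:
    def test_round_trip_with_nd_cells(self, tmp_path):
        table = make_table([[1.88, np.nan, 3.5, 1 / 3, 2e-7, 41.0]])
        path = tmp_path / "t.tsv"
        write_table(table, path)
        text = path.read_text()
        assert "ND" in text  # literal token, not zero
        back = read_abundance_table(path, "cation", "intestine")
        assert back.equals(table)

    def test_missing_standard_row_errors(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("metabolite\tintestine_control_1\nmet_01\t1.0\n")
        with pytest.raises(MissingStandardError, match="internal standard not found"):
            read_abundance_table(path, "cation", "intestine")

    def test_unknown_group_label_names_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("metabolite\tintestine_treated_1\nmet_01\t1.0\n")
        with pytest.raises(UnknownLabelError, match="intestine_treated_1"):
            read_abundance_table(path, "cation", "intestine")

    def test_negative_area_names_row_and_column(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text(
            "metabolite\tintestine_control_1\n"
            "methionine sulfone\t10\n"
            "met_01\t-1.0\n"
        )
        with pytest.raises(NegativeAreaError, match="met_01"):
            read_abundance_table(path, "cation", "intestine")

    def test_empty_table_round_trip(self, tmp_path):
        table = make_table(np.empty((0, 2)), metabolites=[], replicates=1)
        path = tmp_path / "empty.tsv"
        write_table(table, path)
        back = read_abundance_table(path, "cation", "intestine")
        assert back.data.empty and list(back.data.columns) == list(table.data.columns)

    def test_comma_fallback_dialect(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text(
            "metabolite,intestine_control_1,intestine_probiotic_1\n"
            "methionine sulfone,2,4\n"
            "met_01,8,8\n"
        )
        table = read_abundance_table(path, "cation", "intestine")
        np.testing.assert_allclose(
            table.normalize().data.to_numpy()[0], [4.0, 2.0]
        )

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_random_tables(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 8))
        values = rng.lognormal(2, 1.5, size=(n, 6))
        values[rng.random(values.shape) < 0.2] = np.nan
        table = make_table(values, standards=rng.lognormal(5, 0.3, size=6))
        path = tmp_path_factory.mktemp("rt") / "t.tsv"
        write_table(table, path)
        assert read_abundance_table(path, "cation", "intestine").equals(table)
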