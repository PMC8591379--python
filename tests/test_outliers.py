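"""MAD outlier calling, categories, contingency tables and group comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import allomvox as av
from allomvox.outliers import (
    TABLE_RESPONSE_ORDER,
    build_contingency,
    build_outlier_table,
    direction_marks,
    mad_outliers,
    residual_group_comparison,
    size_corrected_raw_comparison,
    tally_outlier_table,
)


class TestMAD:
    def test_single_gross_outlier(self):
        # median 3, MAD 1 -> cutoff 2.5 * 1.4826 = 3.7065; only 100 exceeds
        flags = mad_outliers([1, 2, 3, 4, 100])
        assert flags.tolist() == [False, False, False, False, True]

    def test_constant_vector_has_no_outliers(self):
        with pytest.warns(UserWarning, match="MAD of residuals is zero"):
            flags = mad_outliers([2.0] * 10)
        assert not flags.any()

    def test_degenerate_mad_flags_values_off_median(self):
        with pytest.warns(UserWarning):
            flags = mad_outliers([5.0, 5.0, 5.0, 5.0, 7.0])
        assert flags.tolist() == [False, False, False, False, True]

    @given(st.floats(0.001, 1000.0), st.floats(-50.0, 50.0))
    def test_invariant_to_scale_and_shift(self, c, shift):
        r = np.array([0.1, -0.3, 0.2, 0.05, -0.1, 4.0, -0.02])
        base = mad_outliers(r)
        assert mad_outliers(c * r).tolist() == base.tolist()
        assert mad_outliers(r + shift).tolist() == base.tolist()

    def test_uncorrected_variant_one_flag_away(self):
        r = [0.0, 0.1, -0.1, 0.2, -0.2, 0.45]
        strict = mad_outliers(r, scale_b=1.0)
        lax = mad_outliers(r, scale_b=1.4826)
        assert strict.sum() >= lax.sum()

    def test_too_few_residuals_raise(self):
        with pytest.raises(ValueError):
            mad_outliers([1.0, 2.0])


class TestDirection:
    def test_sign_rules(self):
        marks = direction_marks([0.9, -0.4, 5.0], [True, True, False])
        assert marks == ["U", "D", ""]


class TestContingency:
    def test_paper_shaped_counts(self):
        vpl = np.array([True] * 58 + [False] * 106)
        flags = np.array([True] * 23 + [False] * 35 + [True] * 10 + [False] * 96)
        table = build_contingency(flags, vpl)
        np.testing.assert_array_equal(table.counts, [[23, 35], [10, 96]])

    def test_empty_margins(self):
        vpl = np.array([True, True, False, False, False])
        none = build_contingency(np.zeros(5, bool), vpl)
        np.testing.assert_array_equal(none.counts, [[0, 2], [0, 3]])
        every = build_contingency(np.ones(5, bool), vpl)
        np.testing.assert_array_equal(every.counts, [[2, 0], [3, 0]])

    @given(st.lists(st.tuples(st.booleans(), st.booleans()),
                    min_size=1, max_size=60))
    def test_margins_reconstruct_group_sizes(self, pairs):
        flags = [f for f, _ in pairs]
        vpl = [v for _, v in pairs]
        t = build_contingency(flags, vpl)
        assert t.n_vpl == sum(vpl)
        assert t.n_nonvpl == len(vpl) - sum(vpl)
        assert t.total == len(pairs)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            build_contingency([], [])


class TestCategories:
    @pytest.mark.parametrize("marks,is_vpl,expected", [
        (["U", "U", "U", ""], True, 1),   # bottlenose-dolphin pattern
        (["", "", "U", "D"], True, 5),    # Baiji-dolphin pattern
        (["D", "D", "D", "D"], False, 2), # European-badger pattern
        (["U", "U", "U", "U"], False, 4), # house-mouse pattern
        (["D", "D", "", "D"], True, 3),   # pygmy-right-whale pattern
        (["U", "", "", "D"], False, 6),   # undefined mixed non-VPL -> sentinel
    ])
    def test_assignment_rules(self, marks, is_vpl, expected):
        assert av.assign_category(marks, is_vpl) == expected

    def test_no_marks_raise(self):
        with pytest.raises(ValueError, match="no direction marks"):
            av.assign_category(["", "", "", ""], True)

    @given(st.lists(st.sampled_from(["U", "D", ""]), min_size=4, max_size=4),
           st.booleans())
    def test_every_outlier_gets_exactly_one_category(self, marks, is_vpl):
        if not any(marks):
            return
        cat = av.assign_category(marks, is_vpl)
        assert cat in {1, 2, 3, 4, 5, 6}
        vpl_cats, nonvpl_cats = {1, 3, 5}, {2, 4, 6}
        assert cat in (vpl_cats if is_vpl else nonvpl_cats)


class TestOutlierTable:
    def test_singleton_table(self):
        table = build_outlier_table(
            {"MinDF": {"spA": "U"}}, {"spA": True})
        summary = tally_outlier_table(table)
        assert summary.total_marks == 1
        assert summary.n_upward == 1 and summary.n_downward == 0
        assert summary.category_counts == {1: 1}

    def test_empty_table_tallies_to_zero(self):
        empty = pd.DataFrame(columns=["species", "common_name",
                                      *TABLE_RESPONSE_ORDER, "is_vpl", "category"])
        s = tally_outlier_table(empty)
        assert s.total_marks == 0 and s.n_species == 0

    def test_tallies_agree_with_independent_column_join(self):
        """Row-scan tallies equal a column-join recomputation on the
        packaged reference tables."""
        for table in av.fixture_outlier_tables():
            s = tally_outlier_table(table)
            # (d) via an explicit merge of the two mark columns
            co = len(set(table.loc[table["MaxDF"] == "U", "species"])
                     & set(table.loc[table["RangeDF"] == "U", "species"]))
            assert co == s.maxdf_rangedf_up_cooccurrence
            # (e) via per-column species sets
            primary = (set(table.loc[table["MinDF"] != "", "species"])
                       | set(table.loc[table["MaxDF"] != "", "species"]))
            overlap = sum(
                table.loc[table[col] != "", "species"].isin(primary).sum()
                for col in ("MeanDF", "RangeDF"))
            assert overlap == s.meanrange_overlap_marks

    def test_fixture_categories_recompute_exactly(self):
        """assign_category reproduces the printed category column for all
        58 reference species."""
        for table in av.fixture_outlier_tables():
            for _, row in table.iterrows():
                marks = [row[r] for r in TABLE_RESPONSE_ORDER]
                assert av.assign_category(marks, row["is_vpl"]) == row["category"], \
                    row["species"]


class TestGroupComparisons:
    def test_identical_distributions_are_null(self):
        vals = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        vpl = np.array([True, True, True, False, False, False])
        res = residual_group_comparison(vals, vpl)
        assert res.test.p == 1.0

    def test_complete_separation_exact_p(self):
        # all VPL above all non-VPL, 5 vs 5: two-tailed p = 2/252
        vals = np.array([6, 7, 8, 9, 10, 1, 2, 3, 4, 5], dtype=float)
        vpl = np.array([True] * 5 + [False] * 5)
        res = residual_group_comparison(vals, vpl)
        assert res.test.w == 25
        assert res.test.p == pytest.approx(2 / 252)

    def test_absolute_equals_signed_for_nonnegative_values(self, rng):
        vals = rng.uniform(0, 1, 20)
        vpl = np.arange(20) < 8
        signed = residual_group_comparison(vals, vpl, form="signed")
        absolute = residual_group_comparison(vals, vpl, form="absolute")
        assert signed.test.w == absolute.test.w
        assert signed.test.p == absolute.test.p

    def test_outliers_only_scope_restricts(self):
        vals = np.array([5.0, -4.0, 0.1, -0.2, 0.3, -0.1])
        vpl = np.array([True, False, True, True, False, False])
        flags = np.array([True, True, False, False, False, False])
        res = residual_group_comparison(vals, vpl, scope="outliers_only",
                                        form="signed", outlier_flags=flags)
        assert res.n_vpl == 1 and res.n_nonvpl == 1

    def test_empty_group_after_scoping_raises(self):
        vals = np.array([5.0, 0.1, 0.2, -0.2])
        vpl = np.array([True, True, False, False])
        flags = np.array([True, False, False, False])
        with pytest.raises(ValueError, match="empty"):
            residual_group_comparison(vals, vpl, scope="outliers_only",
                                      outlier_flags=flags)


class TestSizeCorrected:
    def _table(self, freqs_vpl, freqs_non, mass=100.0):
        n1, n2 = len(freqs_vpl), len(freqs_non)
        return pd.DataFrame({
            "species": [f"s{i}" for i in range(n1 + n2)],
            "body_mass_g": mass,
            "min_df_hz": list(freqs_vpl) + list(freqs_non),
            "is_vpl": [True] * n1 + [False] * n2,
        })

    def test_hz_per_gram_units(self):
        t = self._table([200.0], [300.0], mass=100.0)
        res = size_corrected_raw_comparison(t, "MinDF")
        assert res.mean_vpl == pytest.approx(2.0)
        assert res.mean_nonvpl == pytest.approx(3.0)

    def test_identical_groups_are_null(self):
        t = self._table([10.0, 20.0, 30.0], [10.0, 20.0, 30.0])
        res = size_corrected_raw_comparison(t, "MinDF")
        assert res.test.p == 1.0

    def test_doubled_frequencies_double_the_group_mean(self):
        base = [11.0, 22.0, 35.0, 47.0]
        t = self._table([2 * f for f in base], base)
        res = size_corrected_raw_comparison(t, "MinDF")
        assert res.mean_vpl == pytest.approx(2 * res.mean_nonvpl)
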