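"""Tabulation, chi-square and compact-letter grouping."""

import dataclasses
import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synfix import (
    TableError,
    cell_table,
    generate_cohort,
    ingest_table1_fixture,
    letter_groups,
    make_screw_grid,
    marginals,
    pearson_chi_square,
    run_cohort,
    stats_report,
)

# One-way marginals of the published 90-cell table, for cross-checking the
# aggregation path (counts over n=900 per level, n=3000 per rule/diameter).
PUBLISHED_LEVEL_COUNTS = {  # descending level, as printed
    5.0: 587, 4.5: 581, 4.0: 580, 3.5: 587, 3.0: 541,
    2.5: 376, 2.0: 207, 1.5: 42, 1.0: 0, 0.5: 0,
}
PUBLISHED_ANGLE_COUNTS = {"fixed_20": 969, "fixed_30": 1123, "individual": 1409}
PUBLISHED_DIAMETER_COUNTS = {3.5: 1091, 4.0: 1174, 4.5: 1236}


class TestCellTable:
    def test_simple_counting(self):
        frame = pd.DataFrame(
            {
                "ankle_id": ["a", "b"],
                "level_cm": [1.0, 1.0],
                "angle_rule": ["fixed_20"] * 2,
                "resolved_angle_deg": [20.0] * 2,
                "diameter_mm": [3.5] * 2,
                "distance_mm": [1.0, 3.0],
                "injury_flag": [True, False],
            }
        )
        cells = cell_table(frame)
        assert len(cells) == 1
        assert cells.loc[0, "n_total"] == 2
        assert cells.loc[0, "n_flagged"] == 1
        assert cells.loc[0, "pct"] == 50.0

    def test_all_flagged_gives_100(self, small_cohort):
        grid = make_screw_grid([5.0], ["individual"], [4.5])
        records = run_cohort(small_cohort, grid)
        frame = pd.DataFrame([dataclasses.asdict(r) for r in records])
        frame["injury_flag"] = True
        frame["distance_mm"] = 0.0
        cells = cell_table(frame)
        assert (cells["pct"] == 100.0).all()

    def test_empty_records_rejected(self):
        with pytest.raises(TableError):
            cell_table(pd.DataFrame())

    def test_reruns_with_same_seed_give_identical_tables(self, small_config, default_grid):
        a = cell_table(run_cohort(generate_cohort(small_config), default_grid))
        b = cell_table(run_cohort(generate_cohort(small_config), default_grid))
        pd.testing.assert_frame_equal(a, b)


class TestMarginals:
    def test_angle_marginals_match_published(self, table1_cells):
        marg = marginals(table1_cells, "angle_rule").set_index("category")
        for rule, count in PUBLISHED_ANGLE_COUNTS.items():
            assert marg.loc[rule, "n_flagged"] == count
            assert marg.loc[rule, "n_total"] == 3000

    def test_diameter_marginals_match_published(self, table1_cells):
        marg = marginals(table1_cells, "diameter").set_index("category")
        for d, count in PUBLISHED_DIAMETER_COUNTS.items():
            assert marg.loc[d, "n_flagged"] == count

    def test_level_marginals_match_published(self, table1_cells):
        marg = marginals(table1_cells, "level").set_index("category")
        for level, count in PUBLISHED_LEVEL_COUNTS.items():
            assert marg.loc[level, "n_flagged"] == count
            assert marg.loc[level, "n_total"] == 900

    def test_conservation_across_axes(self, table1_cells):
        totals = {
            axis: (
                marginals(table1_cells, axis)["n_flagged"].sum(),
                marginals(table1_cells, axis)["n_total"].sum(),
            )
            for axis in ("level", "angle_rule", "diameter")
        }
        assert set(totals.values()) == {(3501, 9000)}

    def test_diameter_marginals_non_decreasing(self, table1_cells):
        marg = marginals(table1_cells, "diameter").sort_values("category")
        flagged = list(marg["n_flagged"])
        assert flagged == sorted(flagged)

    def test_unknown_axis_rejected(self, table1_cells):
        with pytest.raises(TableError):
            marginals(table1_cells, "screwiness")


class TestPearsonChiSquare:
    def test_identical_proportions_give_zero(self):
        res = pearson_chi_square([(10, 100), (10, 100)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.df == 1

    def test_published_angle_counts_highly_significant(self):
        res = pearson_chi_square([(969, 3000), (1123, 3000), (1409, 3000)])
        assert res.df == 2
        assert res.p_value < 0.001

    def test_all_zero_flagged_is_degenerate_zero(self):
        res = pearson_chi_square([(0, 900), (0, 900)])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_zero_total_rejected(self):
        with pytest.raises(TableError):
            pearson_chi_square([(0, 0), (5, 10)])

    def test_single_category_rejected(self):
        with pytest.raises(TableError):
            pearson_chi_square([(5, 10)])

    def test_small_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="expected"):
            pearson_chi_square([(1, 10), (3, 10)])

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.tuples(st.integers(0, 50), st.integers(1, 60)).map(
                lambda ft: (min(ft), max(ft))
            ),
            min_size=2,
            max_size=5,
        )
    )
    def test_matches_textbook_formula(self, pairs):
        """Statistic equals sum over cells of (O-E)^2/E computed by hand."""
        observed = np.array([[f, t - f] for f, t in pairs], dtype=float)
        col = observed.sum(axis=0)
        if (col == 0).any():
            return  # degenerate tables covered elsewhere
        expected = np.outer(observed.sum(axis=1), col) / observed.sum()
        by_hand = float(((observed - expected) ** 2 / expected).sum())
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = pearson_chi_square(pairs)
        assert abs(res.statistic - by_hand) < 1e-9


class TestLetterGroups:
    def test_identical_categories_single_letter(self):
        groups = letter_groups([(20, 100)] * 4)
        assert set(groups.letters.values()) == {"a"}

    def test_extreme_difference_disjoint_letters(self):
        groups = letter_groups([(10, 100), (90, 100)])
        a, b = groups.letters[0], groups.letters[1]
        assert not set(a) & set(b)

    def test_published_level_pattern(self):
        """Level marginals, in printed (descending) order, reproduce the
        published grouping a,a,a,a,a,b,c,d,e,e."""
        levels = [5.0, 4.5, 4.0, 3.5, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5]
        counts = [(PUBLISHED_LEVEL_COUNTS[lv], 900) for lv in levels]
        groups = letter_groups(counts, alpha=0.05, categories=levels)
        assert [groups.letters[lv] for lv in levels] == [
            "a", "a", "a", "a", "a", "b", "c", "d", "e", "e"
        ]

    def test_published_angle_pattern(self):
        counts = [(c, 3000) for c in PUBLISHED_ANGLE_COUNTS.values()]
        groups = letter_groups(counts, categories=list(PUBLISHED_ANGLE_COUNTS))
        assert [groups.letters[r] for r in PUBLISHED_ANGLE_COUNTS] == ["a", "b", "c"]

    def test_published_diameter_pattern(self):
        counts = [(c, 3000) for c in PUBLISHED_DIAMETER_COUNTS.values()]
        groups = letter_groups(counts, categories=list(PUBLISHED_DIAMETER_COUNTS))
        assert [groups.letters[d] for d in PUBLISHED_DIAMETER_COUNTS] == ["a", "ab", "b"]

    def test_shared_letter_iff_nonsignificant(self):
        """The defining CLD property on a mixed table."""
        pairs = [(0, 900), (0, 900), (42, 900), (207, 900), (210, 900)]
        groups = letter_groups(pairs)
        n = len(pairs)
        n_pairs = n * (n - 1) // 2
        import warnings

        for i in range(n):
            for j in range(i + 1, n):
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = min(1.0, pearson_chi_square([pairs[i], pairs[j]]).p_value * n_pairs)
                shared = bool(set(groups.letters[i]) & set(groups.letters[j]))
                assert shared == (p >= 0.05)

    def test_relabeling_invariance(self):
        pairs = [(587, 900), (376, 900), (207, 900), (42, 900)]
        base = letter_groups(pairs)
        perm = [2, 0, 3, 1]
        permuted = letter_groups([pairs[i] for i in perm])
        # same partition structure: categories i,j share a letter in the base
        # grouping iff their images share one after permutation
        def shares(g, i, j):
            return bool(set(g.letters[i]) & set(g.letters[j]))

        inv = {orig: pos for pos, orig in enumerate(perm)}
        for i in range(4):
            for j in range(i + 1, 4):
                assert shares(base, i, j) == shares(permuted, inv[i], inv[j])


class TestTable1Fixture:
    def test_total_flagged_is_3501(self, table1_cells):
        assert table1_cells["n_flagged"].sum() == 3501
        assert table1_cells["n_total"].sum() == 9000

    def test_specific_cells(self, table1_cells):
        idx = table1_cells.set_index(["level_cm", "angle_rule", "diameter_mm"])
        assert idx.loc[(5.0, "fixed_20", 3.5), "n_flagged"] == 43
        assert idx.loc[(2.5, "individual", 4.5), "n_flagged"] == 45
        assert idx.loc[(1.0, "fixed_30", 4.0), "n_flagged"] == 0

    def test_every_cell_has_n_100(self, table1_cells):
        assert (table1_cells["n_total"] == 100).all()
        assert len(table1_cells) == 90

    def _fixture_frame(self, table1_cells):
        return table1_cells[["level_cm", "angle_rule", "diameter_mm", "pct"]].copy()

    def test_non_integer_pct_rejected(self, table1_cells):
        bad = self._fixture_frame(table1_cells)
        bad.loc[0, "pct"] = 43.5
        with pytest.raises(TableError, match="integer"):
            ingest_table1_fixture(bad)

    def test_out_of_range_pct_rejected(self, table1_cells):
        bad = self._fixture_frame(table1_cells)
        bad.loc[0, "pct"] = 101.0
        with pytest.raises(TableError):
            ingest_table1_fixture(bad)

    def test_missing_cells_rejected(self, table1_cells):
        with pytest.raises(TableError, match="90"):
            ingest_table1_fixture(self._fixture_frame(table1_cells).iloc[:-1])

    def test_csv_ingest_matches_frame_ingest(self, table1_cells):
        buf = io.StringIO()
        self._fixture_frame(table1_cells).to_csv(buf, index=False)
        buf.seek(0)
        pd.testing.assert_frame_equal(ingest_table1_fixture(buf), table1_cells)


class TestStatsReport:
    def test_report_reproduces_published_surface(self, table1_cells):
        report = stats_report(table1_cells)
        assert report["overall"]["n_flagged"] == 3501
        assert report["overall"]["pct"] == pytest.approx(38.9, abs=0.05)
        for axis in ("level", "angle_rule", "diameter"):
            assert report["axes"][axis]["chi_square"]["p_value"] < 0.001
        angle_letters = [
            c["letters"] for c in report["axes"]["angle_rule"]["categories"]
        ]
        assert angle_letters == ["a", "b", "c"]
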