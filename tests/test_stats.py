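import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.integrate import quad

from podnet.catalog import MarkGrade
from podnet.stats import (
    DegenerateTableError,
    chi_square_upper_tail,
    community_feature_counts,
    mark_severity_table,
    pairwise_network_tests,
    pairwise_tests_from_counts,
    pearson_chi_square,
)
from conftest import make_db

# permanent / non-permanent margins of the five-network comparison
NETWORK_COUNTS = pd.DataFrame(
    {"permanent": [72, 33, 8, 30, 9], "other": [120, 9, 3, 1, 1]},
    index=list("ABCDE"),
)


def closed_form_2x2(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


class TestPearsonChiSquare:
    def test_two_network_permanent_comparison(self):
        r = pearson_chi_square(NETWORK_COUNTS.loc[["A", "B"]])
        assert round(r.chi2, 1) == 23.5
        assert r.df == 1

    def test_uniform_table_gives_zero(self):
        r = pearson_chi_square([[10, 10], [10, 10]])
        assert r.chi2 == 0.0 and r.p == 1.0

    def test_omnibus_five_network_statistic(self):
        r = pearson_chi_square(NETWORK_COUNTS)
        assert round(r.chi2, 1) == 60.6
        assert r.df == 4
        assert r.p < 0.001

    def test_expected_margins_match_observed(self):
        r = pearson_chi_square(NETWORK_COUNTS)
        assert r.expected.to_numpy().sum() == pytest.approx(
            r.observed.to_numpy().sum(), abs=1e-9
        )
        assert np.allclose(r.expected.sum(axis=1), r.observed.sum(axis=1))

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            shape = (int(rng.integers(2, 5)), int(rng.integers(2, 5)))
            table = rng.integers(1, 40, size=shape)
            r = pearson_chi_square(table)
            chi2, p, df, _ = sps.chi2_contingency(table, correction=False)
            assert r.chi2 == pytest.approx(chi2)
            assert r.p == pytest.approx(p)
            assert r.df == df

    def test_2x2_closed_form_cross_check(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 60, size=4)
            r = pearson_chi_square([[a, b], [c, d]])
            assert r.chi2 == pytest.approx(closed_form_2x2(a, b, c, d))

    def test_invariant_under_row_and_column_permutation(self):
        rng = np.random.default_rng(9)
        table = rng.integers(1, 30, size=(3, 4))
        base = pearson_chi_square(table).chi2
        for _ in range(5):
            perm = table[rng.permutation(3)][:, rng.permutation(4)]
            assert pearson_chi_square(perm).chi2 == pytest.approx(base)

    @pytest.mark.parametrize(
        "table,err",
        [
            ([[0, 0], [3, 4]], DegenerateTableError),
            ([[1, 0], [3, 0]], DegenerateTableError),
            ([[1.5, 2], [3, 4]], ValueError),
            ([[-1, 2], [3, 4]], ValueError),
            ([[1, 2]], ValueError),
        ],
    )
    def test_invalid_tables_rejected(self, table, err):
        with pytest.raises(err):
            pearson_chi_square(table)


class TestUpperTail:
    def test_zero_statistic_gives_one(self):
        for df in (1, 2, 5):
            assert chi_square_upper_tail(0.0, df) == 1.0

    def test_classical_critical_value(self):
        assert chi_square_upper_tail(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_printed_p_for_5_41_is_a_typo(self):
        # the 1-df upper tail of 5.41 is ~0.020, not 0.201
        assert chi_square_upper_tail(5.41, 1) == pytest.approx(0.020, abs=5e-4)

    def test_matches_numerical_integration_oracle(self):
        for df in (1, 2, 3, 5, 8):
            for x in (0.5, 1.0, 2.0, 3.841, 5.41, 10.0, 25.0):
                oracle, err = quad(lambda t: sps.chi2.pdf(t, df), x, np.inf, limit=200)
                assert abs(chi_square_upper_tail(x, df) - oracle) < 1e-10

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            chi_square_upper_tail(1.0, 0)
        with pytest.raises(ValueError):
            chi_square_upper_tail(-1.0, 1)


class TestPairwiseTests:
    def test_five_network_significance_pattern(self):
        t = pairwise_tests_from_counts(NETWORK_COUNTS, alpha=0.05)
        assert t.n_comparisons == 10
        assert t.corrected_alpha == pytest.approx(0.005)
        significant = {(x.label_a, x.label_b) for x in t.tests if x.significant}
        assert significant == {("A", "B"), ("A", "D"), ("A", "E")}

    def test_explicit_denominator_override(self):
        t = pairwise_tests_from_counts(NETWORK_COUNTS, alpha=0.05, n_comparisons_override=9)
        assert t.corrected_alpha == pytest.approx(0.05 / 9)

    def test_identical_communities_give_zero_statistic(self):
        counts = pd.DataFrame({"yes": [10, 10], "no": [5, 5]}, index=["A", "B"])
        t = pairwise_tests_from_counts(counts)
        assert t.get("A", "B").result.chi2 == 0.0

    def test_degenerate_pair_reported_untestable(self):
        counts = pd.DataFrame({"yes": [0, 0, 5], "no": [4, 3, 5]}, index=["A", "B", "C"])
        t = pairwise_tests_from_counts(counts)
        ab = t.get("A", "B")
        assert ab.result is None and "zero" in ab.untestable
        assert t.n_comparisons == 2  # only testable pairs enter the denominator

    def test_from_partition_counts(self):
        db = make_db(
            [["p1", "p2", "t1"], ["p3", "s1"]],
            grades={"p1": "P", "p2": "P", "p3": "P", "t1": "T", "s1": "S"},
        )
        from podnet.association import association_matrix
        from podnet.community import assign_unmarked, build_sociogram, detect_communities

        m = association_matrix(db, grade_filter={MarkGrade.PERMANENT})
        p = assign_unmarked(db, detect_communities(build_sociogram(m, db)))
        counts = community_feature_counts(db, p, "permanent_mark")
        assert counts.loc["A"].tolist() == [2, 1]
        assert counts.loc["B"].tolist() == [1, 1]
        t = pairwise_network_tests(db, p, feature="permanent_mark")
        assert t.get("A", "B").result is not None

    def test_lower_triangular_layout(self):
        t = pairwise_tests_from_counts(NETWORK_COUNTS)
        tri = t.to_lower_triangular()
        assert list(tri.index) == ["B", "C", "D", "E"]
        assert list(tri.columns) == ["A", "B", "C", "D"]
        assert tri.loc["B", "A"].startswith("chi2 = 23.5")
        assert tri.loc["C", "B"] == "" or "chi2" in tri.loc["C", "B"]


class TestMarkSeverityTable:
    def test_composition_of_constructed_groups(self):
        # group 2 members all sighted exactly once
        db = make_db(
            [["p1", "p2", "t1"], ["p1", "t1"], ["q1", "q2"]],
            grades={"p1": "P", "p2": "P", "q1": "P", "q2": "P", "t1": "T"},
            tip={"q1": True, "q2": True},
        )
        from podnet.association import association_matrix
        from podnet.community import assign_unmarked, build_sociogram, detect_communities

        m = association_matrix(db, grade_filter={MarkGrade.PERMANENT})
        p = assign_unmarked(db, detect_communities(build_sociogram(m, db)))
        table = mark_severity_table(db, p, {"A": {"A"}, "B": {"B"}})
        assert table.loc["B", "pct_sighted_once"] == 100
        assert table.loc["B", "pct_tip_damage"] == 100
        assert table.loc["A", "n"] == 3
        assert table.loc["A", "permanent"] == 2

    def test_single_group_percent_permanent(self):
        grades = {}
        for k in range(152):
            grades[f"p{k}"] = "P"
        for k in range(82):
            grades[f"t{k}"] = "T"
        for k in range(52):
            grades[f"s{k}"] = "S"
        db = make_db([list(grades)], grades=grades)
        from podnet.community import CommunityPartition

        p = CommunityPartition(
            label_of={i: "A" for i in grades},
            provenance={i: "PRIMARY" for i in grades},
        )
        table = mark_severity_table(db, p, {"all": {"A"}})
        assert table.loc["all", "pct_permanent"] == 53

    def test_empty_group_reports_missing_percentages(self):
        db = make_db([["a", "b"]])
        from podnet.community import CommunityPartition

        p = CommunityPartition(
            label_of={"a": "A", "b": "A"}, provenance={"a": "PRIMARY", "b": "PRIMARY"}
        )
        table = mark_severity_table(db, p, {"A": {"A"}, "empty": {"Z"}})
        assert table.loc["empty", "n"] == 0
        assert table.loc["empty", "pct_permanent"] is None or np.isnan(
            table.loc["empty", "pct_permanent"]
        )
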