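"""Assumption tests, test validation, omnibus and post-hoc comparisons.

Exact p-values are cross-checked against a second implementation
(R 4.3.3: shapiro.test, bartlett.test, aov/TukeyHSD, t.test with
var.equal=TRUE, multcomp::glht Dunnett) frozen on fixed fixture vectors.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldplot import (
    TestChoice,
    ValidationError,
    analyze_all,
    assumption_tests,
    detect_groups,
    omnibus_and_posthoc,
    validate_test,
)
from foldplot.tabular_io import GroupedTable

# fixture vectors for the frozen cross-implementation oracle
VEC_X = [2.31, 1.87, 2.02, 2.55, 1.99]
VEC_Y = [3.10, 2.75, 2.98, 3.40]
VEC_Z = [2.20, 2.41, 2.35]
R_SHAPIRO = {"x": 0.49036654435, "y": 0.964674270847, "z": 0.536737125066}
R_BARTLETT = 0.450785528573
R_TUKEY = {  # TukeyHSD p adj
    ("x", "y"): 0.00100785647774,
    ("x", "z"): 0.62254359545786,
    ("y", "z"): 0.00901520814862,
}
R_POOLED_T_XY = 0.00166518595204
R_DUNNETT = {("x", "y"): 0.0007363350, ("x", "z"): 0.5658838359}


def _table(groups: dict[str, list[float]], variable="v") -> GroupedTable:
    rows = [(g, [v]) for g, values in groups.items() for v in values]
    return GroupedTable(list(groups), [variable], rows)


@pytest.fixture(scope="module")
def xyz():
    return _table({"x": VEC_X, "y": VEC_Y, "z": VEC_Z})


class TestDetectAndValidate:
    def test_counts_honor_missing_cells(self, cs1):
        groups = detect_groups(cs1)
        assert list(groups) == ["Control", "40% Dehydrated", "Rehydrated"]
        assert [counts["Cyclin A"] for counts in groups.values()] == [3, 3, 3]
        assert groups["Control"]["Cyclin B1"] == 4

    def test_repeated_blocks_are_one_group(self):
        table = _table({"a": [1, 2], "b": [3, 4]})
        table.rows.append(("a", [5.0]))
        assert list(detect_groups(table)) == ["a", "b"]
        assert detect_groups(table)["a"]["v"] == 3

    @pytest.mark.parametrize(
        "choice,n,ok,suggested",
        [
            (TestChoice.T_TEST, 2, True, None),
            (TestChoice.T_TEST, 3, False, TestChoice.ANOVA_TUKEY),
            (TestChoice.ANOVA_TUKEY, 2, False, TestChoice.T_TEST),
            (TestChoice.ANOVA_TUKEY, 3, True, None),
            (TestChoice.ANOVA_DUNNETT, 2, False, TestChoice.T_TEST),
            (TestChoice.ANOVA_DUNNETT, 4, True, None),
        ],
    )
    def test_test_group_count_rules(self, choice, n, ok, suggested):
        verdict = validate_test(choice, n)
        assert verdict.ok is ok
        assert verdict.suggestion == suggested
        if not ok:
            assert "appropriate" in verdict.message

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError, match="two groups"):
            validate_test(TestChoice.T_TEST, 1)


class TestAssumptions:
    def test_matches_frozen_r_values(self, xyz):
        shapiro, _, bartlett_p = assumption_tests(xyz, "v")
        for group, expected in R_SHAPIRO.items():
            assert shapiro[group].p == pytest.approx(expected, abs=1e-6)
        assert bartlett_p == pytest.approx(R_BARTLETT, abs=1e-6)

    def test_small_group_flagged_not_fatal(self):
        table = _table({"a": [1.0, 2.0], "b": [1.1, 2.2, 3.0]})
        shapiro, _, bartlett_p = assumption_tests(table, "v")
        assert shapiro["a"].p is None
        assert "fewer than 3" in shapiro["a"].reason
        assert shapiro["b"].p is not None
        assert bartlett_p is not None

    def test_zero_variance_group_flagged(self):
        table = _table({"a": [2.0, 2.0, 2.0], "b": [1.0, 2.0, 3.0]})
        shapiro, _, _ = assumption_tests(table, "v")
        assert shapiro["a"].p is None
        assert "variance" in shapiro["a"].reason


class TestOmnibusAndPosthoc:
    def test_tukey_matches_frozen_r_values(self, xyz):
        report = omnibus_and_posthoc(xyz, "v", TestChoice.ANOVA_TUKEY)
        assert report.omnibus_name == "one-way ANOVA"
        observed = {(p.group_a, p.group_b): p.p_value for p in report.posthoc}
        assert set(observed) == set(R_TUKEY)
        for pair, expected in R_TUKEY.items():
            assert observed[pair] == pytest.approx(expected, abs=1e-6)

    def test_pooled_t_matches_frozen_r_value(self):
        table = _table({"x": VEC_X, "y": VEC_Y})
        report = omnibus_and_posthoc(table, "v", TestChoice.T_TEST)
        assert report.omnibus_p == pytest.approx(R_POOLED_T_XY, abs=1e-9)
        (pair,) = report.posthoc
        assert (pair.group_a, pair.group_b) == ("x", "y")
        assert pair.significant

    def test_dunnett_matches_frozen_r_values(self, xyz):
        report = omnibus_and_posthoc(xyz, "v", TestChoice.ANOVA_DUNNETT, rng=1)
        observed = {(p.group_a, p.group_b): p.p_value for p in report.posthoc}
        for pair, expected in R_DUNNETT.items():
            assert observed[pair] == pytest.approx(expected, abs=1e-4)

    def test_identical_groups_give_p_one(self):
        table = _table({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        report = omnibus_and_posthoc(table, "v", TestChoice.T_TEST)
        assert report.omnibus_stat == pytest.approx(0.0)
        assert report.omnibus_p == pytest.approx(1.0)

    def test_tukey_significance_pattern_casestudy(self, cs1):
        report = omnibus_and_posthoc(cs1, "Cyclin A", TestChoice.ANOVA_TUKEY)
        sig = {(p.group_a, p.group_b): p.significant for p in report.posthoc}
        assert sig == {
            ("Control", "40% Dehydrated"): True,
            ("Control", "Rehydrated"): False,
            ("40% Dehydrated", "Rehydrated"): True,
        }

    def test_wrong_choice_raises(self, cs1):
        with pytest.raises(ValidationError, match="t-test"):
            omnibus_and_posthoc(cs1, "Cyclin A", TestChoice.T_TEST)

    def test_tiny_group_raises(self):
        table = _table({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(ValidationError, match="variance is undefined"):
            omnibus_and_posthoc(table, "v", TestChoice.T_TEST)


class TestInvarianceProperties:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_tukey_two_groups_reduces_to_pooled_t(self, seed):
        """With k=2 the studentized range collapses onto t via q = t*sqrt(2)."""
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, rng.integers(3, 8))
        b = rng.normal(rng.normal(), 1, rng.integers(3, 8))
        from scipy import stats as ss

        t_p = ss.ttest_ind(a, b, equal_var=True).pvalue
        tukey_p = ss.tukey_hsd(a, b).pvalue[0, 1]
        assert tukey_p == pytest.approx(t_p, abs=1e-9)

    @given(st.integers(0, 2**31 - 1),
           st.floats(min_value=0.01, max_value=1000.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_row_permutation_and_scaling_leave_p_values_unchanged(self, seed, c):
        rng = np.random.default_rng(seed)
        groups = {
            name: list(rng.normal(loc, 1.0, 5))
            for name, loc in (("a", 0.0), ("b", 0.7), ("c", -0.4))
        }
        base = omnibus_and_posthoc(_table(groups), "v", TestChoice.ANOVA_TUKEY)
        shuffled = {
            name: list(rng.permutation(values)) for name, values in groups.items()
        }
        scaled = {name: [c * v for v in values] for name, values in shuffled.items()}
        other = omnibus_and_posthoc(_table(scaled), "v", TestChoice.ANOVA_TUKEY)
        assert other.omnibus_p == pytest.approx(base.omnibus_p, rel=1e-9)
        for p_base, p_other in zip(base.posthoc, other.posthoc):
            assert p_other.p_value == pytest.approx(p_base.p_value, rel=1e-8)


class TestAnalyzeAll:
    def test_one_report_per_variable(self, cs1):
        reports = analyze_all(cs1, TestChoice.ANOVA_TUKEY)
        assert [r.variable for r in reports] == cs1.variable_names
        assert all(len(r.posthoc) == 3 for r in reports)
        assert all(r.validation is None for r in reports)

    def test_failing_variable_is_contained(self):
        rows = [
            ("a", [1.0, 1.0]), ("a", [2.0, None]), ("a", [3.0, None]),
            ("b", [1.5, 2.0]), ("b", [2.5, 2.1]), ("b", [3.5, 2.2]),
        ]
        table = GroupedTable(["a", "b"], ["good", "bad"], rows)
        reports = {r.variable: r for r in analyze_all(table, TestChoice.T_TEST)}
        assert reports["good"].validation is None
        assert reports["good"].omnibus_p is not None
        assert "variance is undefined" in reports["bad"].validation
        assert reports["bad"].omnibus_p is None

    def test_missing_values_dropped_per_variable(self, cs1):
        reports = {r.variable: r for r in analyze_all(cs1, TestChoice.ANOVA_TUKEY)}
        # Cyclin B1 has complete Control (n=4) but Rehydrated n=3
        assert reports["Cyclin B1"].shapiro["Control"].p is not None
        assert reports["Cyclin B1"].shapiro["Rehydrated"].p is not None
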