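"""Per-variable statistical workflow: assumptions, test validation, omnibus, post-hoc.

For every dependent variable the engine runs Shapiro-Wilk normality per
group and Bartlett's equal-variance test, verifies that the requested
significance test suits the number of groups, then performs either a
pooled-variance Student's t-test (two groups), one-way ANOVA with
Tukey-Kramer all-pairs comparisons, or one-way ANOVA with two-sided
Dunnett comparisons of every group against the standard (first) group.
Missing values are dropped per group, independently per variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import stats as _st

from .errors import ValidationError
from .tabular_io import GroupedTable

__all__ = [
    "TestChoice",
    "PairwiseResult",
    "ShapiroOutcome",
    "StatsReport",
    "Verdict",
    "detect_groups",
    "validate_test",
    "assumption_tests",
    "omnibus_and_posthoc",
    "analyze_all",
]

#: Shapiro-Wilk sample-size window (convention of the reference platform).
SHAPIRO_MIN_N = 3
SHAPIRO_MAX_N = 5000

T_TEST_NAME = "Student's t-test (pooled)"


class TestChoice(str, Enum):
    """User-selectable significance test."""

    T_TEST = "ttest"
    ANOVA_TUKEY = "tukey"
    ANOVA_DUNNETT = "dunnett"


@dataclass
class PairwiseResult:
    """One pairwise comparison; ``group_a`` precedes ``group_b`` in input order."""

    group_a: str
    group_b: str
    p_value: float
    significant: bool


@dataclass
class ShapiroOutcome:
    statistic: float | None
    p: float | None
    reason: str | None = None


@dataclass
class Verdict:
    ok: bool
    message: str | None = None
    suggestion: TestChoice | None = None


@dataclass
class StatsReport:
    """Everything computed for one dependent variable."""

    variable: str
    shapiro: dict[str, ShapiroOutcome] = field(default_factory=dict)
    bartlett_stat: float | None = None
    bartlett_p: float | None = None
    omnibus_name: str | None = None
    omnibus_stat: float | None = None
    omnibus_p: float | None = None
    posthoc: list[PairwiseResult] = field(default_factory=list)
    validation: str | None = None
    alpha: float = 0.05


def detect_groups(table: GroupedTable) -> dict[str, dict[str, int]]:
    """Groups in input order with non-missing replicate counts per variable."""
    return {
        g: {v: len(table.nonmissing(g, v)) for v in table.variable_names}
        for g in table.group_labels
    }


def validate_test(choice: TestChoice, n_groups: int) -> Verdict:
    """Check that the requested test suits the number of groups.

    A t-test needs exactly two groups; the ANOVA variants need three or
    more.  An invalid combination yields a verdict naming the appropriate
    test rather than an exception, so the message can be written into the
    per-variable report section.
    """
    if n_groups < 2:
        raise ValidationError("need at least two groups for any comparison")
    if choice is TestChoice.T_TEST and n_groups != 2:
        return Verdict(
            False,
            f"Student's t-test requires exactly two groups but {n_groups} were "
            "detected; ANOVA with a post-hoc test (Tukey or Dunnett) is "
            "appropriate for a multi-group comparison.",
            TestChoice.ANOVA_TUKEY,
        )
    if choice is not TestChoice.T_TEST and n_groups == 2:
        return Verdict(
            False,
            f"{'Tukey' if choice is TestChoice.ANOVA_TUKEY else 'Dunnett'} "
            "post-hoc ANOVA requires at least three groups but 2 were "
            "detected; Student's t-test is appropriate for a two-group "
            "comparison.",
            TestChoice.T_TEST,
        )
    return Verdict(True)


def assumption_tests(
    table: GroupedTable, variable: str
) -> tuple[dict[str, ShapiroOutcome], float | None, float | None]:
    """Shapiro-Wilk per group and Bartlett across groups for one variable.

    Returns ``(shapiro_by_group, bartlett_statistic, bartlett_p)``.  Groups
    too small for Shapiro (n < 3), too large (n > 5000) or with zero
    variance are flagged not-computable rather than failing the run.
    """
    shapiro: dict[str, ShapiroOutcome] = {}
    for group in table.group_labels:
        values = table.nonmissing(group, variable)
        if len(values) < SHAPIRO_MIN_N:
            shapiro[group] = ShapiroOutcome(
                None, None, f"fewer than {SHAPIRO_MIN_N} non-missing values"
            )
        elif len(values) > SHAPIRO_MAX_N:
            shapiro[group] = ShapiroOutcome(
                None, None, f"more than {SHAPIRO_MAX_N} non-missing values"
            )
        elif np.ptp(values) == 0:
            shapiro[group] = ShapiroOutcome(None, None, "zero variance")
        else:
            res = _st.shapiro(values)
            shapiro[group] = ShapiroOutcome(float(res.statistic), float(res.pvalue))

    eligible = [
        table.nonmissing(g, variable)
        for g in table.group_labels
        if len(table.nonmissing(g, variable)) >= 2
    ]
    if len(eligible) < 2:
        raise ValidationError(
            f"Bartlett's test for {variable!r} needs at least two groups "
            "with two or more non-missing values"
        )
    stat, p = _st.bartlett(*eligible)
    return shapiro, float(stat), float(p)


def _group_samples(table: GroupedTable, variable: str) -> list[np.ndarray]:
    samples = []
    for group in table.group_labels:
        values = table.nonmissing(group, variable)
        if len(values) < 2:
            raise ValidationError(
                f"group {group!r} has fewer than two non-missing values for "
                f"{variable!r}; variance is undefined"
            )
        samples.append(np.asarray(values, dtype=float))
    return samples


def omnibus_and_posthoc(
    table: GroupedTable,
    variable: str,
    choice: TestChoice,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> StatsReport:
    """Run the full per-variable workflow and return a complete report.

    ``rng`` seeds the quasi-Monte-Carlo multivariate-t integration used by
    the Dunnett comparisons; the other tests are deterministic.
    Raises :class:`ValidationError` when the requested test does not suit
    the detected number of groups.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie strictly between 0 and 1")
    verdict = validate_test(choice, table.n_groups)
    if not verdict.ok:
        raise ValidationError(verdict.message)

    samples = _group_samples(table, variable)
    shapiro, bstat, bp = assumption_tests(table, variable)
    report = StatsReport(
        variable=variable,
        shapiro=shapiro,
        bartlett_stat=bstat,
        bartlett_p=bp,
        alpha=alpha,
    )
    groups = table.group_labels

    if choice is TestChoice.T_TEST:
        res = _st.ttest_ind(samples[0], samples[1], equal_var=True)
        report.omnibus_name = T_TEST_NAME
        report.omnibus_stat = float(res.statistic)
        report.omnibus_p = float(res.pvalue)
        report.posthoc = [
            PairwiseResult(groups[0], groups[1], float(res.pvalue),
                           bool(res.pvalue < alpha))
        ]
        return report

    f_res = _st.f_oneway(*samples)
    report.omnibus_name = "one-way ANOVA"
    report.omnibus_stat = float(f_res.statistic)
    report.omnibus_p = float(f_res.pvalue)

    if choice is TestChoice.ANOVA_TUKEY:
        tk = _st.tukey_hsd(*samples)
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                p = float(tk.pvalue[i, j])
                report.posthoc.append(
                    PairwiseResult(groups[i], groups[j], p, p < alpha)
                )
    else:  # Dunnett: every group versus the standard (first) group
        if rng is None or isinstance(rng, int):
            rng = np.random.default_rng(rng)
        dn = _st.dunnett(
            *samples[1:], control=samples[0],
            alternative="two-sided", random_state=rng,
        )
        for k, group in enumerate(groups[1:]):
            p = float(np.atleast_1d(dn.pvalue)[k])
            report.posthoc.append(PairwiseResult(groups[0], group, p, p < alpha))
    return report


def analyze_all(
    table: GroupedTable,
    choice: TestChoice,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> list[StatsReport]:
    """Analyze every dependent variable independently.

    A variable whose analysis fails validation (wrong test for the group
    count, degenerate group, ...) gets a report carrying the message in
    its ``validation`` field; the remaining variables are still analyzed.
    """
    reports: list[StatsReport] = []
    for variable in table.variable_names:
        try:
            reports.append(omnibus_and_posthoc(table, variable, choice, alpha, rng))
        except ValidationError as exc:
            report = StatsReport(variable=variable, alpha=alpha, validation=str(exc))
            try:
                shapiro, bstat, bp = assumption_tests(table, variable)
                report.shapiro = shapiro
                report.bartlett_stat = bstat
                report.bartlett_p = bp
            except ValidationError:
                pass
            reports.append(report)
    return reports
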