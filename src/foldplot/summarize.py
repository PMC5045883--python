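"""Plot-ready summaries: fold change vs the standard, normalized errors, curve means.

The histogram/heatmap path expresses every group mean as a fold change of
the standard (first) group's mean, with SEM or SD normalized by that same
mean.  SEM uses the total number of replicate rows of the group as n —
missing cells still count as replicates (slots) — while the SD itself is
the sample SD over the non-missing values.  The joint-point-curve path
keeps raw means and errors and treats the dependent-variable names as
numeric x coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .errors import InputError, ValidationError
from .tabular_io import GroupedTable, SummaryRow

__all__ = [
    "ErrorType",
    "GroupVariableStats",
    "CurvePoint",
    "CurveSummary",
    "group_stats",
    "fold_change_table",
    "curve_table",
]


class ErrorType(str, Enum):
    SEM = "SEM"
    SD = "SD"


@dataclass
class GroupVariableStats:
    """Raw-unit descriptive statistics for one group x variable cell."""

    group: str
    variable: str
    n_nonmissing: int
    n_slots: int
    mean: float
    sd: float | None  # sample SD (n-1); None with a single replicate
    sem: float | None

    def error(self, error_type: ErrorType) -> float | None:
        return self.sem if error_type is ErrorType.SEM else self.sd


@dataclass
class CurvePoint:
    x: float
    mean: float
    err: float | None


@dataclass
class CurveSummary:
    """Per-group series of (x, mean, error) for joint-point curve plotting."""

    series: dict[str, list[CurvePoint]]
    has_error_bars: bool
    error_type: ErrorType


def group_stats(
    values: Sequence[float | None],
    group: str = "",
    variable: str = "",
    strict_n: bool = False,
) -> GroupVariableStats:
    """Mean, SD and SEM for one group x variable, honoring missing cells.

    ``values`` is the full per-slot list for the group, with ``None`` for
    missing cells, so the slot count is simply ``len(values)``.  SEM is
    SD / sqrt(slots) by default; ``strict_n`` switches the denominator to
    the non-missing count.  With a single non-missing value SD and SEM
    are reported absent (not zero).
    """
    present = [v for v in values if v is not None]
    if not present:
        raise InputError(
            f"all values missing for group {group!r}, variable {variable!r}"
        )
    n = len(present)
    slots = len(values)
    mean = float(np.mean(present))
    if n == 1:
        sd = sem = None
    else:
        sd = float(np.std(present, ddof=1))
        sem = sd / math.sqrt(n if strict_n else slots)
    return GroupVariableStats(group, variable, n, slots, mean, sd, sem)


def fold_change_table(
    table: GroupedTable,
    error_type: ErrorType = ErrorType.SEM,
    strict_n: bool = False,
) -> list[SummaryRow]:
    """Fold-change summary rows (variable-major, groups in input order).

    Every (group, variable) mean is divided by the standard group's mean
    for that variable; errors are divided by the same reference.  The
    standard group's fold change is exactly 1.  Labels are left empty —
    annotation is a separate concern.
    """
    if table.n_groups < 2:
        raise ValidationError("fold-change normalization needs at least two groups")
    standard = table.group_labels[0]
    rows: list[SummaryRow] = []
    next_id = 1
    for variable in table.variable_names:
        ref = group_stats(table.values(standard, variable), standard, variable,
                          strict_n)
        if ref.mean == 0:
            raise InputError(
                f"standard group {standard!r} has zero mean for {variable!r}; "
                "fold change is undefined"
            )
        for group in table.group_labels:
            st = group_stats(table.values(group, variable), group, variable,
                             strict_n)
            err = st.error(error_type)
            rows.append(
                SummaryRow(
                    id=next_id,
                    group=group,
                    variable=variable,
                    nrm_mean=1.0 if group == standard else st.mean / ref.mean,
                    nrm_err=None if err is None else err / abs(ref.mean),
                )
            )
            next_id += 1
    return rows


def curve_table(
    table: GroupedTable, error_type: ErrorType = ErrorType.SEM
) -> CurveSummary:
    """Per-group (x, mean, error) series over numeric dependent variables.

    Errors are raw SEM/SD — never normalized by a reference mean.  When
    every (group, x) cell holds at most one replicate the summary reports
    ``has_error_bars = False`` and omits errors entirely.
    """
    if table.n_groups < 2:
        raise ValidationError(
            "the curve module plots a standard against at least one other group"
        )
    xs: list[tuple[float, str]] = []
    for name in table.variable_names:
        try:
            xs.append((float(name), name))
        except ValueError:
            raise InputError(
                "curve module requires numeric dependent variables "
                f"(got {name!r})"
            ) from None
    xs.sort(key=lambda pair: pair[0])
    if any(a[0] == b[0] for a, b in zip(xs, xs[1:])):
        raise InputError("curve module requires strictly distinct x values")

    series: dict[str, list[CurvePoint]] = {}
    any_replicated = False
    for group in table.group_labels:
        points: list[CurvePoint] = []
        for x, name in xs:
            values = table.nonmissing(group, name)
            if not values:
                continue  # missing fraction: no point to plot
            st = group_stats(table.values(group, name), group, name)
            if st.n_nonmissing > 1:
                any_replicated = True
            points.append(CurvePoint(x, st.mean, st.error(error_type)))
        series[group] = points
    if not any_replicated:
        for points in series.values():
            for point in points:
                point.err = None
    return CurveSummary(series, any_replicated, error_type)
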