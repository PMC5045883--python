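"""Reading the universal grouped-table layout and writing the pipeline's text artifacts.

The universal input layout is a CSV matrix: column 1 holds the group
(independent-variable) labels, one row per biological replicate; columns
2..m hold the dependent variables as raw numeric measurements.  Empty
cells are missing data points.  The first group to appear is the standard
(control) against which everything downstream is normalized.
"""

from __future__ import annotations

import csv
import io
import math
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import pandas as pd

from .errors import InputError, LayoutError

__all__ = [
    "GroupedTable",
    "SummaryRow",
    "read_grouped_table",
    "write_grouped_table",
    "write_metrics_table",
    "read_metrics_table",
    "write_stats_report",
    "METRICS_COLUMNS",
]

#: Exact column names of the plot-metrics file.
METRICS_COLUMNS = [
    "Id",
    "Condition",
    "variable",
    "NrmMean",
    "variableSEM",
    "NrmSEM",
    "variableLbl",
    "Lbl",
]


@dataclass
class GroupedTable:
    """Parsed universal input table.

    Attributes
    ----------
    group_labels:
        Distinct group names in order of first appearance (never sorted).
    variable_names:
        Dependent-variable names in column order.
    rows:
        One ``(group, values)`` tuple per replicate row; ``values`` aligns
        with ``variable_names`` and uses ``None`` for missing cells.
    """

    group_labels: list[str]
    variable_names: list[str]
    rows: list[tuple[str, list[float | None]]]

    def __post_init__(self) -> None:
        known = set(self.group_labels)
        for group, values in self.rows:
            if group not in known:
                raise LayoutError(f"row group {group!r} not in group_labels")
            if len(values) != len(self.variable_names):
                raise LayoutError(
                    f"row for group {group!r} has {len(values)} values, "
                    f"expected {len(self.variable_names)}"
                )

    @property
    def slots_per_group(self) -> dict[str, int]:
        """Total replicate rows per group, missing cells included."""
        slots = {g: 0 for g in self.group_labels}
        for group, _ in self.rows:
            slots[group] += 1
        return slots

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    def values(self, group: str, variable: str) -> list[float | None]:
        """Per-slot values (missing included) for one group x variable."""
        j = self._var_index(variable)
        return [vals[j] for g, vals in self.rows if g == group]

    def nonmissing(self, group: str, variable: str) -> list[float]:
        return [v for v in self.values(group, variable) if v is not None]

    def _var_index(self, variable: str) -> int:
        try:
            return self.variable_names.index(variable)
        except ValueError:
            raise LayoutError(f"unknown variable {variable!r}") from None


@dataclass
class SummaryRow:
    """One (group x variable) line of the plot-metrics table.

    ``nrm_mean`` is the fold change versus the standard group (exactly 1
    for the standard itself); ``nrm_err`` is the SEM or SD divided by the
    standard group's mean, or ``None`` when only a single replicate exists.
    ``label`` is the significance annotation (letters, asterisk or empty).
    """

    id: int
    group: str
    variable: str
    nrm_mean: float
    nrm_err: float | None
    label: str = ""

    def __post_init__(self) -> None:
        if self.nrm_err is not None and self.nrm_err < 0:
            raise ValueError("nrm_err must be non-negative")


def _open_source(source: str | os.PathLike | IO[str]) -> tuple[IO[str], bool]:
    if hasattr(source, "read"):
        return source, False  # type: ignore[return-value]
    return open(source, "r", encoding="utf-8", newline=""), True


def read_grouped_table(
    source: str | os.PathLike | IO[str], decimal: str = "."
) -> GroupedTable:
    """Parse the universal CSV layout into a :class:`GroupedTable`.

    Groups are recorded in order of first appearance and need not form
    contiguous blocks.  Empty (or whitespace-only) cells become missing.
    ``decimal`` allows a non-dot decimal separator convention.
    """
    handle, owned = _open_source(source)
    try:
        raw = [row for row in csv.reader(handle)]
    finally:
        if owned:
            handle.close()
    raw = [row for row in raw if any(cell.strip() for cell in row)]
    if not raw:
        raise LayoutError("input file is empty")
    header = [cell.strip() for cell in raw[0]]
    if len(header) < 2:
        raise LayoutError(
            "input needs at least 2 columns: group labels plus one dependent variable"
        )
    variable_names = header[1:]
    seen: set[str] = set()
    for name in variable_names:
        if name in seen:
            raise LayoutError(f"duplicate dependent-variable name {name!r}")
        seen.add(name)

    group_labels: list[str] = []
    rows: list[tuple[str, list[float | None]]] = []
    for r_idx, row in enumerate(raw[1:], start=2):
        group = row[0].strip() if row else ""
        if group not in group_labels:
            group_labels.append(group)
        cells = row[1:]
        # short rows are padded with missing cells
        cells = list(cells) + [""] * (len(variable_names) - len(cells))
        values: list[float | None] = []
        for c_idx, cell in enumerate(cells[: len(variable_names)]):
            text = cell.strip()
            if not text:
                values.append(None)
                continue
            if decimal != ".":
                text = text.replace(decimal, ".")
            try:
                value = float(text)
            except ValueError:
                raise InputError(
                    f"cell {cell.strip()!r} at row {r_idx}, "
                    f"column {variable_names[c_idx]!r} is not numeric"
                ) from None
            if not math.isfinite(value):
                raise InputError(
                    f"non-finite value at row {r_idx}, column {variable_names[c_idx]!r}"
                )
            values.append(value)
        rows.append((group, values))
    return GroupedTable(group_labels, variable_names, rows)


def write_grouped_table(table: GroupedTable, path: str | os.PathLike) -> None:
    """Write a :class:`GroupedTable` back out in the universal CSV layout."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["Groups", *table.variable_names])
        for group, values in table.rows:
            writer.writerow(
                [group, *["" if v is None else repr(v) for v in values]]
            )


def write_metrics_table(
    summary: Sequence[SummaryRow], error_label: str, path: str | os.PathLike
) -> None:
    """Write the plot-metrics CSV (Id, Condition, variable, NrmMean, ...).

    ``error_label`` names the error metric ("SEM" or "SD") in the
    per-variable reference columns.  Rows are written in the order given
    (variable-major, groups in input order) at full float precision.
    """
    if not summary:
        raise InputError("cannot write a metrics table from an empty summary")
    frame = pd.DataFrame(
        {
            "Id": [row.id for row in summary],
            "Condition": [row.group for row in summary],
            "variable": [row.variable for row in summary],
            "NrmMean": [row.nrm_mean for row in summary],
            "variableSEM": [f"{row.variable}{error_label}" for row in summary],
            "NrmSEM": [row.nrm_err for row in summary],
            "variableLbl": [f"{row.variable}Lbl" for row in summary],
            "Lbl": [row.label for row in summary],
        },
        columns=METRICS_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_metrics_table(path: str | os.PathLike) -> list[SummaryRow]:
    """Read a plot-metrics CSV back into :class:`SummaryRow` objects."""
    frame = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in METRICS_COLUMNS if c not in frame.columns]
    if missing:
        raise LayoutError(f"metrics file lacks columns {missing}")
    out: list[SummaryRow] = []
    for _, rec in frame.iterrows():
        err_text = str(rec["NrmSEM"]).strip()
        out.append(
            SummaryRow(
                id=int(rec["Id"]),
                group=str(rec["Condition"]),
                variable=str(rec["variable"]),
                nrm_mean=float(rec["NrmMean"]),
                nrm_err=float(err_text) if err_text else None,
                label=str(rec["Lbl"]),
            )
        )
    return out


def _fmt_p(p: float | None) -> str:
    return "NA" if p is None else format(p, ".6g")


def write_stats_report(reports: Iterable, path: str | os.PathLike) -> None:
    """Write one plain-text report file with a titled section per variable.

    Each section contains, in order: per-group Shapiro-Wilk normality
    results, Bartlett's equal-variance result, the omnibus test, the
    post-hoc table when applicable (never for a t-test), and any
    validation message.
    """
    reports = list(reports)
    if not reports:
        raise InputError("no analyzed variables to report")
    buf = io.StringIO()
    for report in reports:
        buf.write(f"== {report.variable} ==\n")
        buf.write("[Normality] Shapiro-Wilk, per group:\n")
        for group, outcome in report.shapiro.items():
            if outcome.p is None:
                buf.write(f"  {group}: not computable ({outcome.reason})\n")
            else:
                buf.write(
                    f"  {group}: W = {_fmt_p(outcome.statistic)}, "
                    f"p = {_fmt_p(outcome.p)}\n"
                )
        if report.bartlett_p is None:
            buf.write("[Equal variance] Bartlett: not computable\n")
        else:
            buf.write(
                f"[Equal variance] Bartlett: statistic = "
                f"{_fmt_p(report.bartlett_stat)}, p = {_fmt_p(report.bartlett_p)}\n"
            )
        if report.omnibus_name is not None:
            buf.write(
                f"[Omnibus] {report.omnibus_name}: statistic = "
                f"{_fmt_p(report.omnibus_stat)}, p = {_fmt_p(report.omnibus_p)}\n"
            )
        if report.posthoc and report.omnibus_name != "Student's t-test (pooled)":
            buf.write(f"[Post-hoc] pairwise comparisons (alpha = {report.alpha:g}):\n")
            for pair in report.posthoc:
                tag = "significant" if pair.significant else "ns"
                buf.write(
                    f"  {pair.group_a}-{pair.group_b}: "
                    f"p = {_fmt_p(pair.p_value)} ({tag})\n"
                )
        if report.validation:
            buf.write(f"[Validation] {report.validation}\n")
        buf.write("\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(buf.getvalue())
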