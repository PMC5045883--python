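"""Figure rendering: grouped bar charts, joint-point curves and heatmaps.

All three renderers share the same conventions: PDF vector output by
default, a mirrored (right-hand) y-axis carrying the same major and minor
ticks with no labels, minor ticks realized as unlabeled tick positions
between the labeled majors, and annotation strings taken verbatim from
the plot-metrics table.  Tests inspect the returned matplotlib figure's
object model (bars, texts, tick positions) rather than rendered pixels.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd
from matplotlib.colors import Normalize, TwoSlopeNorm
from matplotlib.figure import Figure

from . import tabular_io
from .axis_range import DEFAULT_HEADROOM, TickScheme, round_sig
from .errors import LayoutError, ValidationError
from .summarize import CurveSummary, ErrorType
from .tabular_io import SummaryRow

__all__ = [
    "PlotConfig",
    "RenderResult",
    "tick_positions",
    "render_histogram",
    "render_curve",
    "render_heatmap",
]

_PALETTE = plt.get_cmap("tab10").colors

#: Histogram/heatmap y-axis defaults (fold-change scale).
DEFAULT_Y_MAJOR = 0.5
DEFAULT_Y_MINOR = 4
#: Curve x-axis defaults.
DEFAULT_X_MAJOR = 0.5
DEFAULT_X_MINOR = 0


@dataclass
class PlotConfig:
    """User-facing plotting options shared by the three renderers."""

    title: str = ""
    x_label: str = ""
    y_label: str = ""
    error_type: ErrorType = ErrorType.SEM
    y_custom: bool = False
    y_lower: float = 0.0
    y_upper: float | None = None
    y_major: float = DEFAULT_Y_MAJOR
    y_minor: int = DEFAULT_Y_MINOR
    x_custom: bool = False
    x_lower: float | None = None
    x_upper: float | None = None
    x_major: float = DEFAULT_X_MAJOR
    x_minor: int = DEFAULT_X_MINOR
    output_path: str | os.PathLike = "figure.pdf"
    fig_width: float = 6.0
    fig_height: float = 5.0
    annotation_offset_frac: float = 0.02
    headroom: float = DEFAULT_HEADROOM


@dataclass
class RenderResult:
    figure: Figure
    figure_path: Path
    metrics_path: Path | None = None


def tick_positions(
    lower: float, upper: float, major_tick_range: float, n_minor_ticks: int
) -> tuple[list[float], list[float]]:
    """Major and minor tick positions for a resolved axis scheme.

    Majors run from ``lower`` to ``upper`` in steps of the major interval
    (the span must be an integer multiple of it); each major interval is
    subdivided by ``n_minor_ticks`` evenly spaced unlabeled minors at
    spacing ``major / (n_minor + 1)``.
    """
    scheme = TickScheme(lower, upper, major_tick_range, n_minor_ticks)
    steps = (scheme.upper - scheme.lower) / scheme.major_tick_range
    if abs(steps - round(steps)) > 1e-9:
        raise LayoutError(
            "axis span is not an integer multiple of the major tick range"
        )
    n_steps = round(steps)
    majors = [
        round_sig(scheme.lower + k * scheme.major_tick_range)
        for k in range(n_steps + 1)
    ]
    spacing = scheme.major_tick_range / (scheme.n_minor_ticks + 1)
    minors = [
        round_sig(majors[k] + j * spacing)
        for k in range(n_steps)
        for j in range(1, scheme.n_minor_ticks + 1)
    ]
    return majors, minors


def _apply_y_scheme(ax, majors: Sequence[float], minors: Sequence[float],
                    lower: float, upper: float) -> None:
    ax.set_ylim(lower, upper)
    ax.set_yticks(majors)
    ax.set_yticks(minors, minor=True)
    # mirror the tick marks onto the right spine, labels left only
    ax.tick_params(axis="y", which="both", right=True, labelright=False)


def _resolve_path(config: PlotConfig) -> Path:
    path = Path(config.output_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    return path


def render_histogram(
    summary: Sequence[SummaryRow], config: PlotConfig
) -> RenderResult:
    """Grouped fold-change bar chart with error bars and annotations.

    Bars cluster by dependent variable (column order), one bar per group
    in input order; annotation strings are drawn just above mean + error
    and the plot-metrics CSV is written next to the figure.
    """
    if not summary:
        raise ValidationError("nothing to plot: empty summary")
    variables = list(dict.fromkeys(row.variable for row in summary))
    groups = list(dict.fromkeys(row.group for row in summary))
    by_cell = {(row.group, row.variable): row for row in summary}

    if config.y_custom:
        if config.y_upper is None:
            raise ValidationError("custom y scheme requires an upper limit")
        scheme = TickScheme(config.y_lower, config.y_upper,
                            config.y_major, config.y_minor)
    else:
        data_max = max(r.nrm_mean + (r.nrm_err or 0.0) for r in summary)
        upper = config.y_major * math.ceil(
            data_max * config.headroom / config.y_major - 1e-9
        )
        scheme = TickScheme(0.0, round_sig(upper), config.y_major, config.y_minor)
    majors, minors = tick_positions(
        scheme.lower, scheme.upper, scheme.major_tick_range, scheme.n_minor_ticks
    )

    fig, ax = plt.subplots(figsize=(config.fig_width, config.fig_height))
    n_groups = len(groups)
    width = 0.8 / n_groups
    offset0 = -0.4 + width / 2
    y_span = scheme.upper - scheme.lower
    for g_idx, group in enumerate(groups):
        cells = [
            (v_idx + offset0 + g_idx * width, by_cell[(group, variable)])
            for v_idx, variable in enumerate(variables)
            if (group, variable) in by_cell
        ]
        ax.bar(
            [x for x, _ in cells],
            [row.nrm_mean for _, row in cells],
            width=width, label=group,
            color=_PALETTE[g_idx % len(_PALETTE)],
            yerr=[row.nrm_err or 0.0 for _, row in cells],
            capsize=3, edgecolor="black", linewidth=0.6,
        )
        for x, row in cells:
            if row.label:
                ax.text(
                    x,
                    row.nrm_mean + (row.nrm_err or 0.0)
                    + config.annotation_offset_frac * y_span,
                    row.label, ha="center", va="bottom",
                )
    ax.set_xticks(range(len(variables)), variables)
    _apply_y_scheme(ax, majors, minors, scheme.lower, scheme.upper)
    ax.set_title(config.title)
    ax.set_xlabel(config.x_label)
    ax.set_ylabel(config.y_label)
    ax.legend(frameon=False)

    figure_path = _resolve_path(config)
    fig.savefig(figure_path)
    metrics_path = figure_path.with_suffix(".metrics.csv")
    tabular_io.write_metrics_table(summary, config.error_type.value, metrics_path)
    return RenderResult(fig, figure_path, metrics_path)


def render_curve(summary: CurveSummary, config: PlotConfig) -> RenderResult:
    """Joint-point curve: one polyline with markers per group over numeric x.

    Error bars appear only when the data carry replication; axis schemes
    default to interval 0.5 with no minors on x and the histogram's
    0.5/4 scheme on y, snapped outward to cover the data.
    """
    if len(summary.series) < 2:
        raise ValidationError(
            "the curve module needs a standard and at least one other group"
        )
    points = [p for series in summary.series.values() for p in series]
    if not points:
        raise ValidationError("no plottable points")

    if config.x_custom:
        if config.x_lower is None or config.x_upper is None:
            raise ValidationError("custom x scheme requires both limits")
        x_scheme = TickScheme(config.x_lower, config.x_upper,
                              config.x_major, config.x_minor)
    else:
        xs = [p.x for p in points]
        x_scheme = TickScheme(
            round_sig(config.x_major * math.floor(min(xs) / config.x_major + 1e-9)),
            round_sig(config.x_major * math.ceil(max(xs) / config.x_major - 1e-9)),
            config.x_major, config.x_minor,
        )
    if config.y_custom:
        if config.y_upper is None:
            raise ValidationError("custom y scheme requires an upper limit")
        y_scheme = TickScheme(config.y_lower, config.y_upper,
                              config.y_major, config.y_minor)
    else:
        los = [p.mean - (p.err or 0.0) for p in points]
        his = [p.mean + (p.err or 0.0) for p in points]
        y_scheme = TickScheme(
            round_sig(config.y_major * math.floor(min(los) / config.y_major + 1e-9)),
            round_sig(config.y_major * math.ceil(max(his) / config.y_major - 1e-9)),
            config.y_major, config.y_minor,
        )
    x_majors, x_minors = tick_positions(
        x_scheme.lower, x_scheme.upper, x_scheme.major_tick_range,
        x_scheme.n_minor_ticks,
    )
    y_majors, y_minors = tick_positions(
        y_scheme.lower, y_scheme.upper, y_scheme.major_tick_range,
        y_scheme.n_minor_ticks,
    )

    fig, ax = plt.subplots(figsize=(config.fig_width, config.fig_height))
    for g_idx, (group, series) in enumerate(summary.series.items()):
        xs = [p.x for p in series]
        means = [p.mean for p in series]
        color = _PALETTE[g_idx % len(_PALETTE)]
        if summary.has_error_bars:
            errs = [p.err or 0.0 for p in series]
            ax.errorbar(xs, means, yerr=errs, marker="o", capsize=3,
                        color=color, label=group)
        else:
            ax.plot(xs, means, marker="o", color=color, label=group)
    ax.set_xlim(x_scheme.lower, x_scheme.upper)
    ax.set_xticks(x_majors)
    ax.set_xticks(x_minors, minor=True)
    _apply_y_scheme(ax, y_majors, y_minors, y_scheme.lower, y_scheme.upper)
    ax.set_title(config.title)
    ax.set_xlabel(config.x_label)
    ax.set_ylabel(config.y_label)
    ax.legend(frameon=False)

    figure_path = _resolve_path(config)
    fig.savefig(figure_path)
    metrics_path = figure_path.with_suffix(".metrics.csv")
    frame = pd.DataFrame(
        [
            {
                "Id": idx + 1,
                "Condition": group,
                "x": p.x,
                "Mean": p.mean,
                summary.error_type.value: p.err,
            }
            for idx, (group, p) in enumerate(
                (g, p) for g, series in summary.series.items() for p in series
            )
        ]
    )
    frame.to_csv(metrics_path, index=False)
    return RenderResult(fig, figure_path, metrics_path)


def render_heatmap(
    summary: Sequence[SummaryRow], config: PlotConfig
) -> RenderResult:
    """Simple fold-change heatmap: groups x variables tiles, anchored at 1.

    Uses a diverging two-color gradient centered on the standard's fold
    change of 1, so enrichment and depletion read symmetrically.
    """
    if not summary:
        raise ValidationError("nothing to plot: empty summary")
    variables = list(dict.fromkeys(row.variable for row in summary))
    groups = list(dict.fromkeys(row.group for row in summary))
    by_cell = {(row.group, row.variable): row.nrm_mean for row in summary}
    grid = [[by_cell[(g, v)] for v in variables] for g in groups]

    values = [v for row in grid for v in row]
    lo, hi = min(values), max(values)
    if lo < 1.0 < hi:
        norm = TwoSlopeNorm(vcenter=1.0, vmin=lo, vmax=hi)
    else:  # one-sided or uniform data: symmetric window around 1
        half = max(abs(v - 1.0) for v in values) or 0.5
        norm = Normalize(vmin=1.0 - half, vmax=1.0 + half)

    fig, ax = plt.subplots(figsize=(config.fig_width, config.fig_height))
    image = ax.imshow(grid, cmap="RdBu_r", norm=norm, aspect="auto")
    ax.set_xticks(range(len(variables)), variables)
    ax.set_yticks(range(len(groups)), groups)
    ax.set_title(config.title)
    ax.set_xlabel(config.x_label)
    ax.set_ylabel(config.y_label)
    fig.colorbar(image, ax=ax, label=f"fold change vs {groups[0]}")

    figure_path = _resolve_path(config)
    fig.savefig(figure_path)
    return RenderResult(fig, figure_path)
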