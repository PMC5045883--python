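"""Axis range finding: optimal major tick range, limits and minor-tick options.

Given the data extreme(s) and an intended number of major ticks, the
module rounds the raw interval up onto a 0.05-times-power-of-ten grid:

    raw            = (max - min) / intended_major_ticks
    i              = ceil(log10(raw))
    major interval = ceil(raw / 10^i / 0.05) * 0.05 * 10^i

Axis limits snap outward to multiples of that interval.  Admissible minor
tick counts come from enumerating the decimal divisors of the interval:
the interval is scaled by the smallest power of ten that makes it an
integer (one extra factor of ten whenever the largest option would fall
below four), each integer divisor d yields the option interval/d - 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal

import sympy

from .errors import ValidationError
from .summarize import ErrorType, curve_table, fold_change_table
from .tabular_io import GroupedTable

__all__ = [
    "RangeQuery",
    "AxisRangeResult",
    "TickScheme",
    "round_sig",
    "optimal_major_tick_range",
    "axis_limits",
    "decimal_divisors",
    "minor_tick_options",
    "autorange_bar_y",
    "autorange_curve",
]

#: Guard against floating-point round-up at exact multiples of the grid.
_EPS = 1e-9

#: Multiplicative padding applied to the data maximum before range finding,
#: leaving room above the tallest bar for significance annotations.
DEFAULT_HEADROOM = 1.1


def round_sig(x: float, digits: int = 12) -> float:
    """Round to ``digits`` significant digits (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, digits - 1 - math.floor(math.log10(abs(x))))


@dataclass
class RangeQuery:
    """Inputs to the range finder for one axis."""

    max: float
    intended_major_ticks: int
    min: float = 0.0
    headroom: float = DEFAULT_HEADROOM

    def __post_init__(self) -> None:
        if self.intended_major_ticks < 1:
            raise ValidationError("intended_major_ticks must be at least 1")


@dataclass
class AxisRangeResult:
    raw_range: float
    i: int
    major_tick_range: float
    lower_limit: float
    upper_limit: float
    minor_tick_options: list[int]


@dataclass
class TickScheme:
    """A fully resolved axis: limits, interval and minor-tick count."""

    lower: float
    upper: float
    major_tick_range: float
    n_minor_ticks: int

    def __post_init__(self) -> None:
        if self.n_minor_ticks < 0:
            raise ValidationError("n_minor_ticks must be non-negative")
        if self.upper <= self.lower:
            raise ValidationError("upper limit must exceed lower limit")


def optimal_major_tick_range(query: RangeQuery) -> tuple[float, int, float]:
    """Rounded major tick interval for the queried axis.

    Returns ``(raw_range, i, major_tick_range)``; headroom multiplies the
    maximum only.
    """
    span = query.max * query.headroom - query.min
    if span <= 0:
        raise ValidationError(
            "degenerate axis range: headroom-adjusted max does not exceed min"
        )
    raw = round_sig(span / query.intended_major_ticks)
    i = math.ceil(round(math.log10(raw), 9))
    optimal = math.ceil(raw / 10**i / 0.05 - _EPS) * 0.05 * 10**i
    return raw, i, round_sig(optimal)


def axis_limits(
    max_value: float,
    min_value: float,
    major_tick_range: float,
    default_zero_lower: bool = True,
) -> tuple[float, float]:
    """Outward-snapped axis limits as multiples of the major interval.

    ``max_value`` is expected to already carry any headroom.  The lower
    limit is 0 under the default convention (bar charts start at zero),
    otherwise it floors ``min_value`` onto the grid.
    """
    if major_tick_range <= 0:
        raise ValidationError("major_tick_range must be positive")
    upper = major_tick_range * math.ceil(max_value / major_tick_range - _EPS)
    if default_zero_lower:
        lower = 0.0
    else:
        lower = major_tick_range * math.floor(min_value / major_tick_range + _EPS)
    return round_sig(lower), round_sig(upper)


def _scaled_integer(x: float) -> tuple[int, int]:
    """Represent positive decimal ``x`` as ``n / 10**k`` with integer n.

    Applies the smallest power of ten making ``x`` integer, then extra
    factors of ten while the largest minor-tick option (n - 1) would be
    below four.
    """
    if x <= 0:
        raise ValidationError("divisor enumeration needs a positive tick range")
    d = Decimal(repr(round_sig(x))).normalize()
    exponent = d.as_tuple().exponent
    k = max(0, -int(exponent))
    n = int(d.scaleb(k))
    while n - 1 < 4:  # second scaling factor: guarantee an option >= 4
        k += 1
        n *= 10
    return n, k


def decimal_divisors(x: float) -> list[float]:
    """All decimal divisors of ``x`` (ascending), via integer scaling."""
    n, k = _scaled_integer(x)
    return [round_sig(dv / 10**k) for dv in sympy.divisors(n)]


def minor_tick_options(major_tick_range: float) -> list[int]:
    """Admissible minor-tick counts: interval / divisor - 1, ascending."""
    n, _ = _scaled_integer(major_tick_range)
    return sorted(n // dv - 1 for dv in sympy.divisors(n))


def _finish(query: RangeQuery, default_zero_lower: bool) -> AxisRangeResult:
    raw, i, interval = optimal_major_tick_range(query)
    lower, upper = axis_limits(
        query.max * query.headroom, query.min, interval, default_zero_lower
    )
    return AxisRangeResult(raw, i, interval, lower, upper,
                           minor_tick_options(interval))


def autorange_bar_y(
    table: GroupedTable,
    intended_major_ticks: int = 5,
    error_type: ErrorType = ErrorType.SEM,
    headroom: float = DEFAULT_HEADROOM,
    min_value: float = 0.0,
) -> AxisRangeResult:
    """Y-axis range finding for the histogram: fold change + normalized error.

    The axis maximum is the largest fold change plus its normalized error
    across all groups and variables, padded by ``headroom``; the minimum
    defaults to zero (bars start at the baseline).
    """
    summary = fold_change_table(table, error_type)
    data_max = max(row.nrm_mean + (row.nrm_err or 0.0) for row in summary)
    query = RangeQuery(data_max, intended_major_ticks, min_value, headroom)
    return _finish(query, default_zero_lower=min_value == 0.0)


def autorange_curve(
    table: GroupedTable,
    intended_x: int = 5,
    intended_y: int = 5,
    error_type: ErrorType = ErrorType.SEM,
    headroom: float = 1.0,
) -> tuple[AxisRangeResult, AxisRangeResult]:
    """Per-axis range finding for the joint-point curve.

    The y-axis spans mean - error to mean + error (no zero forcing, since
    curve data are not normalized); the x-axis spans the numeric
    dependent-variable values.  ``headroom`` multiplies both extremes of
    each axis (default 1: curve axes hug the data).
    """
    summary = curve_table(table, error_type)
    points = [p for series in summary.series.values() for p in series]
    if not points:
        raise ValidationError("no plottable points for range finding")
    y_hi = max(p.mean + (p.err or 0.0) for p in points) * headroom
    y_lo = min(p.mean - (p.err or 0.0) for p in points) * headroom
    x_hi = max(p.x for p in points) * headroom
    x_lo = min(p.x for p in points) * headroom

    x_res = _finish(
        RangeQuery(x_hi, intended_x, x_lo, headroom=1.0),
        default_zero_lower=False,
    )
    y_res = _finish(
        RangeQuery(y_hi, intended_y, y_lo, headroom=1.0),
        default_zero_lower=False,
    )
    return x_res, y_res
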