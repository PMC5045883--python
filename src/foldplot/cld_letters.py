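"""Significance annotation: pair-order normalization and compact letter display.

Tukey-style all-pairs results are condensed into a compact letter display
(CLD): each group receives one or more lower-case letters such that two
groups share a letter exactly when their pairwise comparison is NOT
significant.  The first group in input order always carries "a", so bars
read naturally left to right.  t-test and Dunnett results use asterisk
annotation on groups that differ from the standard.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import InputError, ValidationError
from .stats_engine import PairwiseResult, StatsReport, TestChoice

__all__ = [
    "PairLabel",
    "normalize_pair_order",
    "parse_pair_label",
    "assign_letters",
    "annotation_for",
]

PAIR_SEPARATOR = "-"


@dataclass
class PairLabel:
    """A pairwise-comparison label with its resolved group names."""

    group_a: str
    group_b: str

    @property
    def text(self) -> str:
        return f"{self.group_a}{PAIR_SEPARATOR}{self.group_b}"


def normalize_pair_order(pair: PairLabel, group_order: Sequence[str]) -> PairLabel:
    """Flip a pair so its first group comes first in the input group order.

    Pairwise-test reports often print comparisons treatment-first (e.g.
    "stress-control"); plotting wants the standard first ("control-stress").
    """
    try:
        ia = group_order.index(pair.group_a)
        ib = group_order.index(pair.group_b)
    except ValueError as exc:
        raise InputError(f"unknown group in pair {pair.text!r}: {exc}") from None
    if ib < ia:
        return PairLabel(pair.group_b, pair.group_a)
    return PairLabel(pair.group_a, pair.group_b)


def parse_pair_label(text: str, group_order: Sequence[str]) -> PairLabel:
    """Parse "A-B" against known group names (names may contain the separator)."""
    known = set(group_order)
    pieces = text.split(PAIR_SEPARATOR)
    for cut in range(1, len(pieces)):
        a = PAIR_SEPARATOR.join(pieces[:cut])
        b = PAIR_SEPARATOR.join(pieces[cut:])
        if a in known and b in known:
            return PairLabel(a, b)
    raise InputError(f"cannot resolve pair label {text!r} against known groups")


def _letter(index: int) -> str:
    # a..z, then aa, ab, ... (spreadsheet-style base 26)
    out = ""
    index += 1
    while index > 0:
        index, rem = divmod(index - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def assign_letters(
    pairs: Iterable[PairwiseResult], group_order: Sequence[str]
) -> dict[str, str]:
    """Insert-absorb compact letter display keyed to input group order.

    Sweeps significant pairs in normalized (first-index, second-index)
    order: every letter column containing both members is duplicated and
    split, then columns that became subsets of another are absorbed.
    Non-significant pairs always end up sharing a column, significant
    pairs never do.  Columns are lettered so that the first group in
    ``group_order`` gets "a".
    """
    order = list(group_order)
    index = {g: k for k, g in enumerate(order)}
    wanted = {frozenset((a, b)) for k, a in enumerate(order) for b in order[k + 1:]}
    seen: dict[frozenset, bool] = {}
    for pair in pairs:
        if pair.group_a not in index or pair.group_b not in index:
            raise InputError(f"unknown group in pair {pair.group_a}-{pair.group_b}")
        seen[frozenset((pair.group_a, pair.group_b))] = pair.significant
    if set(seen) != wanted:
        raise InputError(
            "letter assignment needs the complete set of unordered group pairs"
        )

    significant = sorted(
        (key for key, sig in seen.items() if sig),
        key=lambda key: tuple(sorted(index[g] for g in key)),
    )
    columns: list[set[str]] = [set(order)]
    for key in significant:
        a, b = sorted(key, key=index.get)
        next_columns: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                next_columns.append(col - {a})
                next_columns.append(col - {b})
            else:
                next_columns.append(col)
        # absorb: dedupe, drop empties and strict subsets of another column
        unique: list[set[str]] = []
        for col in next_columns:
            if col and col not in unique:
                unique.append(col)
        columns = [
            col for col in unique if not any(col < other for other in unique)
        ]

    # deterministic column order: earliest member first, then member tuple
    columns.sort(key=lambda col: tuple(sorted(index[g] for g in col)))
    letters = {id(col): _letter(k) for k, col in enumerate(columns)}
    return {
        g: "".join(letters[id(col)] for col in columns if g in col) for g in order
    }


def annotation_for(
    choice: TestChoice, report: StatsReport, group_order: Sequence[str]
) -> dict[str, str]:
    """Per-group annotation strings appropriate to the chosen test.

    Tukey results become a compact letter display; t-test and Dunnett
    results mark each non-standard group whose comparison against the
    standard is significant with an asterisk (the standard group itself
    is never marked).
    """
    if choice is TestChoice.ANOVA_TUKEY:
        return assign_letters(report.posthoc, group_order)
    standard = group_order[0]
    labels = {g: "" for g in group_order}
    for pair in report.posthoc:
        norm = normalize_pair_order(PairLabel(pair.group_a, pair.group_b), group_order)
        if norm.group_a != standard:
            raise ValidationError(
                "asterisk annotation needs comparisons against the standard group"
            )
        labels[norm.group_b] = "*" if pair.significant else ""
    return labels
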