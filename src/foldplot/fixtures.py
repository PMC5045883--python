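"""Embedded demo datasets and a synthetic grouped-table generator.

`casestudy1_table` is the wood-frog liver cyclin western-blot dataset
(ECL / Coomassie intensity ratios for four cyclins under a
dehydration-rehydration cycle, n = 3-4 replicates with missing cells from
outlier removal).  `curve_demo_table` is a synthetic two-group,
20-fraction elution-like activity profile for exercising the joint-point
curve path.  `generate` draws arbitrary grouped tables from per-group
normal distributions for property and scaling tests.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass
from math import exp
from typing import Sequence

import numpy as np

from .errors import InputError
from .tabular_io import GroupedTable, read_grouped_table, write_grouped_table

__all__ = [
    "CASESTUDY1_CSV",
    "casestudy1_table",
    "curve_demo_table",
    "GroupSpec",
    "SyntheticSpec",
    "generate",
]

#: Wood-frog cyclin densitometry ratios (dehydration-rehydration cycle).
CASESTUDY1_CSV = """\
Groups,Cyclin A,Cyclin B1,Cyclin D1,Cyclin E
Control,1,1,1,1
Control,1.19604093,0.709922771,0.829852824,1.121621622
Control,,0.701239343,1.043122829,1.198614911
Control,1.090447809,0.713018827,1.086762242,
40% Dehydrated,0.653315462,0.243093923,0.159298618,
40% Dehydrated,0.92430544,0.615747952,0.169557985,0.611308901
40% Dehydrated,0.805826152,0.253410348,0.315173675,0.676607642
40% Dehydrated,,0.510693792,0.313817882,0.665111318
Rehydrated,1.103239032,0.819114471,0.566761364,0.674198593
Rehydrated,,,0.687641907,0.757135246
Rehydrated,1.272757148,0.874822064,0.769900287,
Rehydrated,1.248098927,0.840052737,0.64319508,0.776602925
"""


def casestudy1_table() -> GroupedTable:
    """The embedded 3-group, 4-cyclin densitometry table (missing cells kept)."""
    return read_grouped_table(io.StringIO(CASESTUDY1_CSV))


def curve_demo_table(n_fractions: int = 20) -> GroupedTable:
    """Synthetic two-group elution-profile-like curve dataset.

    One activity value per (group, fraction) — no replication, so the
    curve path must render without error bars.  Values are deterministic
    Gaussian-shaped peaks: the control peaks around fraction 8, the
    dehydrated group later and lower.  This is a synthetic stand-in
    shaped like a column-chromatography readout, not measured data.
    """
    fractions = list(range(1, n_fractions + 1))

    def peak(x: float, center: float, width: float, height: float) -> float:
        return round(height * exp(-((x - center) ** 2) / (2 * width**2)), 6)

    rows = [
        ("Control", [peak(x, 8.0, 2.0, 1.0) for x in fractions]),
        ("40% Dehydrated", [peak(x, 12.0, 3.0, 0.55) for x in fractions]),
    ]
    return GroupedTable(
        group_labels=["Control", "40% Dehydrated"],
        variable_names=[str(x) for x in fractions],
        rows=rows,
    )


@dataclass
class GroupSpec:
    """One synthetic group: name, replicate count, per-variable mean and SD."""

    name: str
    n_replicates: int
    means: Sequence[float]
    sds: Sequence[float]


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic grouped table.

    The default recipe mimics a small densitometry experiment: a control
    and two treatment groups, four replicates, fold-change-scale means
    with ~10% biological scatter and no missing cells.
    """

    groups: Sequence[GroupSpec]
    variables: Sequence[str]
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.groups) < 2:
            raise InputError("synthetic spec needs at least two groups")
        if not self.variables:
            raise InputError("synthetic spec needs at least one variable")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise InputError("missing_rate must lie in [0, 0.5]")
        for group in self.groups:
            if group.n_replicates < 1:
                raise InputError(f"group {group.name!r} needs >= 1 replicate")
            if len(group.means) != len(self.variables) or len(group.sds) != len(
                self.variables
            ):
                raise InputError(
                    f"group {group.name!r}: means/sds must align with variables"
                )
            if any(sd < 0 for sd in group.sds):
                raise InputError(f"group {group.name!r}: SDs must be >= 0")

    @classmethod
    def default(cls, seed: int = 0) -> "SyntheticSpec":
        return cls(
            groups=[
                GroupSpec("Control", 4, (1.0, 1.0), (0.10, 0.10)),
                GroupSpec("Treatment A", 4, (0.60, 1.40), (0.10, 0.15)),
                GroupSpec("Treatment B", 4, (1.10, 0.80), (0.10, 0.12)),
            ],
            variables=["Protein X", "Protein Y"],
            missing_rate=0.0,
            seed=seed,
        )


def generate(
    spec: SyntheticSpec, path: str | os.PathLike | None = None
) -> GroupedTable:
    """Draw a reproducible synthetic table from per-group normal distributions.

    Cells are masked independently at ``missing_rate``, except the first
    replicate row of each group, which is always kept so that every
    (group, variable) retains at least one observation and the full
    pipeline stays runnable.  Optionally writes the table as CSV.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple[str, list[float | None]]] = []
    for group in spec.groups:
        draws = rng.normal(
            loc=np.asarray(group.means, dtype=float),
            scale=np.asarray(group.sds, dtype=float),
            size=(group.n_replicates, len(spec.variables)),
        )
        mask = rng.random(draws.shape) < spec.missing_rate
        mask[0, :] = False  # guarantee one observation per cell
        for r in range(group.n_replicates):
            rows.append(
                (
                    group.name,
                    [
                        None if mask[r, c] else float(draws[r, c])
                        for c in range(len(spec.variables))
                    ],
                )
            )
    table = GroupedTable(
        group_labels=[g.name for g in spec.groups],
        variable_names=list(spec.variables),
        rows=rows,
    )
    if path is not None:
        write_grouped_table(table, path)
    return table
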