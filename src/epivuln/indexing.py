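"""Zero unitarization and Perkal standardized-sums synthetic indices.

Zero unitarization maps each indicator to [0, 1] within the analysed
district set:

* stimulant:    v = (x − min x) / (max x − min x)
* destimulant:  v = (max x − x) / (max x − min x)

so that after the transform a *high* unitized value is always favourable
(low vulnerability).  The Perkal index of a group of indicators is the
arithmetic mean of the group's unitized columns, w = Σ v_ij / n, again in
[0, 1].  The convention throughout the package: **the lower the synthetic
index, the more vulnerable the district.**

:func:`compute_all_indices` produces the general index WO over all kept
indicators and six component indices: Wd / Ws / Wg / Wzp over the
demographic / social / economic / spatial-development nature groups and
Wz / Wn over the intended / unintended relation groups (an indicator
tagged with both relations contributes to both, so Wz and Wn overlap).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .registry import IndicatorRegistry

#: index name -> (filter kind, tag)
COMPONENT_GROUPS: dict[str, tuple[str, str]] = {
    "Wd": ("nature", "D"),
    "Ws": ("nature", "S"),
    "Wg": ("nature", "E"),
    "Wzp": ("nature", "L"),
    "Wz": ("relation", "intended"),
    "Wn": ("relation", "unintended"),
}


class UnitizationError(ValueError):
    """Raised when a column cannot be unitized (degenerate range)."""


def unitize(values: pd.Series, orientation: str) -> pd.Series:
    """Zero-unitarize one raw indicator column.

    Stimulants map min→0, max→1; destimulants are reversed (min→1, max→0).
    The min/max are taken over the column itself, so the transform is
    invariant to positive affine rescaling of the raw indicator.
    """
    lo, hi = float(values.min()), float(values.max())
    if not hi > lo:
        raise UnitizationError(
            f"column {values.name!r} has max == min ({hi}); constant columns "
            "must be removed during screening"
        )
    if orientation == "stimulant":
        return (values - lo) / (hi - lo)
    if orientation == "destimulant":
        return (hi - values) / (hi - lo)
    raise UnitizationError(f"unknown orientation {orientation!r}")


def unitize_table(table: pd.DataFrame, registry: IndicatorRegistry) -> pd.DataFrame:
    """Unitize every column of *table* using orientations from *registry*."""
    registry.resolve(table.columns)
    return pd.DataFrame(
        {c: unitize(table[c], registry.orientation(c)) for c in table.columns},
        index=table.index,
    )


def perkal_index(unitized: pd.DataFrame, codes: Sequence[str]) -> pd.Series:
    """Standardized-sums (Perkal) index: per-district mean of the group's
    unitized columns."""
    codes = list(codes)
    if not codes:
        raise UnitizationError("Perkal index of an empty indicator group")
    missing = [c for c in codes if c not in unitized.columns]
    if missing:
        raise UnitizationError(f"group codes missing from unitized table: {missing}")
    return unitized[codes].mean(axis=1)


@dataclass
class SyntheticIndices:
    """Per-district synthetic indices plus the group memberships behind them.

    ``frame`` holds one column per computed index (WO always; component
    indices only when their group is non-empty after screening).
    """

    frame: pd.DataFrame
    groups: dict[str, list[str]] = field(default_factory=dict)

    @property
    def group_sizes(self) -> dict[str, int]:
        return {name: len(codes) for name, codes in self.groups.items()}

    def __getitem__(self, name: str) -> pd.Series:
        return self.frame[name]

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index_label="district_id")

    def summary_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"groups": self.groups, "n": self.group_sizes}, indent=2
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def compute_all_indices(
    table: pd.DataFrame, registry: IndicatorRegistry
) -> SyntheticIndices:
    """Compute WO and the six component indices from a screened raw table.

    A nature/relation group left empty by screening yields no column for
    that index; a warning is emitted.
    """
    unitized = unitize_table(table, registry)
    groups: dict[str, list[str]] = {"WO": list(table.columns)}
    for name, (kind, tag) in COMPONENT_GROUPS.items():
        if kind == "nature":
            member = registry.subset_codes(nature=tag)
        else:
            member = registry.subset_codes(relation=tag)
        groups[name] = [c for c in table.columns if c in set(member)]

    columns: dict[str, pd.Series] = {}
    for name, codes in groups.items():
        if not codes:
            warnings.warn(
                f"component index {name} has no indicators after screening; omitted",
                stacklevel=2,
            )
            continue
        columns[name] = perkal_index(unitized, codes)
    present_groups = {name: groups[name] for name in columns}
    return SyntheticIndices(frame=pd.DataFrame(columns, index=table.index),
                            groups=present_groups)
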