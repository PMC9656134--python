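"""Temporal association between synthetic indices and epidemic incidence.

The incidence input is a panel of *cumulative* registered case counts per
district at successive snapshot dates (the study design samples the
epidemic at 30-day intervals).  For each synthetic index and each
snapshot, the Pearson correlation between the index and the cumulative
counts is computed across districts.  Because a low index means high
vulnerability, a vulnerability-driven epidemic shows *negative*
correlations whose magnitude grows as the outbreak couples more strongly
to the underlying socio-economic structure.

Counts are correlated on their raw scale by default; ``log1p=True``
applies log(1 + C) first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .indexing import SyntheticIndices

logger = logging.getLogger(__name__)


class CorrelationError(ValueError):
    """Raised on invalid correlation inputs."""


# ---------------------------------------------------------------------------
# incidence panel
# ---------------------------------------------------------------------------

@dataclass
class IncidencePanel:
    """Cumulative case counts: districts × ordered snapshot dates.

    ``counts`` is a wide DataFrame indexed by district id with one column
    per snapshot (pandas Timestamps), non-decreasing along columns.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        cols = pd.DatetimeIndex(self.counts.columns)
        if not cols.is_monotonic_increasing or cols.has_duplicates:
            raise CorrelationError("snapshot dates must be strictly increasing")
        self.counts = self.counts.set_axis(cols, axis=1)
        if self.counts.index.has_duplicates:
            raise CorrelationError("duplicate district ids in incidence panel")
        values = self.counts.to_numpy(dtype=float)
        if (values < 0).any():
            raise CorrelationError("case counts must be non-negative")
        diffs = np.diff(values, axis=1)
        if diffs.size and (diffs < 0).any():
            bad = self.counts.index[(diffs < 0).any(axis=1)].tolist()
            raise CorrelationError(
                f"cumulative counts decrease over time for districts {bad[:5]}"
            )

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.counts.columns)

    @property
    def district_ids(self) -> pd.Index:
        return self.counts.index

    # -- long-format CSV (district_id, date, cumulative_cases) --------------
    @classmethod
    def from_long_csv(cls, path: str | Path) -> "IncidencePanel":
        long = pd.read_csv(path, parse_dates=["date"])
        wide = long.pivot(index="district_id", columns="date", values="cumulative_cases")
        return cls(wide.sort_index(axis=1))

    def to_long_csv(self, path: str | Path) -> None:
        long = (
            self.counts.rename_axis(index="district_id", columns="date")
            .stack()
            .rename("cumulative_cases")
            .reset_index()
        )
        long["date"] = long["date"].dt.strftime("%Y-%m-%d")
        long.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided p-value (t transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CorrelationError("pearson requires two equal-length vectors")
    if x.size < 3:
        raise CorrelationError("pearson requires at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise CorrelationError("pearson is undefined for a constant input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_series(
    indices: SyntheticIndices | pd.DataFrame,
    panel: IncidencePanel,
    log1p: bool = False,
) -> pd.DataFrame:
    """Pearson r between each index and cumulative cases at each snapshot.

    Districts present in only one source are excluded (counts logged);
    within each (index, date) pair, rows with missing values are dropped
    pairwise.  Returns a long DataFrame with columns
    ``index, date, r, p, n``.
    """
    frame = indices.frame if isinstance(indices, SyntheticIndices) else indices
    common = frame.index.intersection(panel.district_ids)
    if len(common) < 3:
        raise CorrelationError(
            f"only {len(common)} districts shared between indices and panel"
        )
    dropped = (len(frame) - len(common), len(panel.district_ids) - len(common))
    if any(dropped):
        logger.info(
            "correlation alignment dropped %d index districts and %d panel districts",
            *dropped,
        )
    counts = panel.counts.loc[common].astype(float)
    if log1p:
        counts = np.log1p(counts)
    rows = []
    for name in frame.columns:
        idx = frame.loc[common, name]
        for date in panel.dates:
            pair = pd.concat([idx, counts[date]], axis=1).dropna()
            if len(pair) < 3:
                raise CorrelationError(
                    f"fewer than 3 complete districts for {name} at {date.date()}"
                )
            r, p = pearson(pair.iloc[:, 0], pair.iloc[:, 1])
            rows.append({"index": name, "date": date, "r": r, "p": p, "n": len(pair)})
    return pd.DataFrame(rows)


def correlation_wide(series: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long correlation series to dates × index names (r values)."""
    return series.pivot(index="date", columns="index", values="r")
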