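"""Variable screening: quasi-constant elimination and collinearity pruning.

Screening runs in two passes over a district-by-indicator table:

1. **Coefficient-of-variation filter.**  Indicators whose sample CV
   (standard deviation over |mean|, n−1 denominator) does not exceed a
   threshold (default 0.1) carry almost no discriminating information
   across districts ("quasi-variables") and are removed.
2. **Correlation pruning.**  Among the survivors, strongly collinear
   indicators (pairwise Pearson |r| above a threshold, default 0.6) are
   pruned greedily: while any offending pair remains, the member of an
   offending pair with the largest mean absolute correlation to all
   currently kept indicators is dropped; exact ties are broken by column
   order (the later column is dropped).

The result is a reduced table in which every remaining pairwise |r| is at
or below the threshold, plus a :class:`ScreeningReport` that partitions
the input codes into kept / CV-removed / correlation-removed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import IndicatorRegistry

logger = logging.getLogger(__name__)


class ScreeningError(ValueError):
    """Raised on invalid screening inputs."""


# ---------------------------------------------------------------------------
# indicator table helpers
# ---------------------------------------------------------------------------

def validate_table(table: pd.DataFrame, registry: IndicatorRegistry | None = None) -> None:
    """Check a raw indicator table: unique district ids and codes, and
    (when a registry is given) that every column resolves in it."""
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ScreeningError(f"duplicate district ids: {dupes}")
    if table.columns.has_duplicates:
        dupes = table.columns[table.columns.duplicated()].unique().tolist()
        raise ScreeningError(f"duplicate indicator codes: {dupes}")
    if registry is not None:
        registry.resolve(table.columns)


def load_indicator_table(path: str | Path) -> pd.DataFrame:
    """Read a district × indicator CSV (first column = district id)."""
    return pd.read_csv(path, index_col=0)


def handle_missing(table: pd.DataFrame, policy: str = "drop") -> pd.DataFrame:
    """Resolve missing values before screening.

    ``"drop"`` removes districts with any missing indicator (counts are
    logged); ``"impute"`` replaces missing entries by the column mean.
    """
    if not table.isna().any().any():
        return table
    if policy == "drop":
        kept = table.dropna()
        logger.info(
            "dropped %d of %d districts with missing indicator values",
            len(table) - len(kept),
            len(table),
        )
        if kept.empty:
            raise ScreeningError("all districts removed by missing-value policy")
        return kept
    if policy == "impute":
        logger.info("mean-imputed %d missing values", int(table.isna().sum().sum()))
        return table.fillna(table.mean())
    raise ScreeningError(f"unknown missing-value policy {policy!r}")


# ---------------------------------------------------------------------------
# stage 1a: coefficient of variation
# ---------------------------------------------------------------------------

def coefficient_of_variation(values) -> float:
    """Sample CV: sd (n−1 denominator) divided by |mean|.

    Returns ``0`` for a constant vector and ``+inf`` when the mean is 0
    but the spread is not (such columns are informative and must be kept
    by the filter — e.g. migration balances centred on zero).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ScreeningError("CV requires a 1-d vector of at least 2 values")
    if np.isnan(x).any():
        raise ScreeningError("CV input contains missing values; resolve them upstream")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        return 0.0
    mean = abs(float(np.mean(x)))
    if mean == 0.0:
        return math.inf
    return sd / mean


def screen_by_cv(
    table: pd.DataFrame, threshold: float = 0.1
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Remove quasi-constant indicators (CV ≤ *threshold*).

    Returns the reduced table (original column order preserved) and a
    mapping of removed code → CV.
    """
    if threshold < 0:
        raise ScreeningError("CV threshold must be non-negative")
    cvs = {c: coefficient_of_variation(table[c]) for c in table.columns}
    removed = {c: cv for c, cv in cvs.items() if cv <= threshold}
    kept = [c for c in table.columns if c not in removed]
    if not kept:
        raise ScreeningError("CV filter removed every indicator; nothing to aggregate")
    return table[kept], removed


# ---------------------------------------------------------------------------
# stage 1b: correlation pruning
# ---------------------------------------------------------------------------

@dataclass
class ScreeningReport:
    """Partition of screened indicator codes with supporting statistics."""

    cv: dict[str, float]
    cv_removed: dict[str, float]
    corr_matrix: pd.DataFrame  # among CV survivors, before pruning
    corr_removed: dict[str, int]  # code -> pruning step (1-based)
    kept: list[str] = field(default_factory=list)
    n_districts: int = 0

    def check_partition(self, input_codes: list[str]) -> None:
        """Assert kept ∪ cv_removed ∪ corr_removed partitions the input."""
        kept, cvr, cor = set(self.kept), set(self.cv_removed), set(self.corr_removed)
        if kept & cvr or kept & cor or cvr & cor:
            raise ScreeningError("screening report groups are not disjoint")
        if kept | cvr | cor != set(input_codes):
            raise ScreeningError("screening report does not cover the input codes")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "cv": self.cv,
            "cv_removed": self.cv_removed,
            "corr_removed": self.corr_removed,
            "kept": self.kept,
            "n_districts": self.n_districts,
            "corr_matrix": self.corr_matrix.round(6).to_dict(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def correlation_prune(
    table: pd.DataFrame, threshold: float = 0.6
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Greedy collinearity pruning at Pearson |r| > *threshold*.

    Returns ``(reduced table, full correlation matrix, removed codes with
    the 1-based step at which each was dropped)``.  The final kept set
    satisfies max pairwise |r| ≤ threshold, which is asserted.
    """
    if len(table) < 2:
        raise ScreeningError("correlation pruning requires at least 2 districts")
    sds = table.std(ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ScreeningError(
            f"zero-variance columns {constant}: remove by CV screening first"
        )
    corr = table.corr(method="pearson")
    order = {c: i for i, c in enumerate(table.columns)}
    kept = list(table.columns)
    removed: dict[str, int] = {}
    step = 0
    while True:
        sub = corr.loc[kept, kept].abs()
        np.fill_diagonal(sub.values, 0.0)
        if len(kept) < 2 or float(sub.values.max()) <= threshold:
            break
        step += 1
        offenders = sub.index[(sub > threshold).any(axis=1)]
        # mean |r| of each offender against all other kept indicators
        mean_abs = sub.loc[offenders].sum(axis=1) / (len(kept) - 1)
        worst = mean_abs.max()
        tied = [c for c in offenders if mean_abs[c] == worst]
        drop = max(tied, key=order.__getitem__)  # later column on exact ties
        kept.remove(drop)
        removed[drop] = step
    final = corr.loc[kept, kept].abs().values.copy()
    np.fill_diagonal(final, 0.0)
    assert final.size == 0 or final.max() <= threshold + 1e-12
    return table[kept], corr, removed


# ---------------------------------------------------------------------------
# orchestrated stage-1 screen
# ---------------------------------------------------------------------------

def screen(
    table: pd.DataFrame,
    registry: IndicatorRegistry | None = None,
    cv_threshold: float = 0.1,
    corr_threshold: float = 0.6,
    missing: str = "drop",
) -> tuple[pd.DataFrame, ScreeningReport]:
    """Full stage-1 screen: missing-value policy → CV filter → correlation
    pruning.  Returns the reduced table and a :class:`ScreeningReport`."""
    validate_table(table, registry)
    clean = handle_missing(table, policy=missing)
    cvs = {c: coefficient_of_variation(clean[c]) for c in clean.columns}
    reduced, cv_removed = screen_by_cv(clean, cv_threshold)
    pruned, corr, corr_removed = correlation_prune(reduced, corr_threshold)
    report = ScreeningReport(
        cv=cvs,
        cv_removed=cv_removed,
        corr_matrix=corr,
        corr_removed=corr_removed,
        kept=list(pruned.columns),
        n_districts=len(clean),
    )
    report.check_partition(list(table.columns))
    return pruned, report
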