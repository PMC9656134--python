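"""Stepwise OLS refinement of the vulnerability index.

The refinement stage regresses registered infections on the candidate
indicators, Y = a0 + a1·x1 + … + ak·xk, selecting terms by bidirectional
stepwise search from the empty model: at each step the candidate with the
smallest p-value enters if p < ``alpha_enter``; then any included term
whose p-value has risen to ≥ ``alpha_remove`` is removed (largest first).
The selected indicator subset defines the refined index WO(pop), obtained
by re-running zero unitarization and the Perkal mean over exactly those
indicators.  Finally each selected attribute is related to the refined
index by a straight-line fit, reported in both directions
(attribute-on-index and index-on-attribute) with their shared r².

Fitting is delegated to :mod:`statsmodels`; this module owns the
selection policy, the refined index and the reporting contracts
(t = b/se, adjusted R², F).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .indexing import perkal_index, unitize_table
from .registry import IndicatorRegistry


class RegressionError(ValueError):
    """Raised on invalid regression inputs."""


# ---------------------------------------------------------------------------
# reporting contracts
# ---------------------------------------------------------------------------

def t_statistic(coefficient: float, standard_error: float) -> float:
    """Student t of one regression term: coefficient / standard error."""
    if standard_error <= 0:
        raise RegressionError("standard error must be positive")
    return coefficient / standard_error


def adjusted_r2(r2: float, n: int, k: int) -> float:
    """Adjusted R² = 1 − (1 − R²)(n − 1)/(n − k − 1) for k regressors."""
    if n <= k + 1:
        raise RegressionError("adjusted R² requires n > k + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# plain OLS
# ---------------------------------------------------------------------------

@dataclass
class OLSFit:
    """Least-squares fit summary (intercept term named ``const``)."""

    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    r2: float
    adj_r2: float
    f_stat: float
    df_model: int
    df_resid: int
    n: int

    @property
    def r(self) -> float:
        return float(np.sqrt(self.r2))

    @property
    def terms(self) -> list[str]:
        return [t for t in self.params.index if t != "const"]


def _check_rank(X: pd.DataFrame) -> None:
    mat = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # identify offending columns via pivoted QR: the columns not among
        # the first `rank` pivots are (numerically) linear combinations
        from scipy.linalg import qr

        _, _, piv = qr(mat, pivoting=True, mode="economic")
        names = ["const"] + list(X.columns)
        dependent = sorted(names[i] for i in piv[rank:])
        raise RegressionError(f"design matrix is rank deficient; collinear columns: {dependent}")


def ols(y: pd.Series, X: pd.DataFrame) -> OLSFit:
    """OLS of *y* on named columns *X* (intercept added automatically)."""
    y = pd.Series(y, dtype=float)
    X = pd.DataFrame(X).astype(float)
    n, k = len(y), X.shape[1]
    if n != len(X):
        raise RegressionError("y and X have different lengths")
    if n <= k + 1:
        raise RegressionError(f"n = {n} too small for {k} regressors")
    _check_rank(X)
    res = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    return OLSFit(
        params=res.params,
        bse=res.bse,
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        n=n,
    )


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseResult:
    """Outcome of bidirectional stepwise selection with its path trace."""

    y_name: str
    selected: list[str]  # in entry order, minus removed terms
    fit: OLSFit | None  # final refit; None when intercept-only
    alpha_enter: float
    alpha_remove: float
    n: int
    trace: list[dict] = field(default_factory=list)
    intercept_only: bool = False

    def coefficient_table(self, registry: IndicatorRegistry | None = None) -> pd.DataFrame:
        """Per-term coefficient/se/t/p table (plus registry tags if given)."""
        if self.fit is None:
            return pd.DataFrame(
                columns=["term", "coefficient", "se", "t", "p", "nature", "relations"]
            )
        rows = []
        for term in list(self.fit.params.index):
            row = {
                "term": term,
                "coefficient": self.fit.params[term],
                "se": self.fit.bse[term],
                "t": self.fit.tvalues[term],
                "p": self.fit.pvalues[term],
            }
            if registry is not None and term in registry:
                d = registry[term]
                row["nature"] = d.nature
                row["relations"] = "|".join(sorted(d.relations))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "y": self.y_name,
            "selected": self.selected,
            "alpha_enter": self.alpha_enter,
            "alpha_remove": self.alpha_remove,
            "n": self.n,
            "intercept_only": self.intercept_only,
            "trace": self.trace,
        }
        if self.fit is not None:
            payload["fit"] = {
                "coefficients": self.fit.params.to_dict(),
                "se": self.fit.bse.to_dict(),
                "t": self.fit.tvalues.to_dict(),
                "p": self.fit.pvalues.to_dict(),
                "r": self.fit.r,
                "r2": self.fit.r2,
                "adj_r2": self.fit.adj_r2,
                "f": self.fit.f_stat,
                "df": [self.fit.df_model, self.fit.df_resid],
            }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def stepwise_select(
    y: pd.Series,
    candidates: pd.DataFrame,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> StepwiseResult:
    """Bidirectional stepwise OLS selection from the empty model.

    Entry: the candidate with the smallest p-value in a fit alongside the
    current model enters if p < *alpha_enter* (ties broken by column
    order, earlier column preferred).  Removal: after each entry, included
    terms with p ≥ *alpha_remove* are dropped, largest p first.  The
    procedure is deterministic and terminates (revisited models stop the
    search).  The final model is refit and reported.
    """
    y = pd.Series(y, dtype=float)
    candidates = pd.DataFrame(candidates).astype(float)
    if (candidates.std(ddof=1) == 0).any():
        bad = candidates.columns[candidates.std(ddof=1) == 0].tolist()
        raise RegressionError(f"constant candidate columns {bad}: screen them first")
    order = {c: i for i, c in enumerate(candidates.columns)}
    included: list[str] = []
    trace: list[dict] = []
    seen: set[frozenset] = {frozenset()}
    step = 0
    while True:
        step += 1
        changed = False
        # -- entry scan
        best_code, best_p = None, np.inf
        for code in candidates.columns:
            if code in included:
                continue
            try:
                fit = ols(y, candidates[included + [code]])
            except RegressionError:
                continue  # candidate collinear with current model
            p = float(fit.pvalues[code])
            if p < best_p:
                best_code, best_p = code, p
        if best_code is not None and best_p < alpha_enter:
            included.append(best_code)
            trace.append({"step": step, "action": "add", "code": best_code, "p": best_p})
            changed = True
        # -- removal scan (largest p first)
        while included:
            fit = ols(y, candidates[included])
            pvals = fit.pvalues.drop("const")
            worst = pvals.idxmax()
            if float(pvals[worst]) >= alpha_remove:
                included.remove(worst)
                trace.append(
                    {"step": step, "action": "remove", "code": worst,
                     "p": float(pvals[worst])}
                )
                changed = True
            else:
                break
        if not changed:
            break
        state = frozenset(included)
        if state in seen:  # revisited model: entry/removal cycle
            break
        seen.add(state)
        if step > 4 * len(candidates.columns) + 8:  # safety net
            break

    if not included:
        return StepwiseResult(
            y_name=str(y.name or "Y"),
            selected=[],
            fit=None,
            alpha_enter=alpha_enter,
            alpha_remove=alpha_remove,
            n=len(y),
            trace=trace,
            intercept_only=True,
        )
    final = ols(y, candidates[sorted(included, key=order.__getitem__)])
    # keep entry order in `selected`
    return StepwiseResult(
        y_name=str(y.name or "Y"),
        selected=included,
        fit=final,
        alpha_enter=alpha_enter,
        alpha_remove=alpha_remove,
        n=len(y),
        trace=trace,
    )


# ---------------------------------------------------------------------------
# refined index and univariate relations
# ---------------------------------------------------------------------------

def refined_index(
    table: pd.DataFrame, selected: Sequence[str], registry: IndicatorRegistry
) -> pd.Series:
    """WO(pop): zero unitarization + Perkal mean over the selected codes."""
    selected = list(selected)
    if not selected:
        raise RegressionError("refined index requires a non-empty selection")
    missing = [c for c in selected if c not in table.columns]
    if missing:
        raise RegressionError(f"selected codes missing from table: {missing}")
    registry.resolve(selected)
    unitized = unitize_table(table[selected], registry)
    out = perkal_index(unitized, selected)
    out.name = "WO_pop"
    return out


@dataclass
class UnivariateFit:
    """Straight-line relation between one attribute and the refined index.

    Reported in both directions because slope interpretation depends on
    which variable is treated as response; r² is direction-free.
    """

    attribute: str
    #: attribute = b0 + b1 · index
    attr_on_index: tuple[float, float]
    #: index = b0 + b1 · attribute
    index_on_attr: tuple[float, float]
    r2: float


def univariate_relate(attribute: pd.Series, refined: pd.Series) -> UnivariateFit:
    """Fit the attribute–refined-index line in both directions."""
    x = pd.Series(attribute, dtype=float)
    y = pd.Series(refined, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise RegressionError("univariate relation requires equal length >= 3")
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        raise RegressionError("univariate relation is undefined for constant input")
    fwd = stats.linregress(y, x)  # attribute on index
    rev = stats.linregress(x, y)  # index on attribute
    return UnivariateFit(
        attribute=str(x.name or "attribute"),
        attr_on_index=(float(fwd.intercept), float(fwd.slope)),
        index_on_attr=(float(rev.intercept), float(rev.slope)),
        r2=float(fwd.rvalue**2),
    )
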