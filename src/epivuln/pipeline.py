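"""End-to-end orchestration of the vulnerability-index analysis.

:func:`run_pipeline` chains the stages on concrete inputs:

1. screen the raw indicator table (CV filter, correlation pruning);
2. unitize and aggregate into WO and the component indices;
3. delimit four vulnerability classes from WO;
4. correlate every index with cumulative cases at each snapshot;
5. stepwise-select indicators against cases at a chosen snapshot;
6. rebuild the refined index WO(pop) over the selected set, classify it,
   and fit the univariate attribute–index relations.

:func:`evaluate_recovery` repeats the generate → select → correlate cycle
over many seeds of a synthetic scenario and scores how well the selection
recovers the generator's informative indicators — the package's
power/validation experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import VulnerabilityClassification, classify as classify_index
from .correlate import IncidencePanel, correlation_series
from .indexing import SyntheticIndices, compute_all_indices
from .registry import IndicatorRegistry
from .regress import (
    RegressionError,
    StepwiseResult,
    UnivariateFit,
    refined_index,
    stepwise_select,
    univariate_relate,
)
from .screening import ScreeningReport, screen
from .simulate import SyntheticScenario, generate, scenario_registry


@dataclass
class PipelineResult:
    """Everything the analysis produces for one dataset."""

    screened_table: pd.DataFrame
    screening: ScreeningReport
    indices: SyntheticIndices
    classification: VulnerabilityClassification
    correlations: pd.DataFrame
    stepwise: StepwiseResult
    refined: pd.Series | None
    refined_classification: VulnerabilityClassification | None
    univariate: dict[str, UnivariateFit] = field(default_factory=dict)


def run_pipeline(
    table: pd.DataFrame,
    panel: IncidencePanel,
    registry: IndicatorRegistry,
    *,
    cv_threshold: float = 0.1,
    corr_threshold: float = 0.6,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    candidates: str = "all",
    y_snapshot=None,
    classify_on: str = "values",
) -> PipelineResult:
    """Run the full analysis on a raw indicator table and incidence panel.

    ``candidates`` chooses the stepwise candidate set: ``"all"`` (every
    indicator in the raw table, the default) or ``"screened"`` (the
    stage-1 survivors).  ``y_snapshot`` picks the dependent snapshot
    (default: the final one).
    """
    screened, report = screen(
        table, registry, cv_threshold=cv_threshold, corr_threshold=corr_threshold
    )
    indices = compute_all_indices(screened, registry)
    classification = classify_index(indices["WO"], method=classify_on)
    correlations = correlation_series(indices, panel)

    snapshot = pd.Timestamp(y_snapshot) if y_snapshot is not None else panel.dates[-1]
    if snapshot not in panel.dates:
        raise RegressionError(f"snapshot {snapshot.date()} not in incidence panel")
    cand_table = table if candidates == "all" else screened
    if candidates not in {"all", "screened"}:
        raise RegressionError(f"unknown candidate mode {candidates!r}")
    common = cand_table.index.intersection(panel.district_ids)
    y = panel.counts.loc[common, snapshot].astype(float)
    y.name = f"cases_{snapshot.date()}"
    result = stepwise_select(
        y,
        cand_table.loc[common],
        alpha_enter=alpha_enter,
        alpha_remove=alpha_remove,
    )

    refined = refined_cls = None
    univariate: dict[str, UnivariateFit] = {}
    if result.selected:
        refined = refined_index(table, result.selected, registry)
        refined_cls = classify_index(refined, method=classify_on)
        for code in result.selected:
            univariate[code] = univariate_relate(table[code], refined)

    return PipelineResult(
        screened_table=screened,
        screening=report,
        indices=indices,
        classification=classification,
        correlations=correlations,
        stepwise=result,
        refined=refined,
        refined_classification=refined_cls,
        univariate=univariate,
    )


@dataclass
class RecoveryOutcome:
    """Per-seed score of the selection-recovery experiment."""

    seed: int
    selected: list[str]
    informative_recovered: int
    spurious_selected: int
    wo_case_r: list[float]  # per snapshot, generator order
    inversions: int  # steps where |r| decreases

    @property
    def success(self) -> bool:
        """At least 9 of the 11 designed informative indicators recovered,
        with at most 2 spurious entries."""
        return self.informative_recovered >= 9 and self.spurious_selected <= 2


def _count_inversions(r_values: list[float]) -> int:
    mags = np.abs(np.asarray(r_values))
    return int(np.sum(np.diff(mags) < 0))


def evaluate_recovery(
    scenario: SyntheticScenario,
    seeds,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> list[RecoveryOutcome]:
    """Generate → stepwise-select → correlate for each seed; score recovery
    of the scenario's informative indicators and the temporal trend of the
    WO–cases correlation."""
    registry = scenario_registry(scenario)
    informative = set(scenario.informative_codes)
    outcomes = []
    for seed in seeds:
        table, panel, _ = generate(scenario.with_seed(int(seed)))
        y = panel.counts.iloc[:, -1].astype(float)
        y.name = "cases_final"
        result = stepwise_select(
            y, table, alpha_enter=alpha_enter, alpha_remove=alpha_remove
        )
        selected = set(result.selected)
        screened, _ = screen(table, registry)
        indices = compute_all_indices(screened, registry)
        corr = correlation_series(indices, panel)
        wo = corr[corr["index"] == "WO"].sort_values("date")["r"].tolist()
        outcomes.append(
            RecoveryOutcome(
                seed=int(seed),
                selected=result.selected,
                informative_recovered=len(selected & informative),
                spurious_selected=len(selected - informative),
                wo_case_r=wo,
                inversions=_count_inversions(wo),
            )
        )
    return outcomes
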