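"""Latent-factor synthetic data: district indicators and incidence panels.

The generator emulates the statistical structure the analysis pipeline
assumes, at the study's scale (314 rural districts, 33 mixed-orientation
indicators, 8 monthly cumulative-incidence snapshots), together with a
ground-truth record that enables recovery tests.

Model
-----
Each district *i* carries a latent vulnerability ``V_i ~ N(0, 1)``.
Indicator *j* is

    x_ij = m_j + s_j · (d_j · λ_j · V_i + sqrt(1 − λ_j²) · ε_ij)

with ``ε_ij ~ N(0, 1)`` and direction ``d_j = +1`` for destimulants,
``−1`` for stimulants: higher vulnerability raises destimulants and
lowers stimulants, so a *low* synthetic index WO means *high*
vulnerability.  λ_j ∈ [0, 1] is the loading; indicators with λ_j = 0 are
pure noise.  Two kinds of data defects are injected on top: collinear
copies (a target column rebuilt from a source column plus noise) and
quasi-constant columns (scale forced tiny, so the CV filter should drop
them).

New registered cases in period *t* are log-normal with a coupling to the
latent factor that strengthens over time,

    N_it = round(exp(α_t + β_t · V_i + σ_ε · η_it)),   η_it ~ N(0, 1)

and the panel reports the accumulated cumulative counts
``C_it = Σ_{u ≤ t} N_iu``, which are non-decreasing by construction.  A
linearly increasing β_t reproduces the empirical pattern of an epidemic
whose spatial footprint couples to socio-economic vulnerability more and
more strongly as it unfolds.

All randomness derives from ``scenario.master_seed``; the same scenario
generates bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .correlate import IncidencePanel
from .registry import IndicatorRegistry, load_packaged_registry


class ScenarioError(ValueError):
    """Raised when a synthetic scenario fails validation."""


#: Default snapshot dates: month-end samples spanning the first epidemic
#: wave (30 April – 30 November), eight snapshots ~30 days apart.
DEFAULT_DATES = [f"2020-{m:02d}-30" for m in range(4, 12)]

#: Indicators designated informative in the default scenario: the codes
#: retained by the refined 11-variable vulnerability model.
DEFAULT_INFORMATIVE = [
    "X1", "X5", "X8", "X13", "X14", "X15", "X16", "X18", "X21", "X28", "X29",
]

#: Plausible rural-district location/scale per indicator (raw units).
_DEFAULT_MOMENTS: dict[str, tuple[float, float]] = {
    "X1": (60.0, 35.0),
    "X2": (20.0, 2.5),
    "X3": (25.0, 5.0),
    "X4": (3500.0, 1200.0),
    "X5": (-1.0, 3.5),
    "X6": (0.2, 1.0),
    "X7": (8.0, 3.0),
    "X8": (3.4, 0.5),
    "X9": (0.9, 0.15),
    "X10": (6.0, 4.0),
    "X11": (620.0, 90.0),
    "X12": (1.2, 1.1),
    "X13": (8.0, 4.0),
    "X14": (2.5, 1.6),
    "X15": (15.0, 7.0),
    "X16": (120.0, 60.0),
    "X17": (350.0, 180.0),
    "X18": (2800.0, 1100.0),
    "X19": (40.0, 60.0),
    "X20": (2400.0, 700.0),
    "X21": (950.0, 300.0),
    "X22": (28.0, 4.0),
    "X23": (400.0, 160.0),
    "X24": (1.5, 1.0),
    "X25": (85.0, 20.0),
    "X26": (3600.0, 900.0),
    "X27": (12.0, 5.0),
    "X28": (4.5, 2.2),
    "X29": (780.0, 160.0),
    "X30": (14.0, 4.0),
    "X31": (35.0, 8.0),
    "X32": (900.0, 500.0),
    "X33": (38.0, 9.0),
}


@dataclass(frozen=True)
class IndicatorSpec:
    """Generator parameters for one indicator column."""

    code: str
    orientation: str
    nature: str
    relations: tuple[str, ...]
    location: float
    scale: float
    loading: float = 0.0


@dataclass(frozen=True)
class CollinearSpec:
    """Rebuild *target* from *source* (affine match of target moments)
    plus Gaussian noise of sd ``noise_frac`` × target scale."""

    target: str
    source: str
    noise_frac: float = 0.2


@dataclass
class SyntheticScenario:
    """Full description of one synthetic study."""

    n_districts: int
    dates: list[str]
    indicators: list[IndicatorSpec]
    alpha: list[float]  # per-snapshot log baseline of new cases
    beta: list[float]  # per-snapshot coupling of new cases to V
    sigma_eps: float  # per-snapshot log-normal dispersion
    collinear: list[CollinearSpec] = field(default_factory=list)
    quasi_constant: list[str] = field(default_factory=list)
    master_seed: int = 0

    def __post_init__(self) -> None:
        codes = [s.code for s in self.indicators]
        if len(set(codes)) != len(codes):
            raise ScenarioError("duplicate indicator codes in scenario")
        for s in self.indicators:
            if not 0.0 <= s.loading <= 1.0:
                raise ScenarioError(f"{s.code}: loading must lie in [0, 1]")
            if s.scale <= 0:
                raise ScenarioError(f"{s.code}: scale must be positive")
        if len(self.alpha) != len(self.dates) or len(self.beta) != len(self.dates):
            raise ScenarioError("alpha and beta must have one value per snapshot")
        if self.sigma_eps < 0:
            raise ScenarioError("sigma_eps must be non-negative")
        known = set(codes)
        for c in self.collinear:
            if c.target not in known or c.source not in known:
                raise ScenarioError(f"collinear spec refers to unknown code: {c}")
        for q in self.quasi_constant:
            if q not in known:
                raise ScenarioError(f"quasi-constant code {q!r} unknown")

    @property
    def codes(self) -> list[str]:
        return [s.code for s in self.indicators]

    @property
    def informative_codes(self) -> list[str]:
        return [s.code for s in self.indicators if s.loading > 0]

    def with_seed(self, master_seed: int) -> "SyntheticScenario":
        return replace(self, master_seed=int(master_seed))

    # -- YAML round trip ----------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = asdict(self)
        payload["indicators"] = [asdict(s) | {"relations": list(s.relations)}
                                 for s in self.indicators]
        payload["collinear"] = [asdict(c) for c in self.collinear]
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SyntheticScenario":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        payload = yaml.safe_load(text)
        payload["indicators"] = [
            IndicatorSpec(**(d | {"relations": tuple(d["relations"])}))
            for d in payload["indicators"]
        ]
        payload["collinear"] = [CollinearSpec(**d) for d in payload.get("collinear", [])]
        return cls(**payload)


@dataclass
class GroundTruth:
    """What the generator actually did — never consumed by the pipeline."""

    latent: pd.Series  # V_i per district
    loadings: dict[str, float]
    informative: list[str]
    alpha: list[float]
    beta: list[float]
    sigma_eps: float

    def to_json(self, path: str | Path) -> None:
        import json

        Path(path).write_text(
            json.dumps(
                {
                    "latent": self.latent.round(9).to_dict(),
                    "loadings": self.loadings,
                    "informative": self.informative,
                    "alpha": self.alpha,
                    "beta": self.beta,
                    "sigma_eps": self.sigma_eps,
                },
                indent=2,
            )
        )


def default_scenario(master_seed: int = 0) -> SyntheticScenario:
    """The reference study conditions: 314 districts, the packaged
    33-indicator registry, 11 informative indicators at λ = 0.7, two
    collinear and two quasi-constant injections, and eight snapshots with
    coupling β_t rising linearly from 0.1 to 1.0."""
    registry = load_packaged_registry()
    informative = set(DEFAULT_INFORMATIVE)
    indicators = [
        IndicatorSpec(
            code=d.code,
            orientation=d.orientation,
            nature=d.nature,
            relations=tuple(sorted(d.relations)),
            location=_DEFAULT_MOMENTS[d.code][0],
            scale=_DEFAULT_MOMENTS[d.code][1],
            loading=0.7 if d.code in informative else 0.0,
        )
        for d in registry
    ]
    n_snap = len(DEFAULT_DATES)
    return SyntheticScenario(
        n_districts=314,
        dates=list(DEFAULT_DATES),
        indicators=indicators,
        # first-wave profile: per-period new cases spike early then settle
        # on a low plateau, so cumulative counts integrate every coupling
        # phase instead of being dominated by the strongly coupled tail
        alpha=[6.6, 5.6, 4.6, 3.6, 2.4, 2.4, 2.4, 2.4],
        beta=[round(float(b), 6) for b in np.linspace(0.1, 1.0, n_snap)],
        sigma_eps=0.105,
        collinear=[
            CollinearSpec(target="X3", source="X2", noise_frac=0.2),
            CollinearSpec(target="X31", source="X10", noise_frac=0.2),
        ],
        quasi_constant=["X30", "X33"],
        master_seed=master_seed,
    )


def scenario_registry(scenario: SyntheticScenario) -> IndicatorRegistry:
    """Build a registry matching the scenario's indicator metadata."""
    from .registry import IndicatorDefinition

    return IndicatorRegistry(
        [
            IndicatorDefinition(
                code=s.code,
                label=s.code,
                orientation=s.orientation,
                nature=s.nature,
                relations=frozenset(s.relations),
            )
            for s in scenario.indicators
        ]
    )


_QUASI_SCALE_FRAC = 0.002  # forced scale of quasi-constant columns


def generate(
    scenario: SyntheticScenario,
) -> tuple[pd.DataFrame, IncidencePanel, GroundTruth]:
    """Draw one synthetic dataset from *scenario*.

    Returns the raw indicator table (districts × codes), the cumulative
    incidence panel, and the ground truth.  Deterministic in
    ``scenario.master_seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(scenario.master_seed))
    n = scenario.n_districts
    district_ids = pd.Index([f"D{i:03d}" for i in range(1, n + 1)], name="district_id")
    v = rng.standard_normal(n)

    quasi = set(scenario.quasi_constant)
    columns: dict[str, np.ndarray] = {}
    for s in scenario.indicators:
        d = 1.0 if s.orientation == "destimulant" else -1.0
        z = d * s.loading * v + np.sqrt(1.0 - s.loading**2) * rng.standard_normal(n)
        scale = s.scale
        if s.code in quasi:
            scale = max(_QUASI_SCALE_FRAC * abs(s.location), 1e-3)
        columns[s.code] = s.location + scale * z

    by_code = {s.code: s for s in scenario.indicators}
    for c in scenario.collinear:
        src, tgt = by_code[c.source], by_code[c.target]
        standardized = (columns[c.source] - src.location) / src.scale
        noise = c.noise_frac * rng.standard_normal(n)
        columns[c.target] = tgt.location + tgt.scale * (standardized + noise)

    table = pd.DataFrame(columns, index=district_ids)

    alpha = np.asarray(scenario.alpha, dtype=float)
    beta = np.asarray(scenario.beta, dtype=float)
    eta = rng.standard_normal((n, len(alpha)))
    log_new = alpha[None, :] + beta[None, :] * v[:, None] + scenario.sigma_eps * eta
    new_cases = np.round(np.exp(log_new))
    cumulative = np.cumsum(new_cases, axis=1).astype(int)
    panel = IncidencePanel(
        pd.DataFrame(
            cumulative, index=district_ids, columns=pd.to_datetime(scenario.dates)
        )
    )

    truth = GroundTruth(
        latent=pd.Series(v, index=district_ids, name="V"),
        loadings={s.code: s.loading for s in scenario.indicators},
        informative=scenario.informative_codes,
        alpha=list(scenario.alpha),
        beta=list(scenario.beta),
        sigma_eps=scenario.sigma_eps,
    )
    return table, panel, truth
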