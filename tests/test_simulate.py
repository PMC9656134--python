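import dataclasses

import numpy as np
import pandas as pd
import pytest

from epivuln.correlate import correlation_series
from epivuln.indexing import compute_all_indices
from epivuln.registry import load_packaged_registry
from epivuln.screening import screen
from epivuln.simulate import (
    CollinearSpec,
    IndicatorSpec,
    ScenarioError,
    SyntheticScenario,
    default_scenario,
    generate,
    scenario_registry,
)


def small_scenario(
    n=300,
    loading=0.0,
    orientation="destimulant",
    n_ind=8,
    seed=11,
    beta=(0.3, 0.6, 0.9),
):
    indicators = [
        IndicatorSpec(
            code=f"K{i}",
            orientation=orientation,
            nature="D",
            relations=("intended",),
            location=10.0,
            scale=3.0,
            loading=loading,
        )
        for i in range(1, n_ind + 1)
    ]
    dates = [f"2020-0{m}-28" for m in range(4, 4 + len(beta))]
    return SyntheticScenario(
        n_districts=n,
        dates=dates,
        indicators=indicators,
        alpha=[3.0] * len(beta),
        beta=list(beta),
        sigma_eps=0.3,
        master_seed=seed,
    )


class TestDefaultScenario:
    def test_shapes_match_study_design(self):
        scenario = default_scenario()
        table, panel, truth = generate(scenario)
        assert table.shape == (314, 33)
        assert panel.counts.shape == (314, 8)
        assert len(truth.informative) == 11

    def test_indicator_metadata_matches_packaged_registry(self):
        scenario = default_scenario()
        registry = load_packaged_registry()
        for spec in scenario.indicators:
            definition = registry[spec.code]
            assert spec.orientation == definition.orientation
            assert spec.nature == definition.nature
            assert frozenset(spec.relations) == definition.relations

    def test_screening_removes_injected_defects(self):
        scenario = default_scenario(master_seed=5)
        table, _, _ = generate(scenario)
        _, report = screen(table, load_packaged_registry())
        assert set(scenario.quasi_constant) <= set(report.cv_removed)
        for pair in scenario.collinear:
            assert {pair.target, pair.source} & set(report.corr_removed)

    def test_coupling_ramp_is_non_decreasing(self):
        scenario = default_scenario()
        assert (np.diff(scenario.beta) >= 0).all()


class TestGenerate:
    def test_same_seed_bit_identical(self):
        scenario = default_scenario(master_seed=9)
        t1, p1, g1 = generate(scenario)
        t2, p2, g2 = generate(scenario)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(p1.counts, p2.counts)
        pd.testing.assert_series_equal(g1.latent, g2.latent)

    def test_different_seeds_differ(self):
        t1, _, _ = generate(default_scenario(master_seed=1))
        t2, _, _ = generate(default_scenario(master_seed=2))
        assert not t1.equals(t2)

    def test_panels_are_cumulative_for_many_seeds(self):
        for seed in range(5):
            _, panel, _ = generate(default_scenario(master_seed=seed))
            diffs = panel.counts.diff(axis=1).iloc[:, 1:]
            assert (diffs.to_numpy() >= 0).all()

    def test_null_loadings_leave_wo_uncorrelated_with_latent(self):
        scenario = small_scenario(loading=0.0)
        table, _, truth = generate(scenario)
        registry = scenario_registry(scenario)
        screened, _ = screen(table, registry)
        wo = compute_all_indices(screened, registry)["WO"]
        assert abs(np.corrcoef(wo, truth.latent)[0, 1]) < 0.15

    def test_loaded_destimulants_give_negative_case_correlation(self):
        scenario = small_scenario(loading=0.9)
        table, panel, _ = generate(scenario)
        registry = scenario_registry(scenario)
        screened, _ = screen(table, registry)
        indices = compute_all_indices(screened, registry)
        series = correlation_series(indices, panel)
        assert (series.loc[series["index"] == "WO", "r"] < 0).all()

    def test_stimulant_orientation_flips_indicator_latent_sign(self):
        dest = small_scenario(loading=0.8)
        stim = dataclasses.replace(
            dest,
            indicators=[
                dataclasses.replace(s, orientation="stimulant") for s in dest.indicators
            ],
        )
        t_dest, _, g = generate(dest)
        t_stim, _, _ = generate(stim)
        r_dest = np.corrcoef(t_dest["K1"], g.latent)[0, 1]
        r_stim = np.corrcoef(t_stim["K1"], g.latent)[0, 1]
        assert r_dest > 0.5 and r_stim < -0.5

    def test_collinear_injection_produces_strong_pair(self):
        scenario = dataclasses.replace(
            small_scenario(loading=0.0),
            collinear=[CollinearSpec(target="K2", source="K1", noise_frac=0.2)],
        )
        table, _, _ = generate(scenario)
        assert abs(np.corrcoef(table["K1"], table["K2"])[0, 1]) > 0.9


class TestScenarioValidation:
    def test_loading_out_of_bounds_rejected(self):
        with pytest.raises(ScenarioError, match="loading"):
            small_scenario(loading=1.2)

    def test_nonpositive_scale_rejected(self):
        base = small_scenario()
        bad = [dataclasses.replace(s, scale=0.0) for s in base.indicators]
        with pytest.raises(ScenarioError, match="scale"):
            dataclasses.replace(base, indicators=bad)

    def test_snapshot_parameter_length_mismatch_rejected(self):
        with pytest.raises(ScenarioError, match="per snapshot"):
            dataclasses.replace(small_scenario(), alpha=[1.0, 2.0])

    def test_unknown_collinear_code_rejected(self):
        with pytest.raises(ScenarioError, match="unknown"):
            dataclasses.replace(
                small_scenario(),
                collinear=[CollinearSpec(target="Z9", source="K1")],
            )

    def test_yaml_round_trip(self, tmp_path):
        scenario = default_scenario(master_seed=3)
        path = tmp_path / "scenario.yaml"
        scenario.to_yaml(path)
        loaded = SyntheticScenario.from_yaml(path)
        assert loaded == scenario
        # and the round-tripped scenario generates identical data
        pd.testing.assert_frame_equal(generate(loaded)[0], generate(scenario)[0])
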