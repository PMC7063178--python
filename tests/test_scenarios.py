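import numpy as np
import pytest

from ersim.inputs import InputPolicy
from ersim.patterns import PatternConstraint, PatternTable
from ersim.scenarios import (
    CASES,
    CONDITIONS,
    CalibrationSpec,
    Scenario,
    ScenarioConfigError,
    build_scenario,
    calibrate,
    classify_verdict,
    flux_drop_time,
    load_default_battery,
    load_default_model,
    mean_upr_ratio,
    run_scenario,
    run_thought_experiment,
    scenario_names,
    verdict_mismatches,
)
from ersim.simulate import SimulationConfig, SimulationResult


def synthetic_result(**readouts):
    times = np.linspace(0.0, 10.0, 11)
    return SimulationResult(
        times=times,
        states={},
        inputs={},
        readouts={k: np.full(11, v) for k, v in readouts.items()},
    )


class TestScenarioInvariants:
    def test_ncd_requires_zero_stress_drive(self):
        with pytest.raises(ScenarioConfigError, match="NCD"):
            Scenario(
                name="NCD",
                input_policy=InputPolicy(modes={"u1": "steady_state_amplified"}),
            )

    def test_dio_requires_equilibrium_drive(self):
        with pytest.raises(ScenarioConfigError, match="DIO"):
            Scenario(name="DIO", input_policy=InputPolicy(modes={"u1": "zero"}))

    def test_thought_experiment_needs_two_loops(self):
        with pytest.raises(ScenarioConfigError, match="two loops"):
            Scenario(
                name="case_I_i",
                input_policy=InputPolicy(modes={"u1": "controller"}),
                loops=[],
            )

    def test_scenario_names_cover_battery(self):
        names = scenario_names()
        assert names[:2] == ["NCD", "DIO"]
        assert len(names) == 14


class TestBuildScenario:
    def test_unknown_scenario_rejected(self, default_model, default_battery):
        with pytest.raises(ScenarioConfigError, match="unknown scenario"):
            build_scenario(default_model, default_battery, "case_IV_i")

    def test_missing_reference_rejected(self, default_model, default_battery):
        battery = default_battery.copy()
        battery.references.pop("IRpY")
        with pytest.raises(ScenarioConfigError, match="IRpY"):
            build_scenario(default_model, battery, "case_I_i")

    def test_condition_grid_wiring(self, default_model, default_battery):
        sc = build_scenario(default_model, default_battery, "case_II_iii")
        assert [l.controlled_readout for l in sc.loops] == ["pPERK", "IRSpY"]
        assert [l.actuated_input for l in sc.loops] == ["u1", "u2"]
        refs = default_battery.references
        assert sc.loops[0].controller.reference == refs["pPERK"]["low"]
        assert sc.loops[1].controller.reference == refs["IRSpY"]["high"]
        # shipped gains
        assert sc.loops[0].controller.ki == pytest.approx(0.0691)
        assert sc.loops[1].controller.kp == pytest.approx(0.2134)
        assert sc.loops[1].controller.kd == pytest.approx(-0.1082)

    def test_controller_preloads_resolved(self, default_model, default_battery):
        from ersim.inputs import derive_u1, derive_u2

        sc = build_scenario(default_model, default_battery, "case_I_i")
        init = default_model.initial_state()
        assert sc.loops[0].controller.initial_output == pytest.approx(
            derive_u1(init, default_model.parameters)
        )
        assert sc.loops[1].controller.initial_output == pytest.approx(
            derive_u2(init, default_model.parameters)
        )


class TestRunScenario:
    def test_unknown_pattern_readout_is_config_error(self, eq1_pair):
        scenario = Scenario(
            name="NCD", input_policy=InputPolicy(modes={"u1": "zero"})
        )
        table = PatternTable(
            [PatternConstraint("bad", "missing_readout", "NCD", "DIO", "greater")]
        )
        config = SimulationConfig(t_span=(0.0, 1.0), n_points=3)
        with pytest.raises(ScenarioConfigError, match="missing_readout"):
            run_scenario(eq1_pair, scenario, config, patterns=table)

    def test_pattern_annotation_with_companions(
        self, battery_outcome, default_model, default_battery, pattern_table
    ):
        scenario = build_scenario(default_model, default_battery, "DIO")
        result = run_scenario(
            default_model,
            scenario,
            default_battery.sim_config(),
            patterns=pattern_table,
            companion_results={"NCD": battery_outcome.results["NCD"]},
        )
        assert len(result.pattern_verdicts) == 12
        assert all(result.pattern_verdicts.values())

    def test_zeroed_model_completes_and_fails_all_patterns(
        self, default_model, default_battery, pattern_table
    ):
        """Degenerate model: nothing moves, so every strict ordering ties."""
        params = default_model.parameters.copy()
        for name in params.rate_constants:
            params.rate_constants[name] = 0.0
        params.rate_constants["k1"] = 1.0  # keep input derivations defined
        params.rate_constants["k53"] = 1.0
        dead = default_model.with_parameters(params)
        config = default_battery.sim_config(n_points=21)
        results = {
            name: run_scenario(dead, build_scenario(dead, default_battery, name), config)
            for name in ("NCD", "DIO")
        }
        from ersim.patterns import check_qualitative_patterns

        report = check_qualitative_patterns(results, pattern_table)
        assert report.score == 0.0


class TestVerdicts:
    THRESHOLDS = {
        "insulin_sensitivity": 2.0,
        "upl_flux": 0.05,
        "upr_ratio": 0.6,
    }

    def test_classification_against_thresholds(self):
        result = synthetic_result(
            insulin_sensitivity=4.7,
            upl_flux=0.09,
            pPERK_ratio=0.8,
            pIRE1a_ratio=0.8,
            peIF2a_ratio=0.8,
        )
        verdict, values = classify_verdict(result, self.THRESHOLDS)
        assert verdict["er_stress"] == "high"
        assert verdict["insulin_sensitivity"] == "high"
        assert set(verdict["upr_ratios"].values()) == {"high"}
        assert values["insulin_sensitivity"] == pytest.approx(4.7)

    def test_mismatch_reporting(self):
        result = synthetic_result(
            insulin_sensitivity=1.0,
            upl_flux=0.01,
            pPERK_ratio=0.5,
            pIRE1a_ratio=0.5,
            peIF2a_ratio=0.5,
        )
        verdict, _ = classify_verdict(result, self.THRESHOLDS)
        expected = {
            "er_stress": "low",
            "insulin_sensitivity": "high",
            "upr_ratios": "low",
        }
        assert verdict_mismatches(verdict, expected) == ["insulin_sensitivity"]

    def test_run_thought_experiment_validates_labels(self, default_model):
        with pytest.raises(ScenarioConfigError, match="case"):
            run_thought_experiment(default_model, "IV", "i")
        with pytest.raises(ScenarioConfigError, match="condition"):
            run_thought_experiment(default_model, "I", "v")


class TestDerivedMeasurements:
    def test_flux_drop_time_basic(self):
        times = np.linspace(0.0, 100.0, 11)
        flux = np.array([10.0, 5.0, 1.0, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05])
        result = SimulationResult(
            times=times, states={}, inputs={}, readouts={"upl_flux": flux}
        )
        assert flux_drop_time(result) == pytest.approx(30.0)

    def test_flux_never_dropping_is_inf(self):
        times = np.linspace(0.0, 10.0, 5)
        result = SimulationResult(
            times=times, states={}, inputs={},
            readouts={"upl_flux": np.full(5, 2.0)},
        )
        assert flux_drop_time(result) == np.inf

    def test_flux_rebound_counts_last_crossing(self):
        times = np.linspace(0.0, 40.0, 5)
        flux = np.array([10.0, 0.01, 5.0, 0.01, 0.01])
        result = SimulationResult(
            times=times, states={}, inputs={}, readouts={"upl_flux": flux}
        )
        assert flux_drop_time(result) == pytest.approx(30.0)

    def test_mean_upr_ratio(self):
        result = synthetic_result(
            pPERK_ratio=0.7, pIRE1a_ratio=0.8, peIF2a_ratio=0.9
        )
        assert mean_upr_ratio(result) == pytest.approx(0.8)


class TestCalibrate:
    def test_empty_patterns_returns_first_sample(self, default_model):
        battery = load_default_battery(calibrated=False)
        spec = CalibrationSpec(
            free_parameters={"amplify1": (1.0, 2.0)}, seed=5, anchors={}
        )
        a = calibrate(default_model, spec, PatternTable([]), battery)
        b = calibrate(default_model, spec, PatternTable([]), battery)
        assert a.success
        assert a.assignment == b.assignment
        assert 1.0 <= a.assignment["amplify1"] <= 2.0
        expected = float(np.random.default_rng(5).uniform(1.0, 2.0))
        assert a.assignment["amplify1"] == expected

    def test_unsatisfiable_patterns_yield_failure_report(self, default_model):
        battery = load_default_battery()  # calibrated thresholds available
        contradictory = PatternTable(
            [
                PatternConstraint("up", "pJNK", "DIO", "NCD", "greater"),
                PatternConstraint("down", "pJNK", "DIO", "NCD", "less"),
            ]
        )
        spec = CalibrationSpec(
            free_parameters={"amplify1": (6.0, 8.0)},
            seed=3,
            max_trials=0,
            anchors={},
        )
        result = calibrate(default_model, spec, contradictory, battery)
        assert not result.success
        assert result.failure_report is not None
        violated = result.failure_report["most_violated_patterns"]
        assert "down" in violated or "up" in violated
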