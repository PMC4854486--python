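"""Engine: integration, events, steady states, scenarios, export."""

import numpy as np
import pandas as pd
import pytest

import betacell as bc
from betacell import model
from betacell.engine import Event, ScenarioConfig, export_trajectory
from betacell.scenarios import list_scenarios, preset_scenario


class TestAssembly:
    def test_basal_initials_near_fixed_point(self, params):
        """Integrating 1000 s from the tabulated initials at low glucose
        changes every state by only a few percent (rest protocol)."""
        cfg = ScenarioConfig(duration=1000.0, sample_dt=1000.0,
                            steady_state_first=False)
        traj = bc.integrate(cfg, params)
        x0 = model.table_initial_state(params)
        x1 = traj.final_state()
        for name in ("ATD", "Vp", "Cac", "CaER", "cAMP", "PIP2", "P4P"):
            i = model.STATE_INDEX[name]
            assert x1[i] == pytest.approx(x0[i], rel=0.35), name

    def test_zero_rates_give_zero_cascade_derivatives(self, params):
        zero_rates = {f"R{i}{j}": 0.0 for i in (1, 2, 3, 6, 7)
                      for j in range(1, 10)}
        zero_rates.update({f"R{i}2r": 0.0 for i in (1, 2, 3, 6, 7)})
        p = params.with_overrides(zero_rates)
        x = model.table_initial_state(p)
        dy = model.assemble_derivatives(0.0, x, model.default_inputs(p), p)
        for spec_states in (("LR1", "LRG1", "ReGLd", "GaT1", "GaD1", "ACGLP"),
                            ("RG6", "LRG6", "ReM3d", "GaT6", "GaD6", "PLCM3")):
            for name in spec_states:
                assert dy[model.STATE_INDEX[name]] == 0.0

    def test_shared_pool_coupling_is_instantaneous(self, params):
        x = model.table_initial_state(params)
        d = model.derived_quantities(x, model.default_inputs(params), params)
        x2 = x.copy()
        x2[model.STATE_INDEX["ACAR"]] += 1.0
        d2 = model.derived_quantities(x2, model.default_inputs(params), params)
        assert d2["AC_pf"] == pytest.approx(d["AC_pf"] - 1.0)


class TestSteadyState:
    def test_residual_definition(self, params, basal_ss):
        dy = model.assemble_derivatives(0.0, basal_ss.state,
                                        basal_ss.inputs, params)
        assert np.max(np.abs(dy)) < 1e-6

    def test_monotone_glucose_response_of_atd(self, params):
        values = []
        state = None
        for glu in (2000.0, 4000.0, 6000.0):
            ss = bc.find_steady_state(params, {"Glu": glu}, from_state=state)
            state = ss.state
            values.append(ss["ATD"])
        assert values[0] < values[1] < values[2]

    def test_solver_tolerance_robustness(self, params, basal_ss):
        """Halving tolerances moves reported steady values by < 0.1%."""
        tight = bc.find_steady_state(params, {"Glu": 3000.0},
                                     from_state=basal_ss.state, rtol=5e-9)
        for name in ("Vp", "Cac", "cAMP", "CaER", "PIP2"):
            assert tight[name] == pytest.approx(basal_ss[name], rel=1e-3)


class TestEventsAndScenarios:
    def test_empty_schedule_stays_at_rest(self, params):
        cfg = ScenarioConfig(duration=500.0, sample_dt=50.0)
        traj = bc.integrate(cfg, params)
        for name in ("Vp", "Cac", "cAMP"):
            series = traj[name]
            assert np.ptp(series) <= 1e-3 * max(1.0, abs(series[0]))

    def test_event_changes_input_at_breakpoint(self, params):
        cfg = ScenarioConfig(duration=400.0, sample_dt=10.0,
                             events=[Event(200.0, "Glu", 8000.0)])
        traj = bc.integrate(cfg, params)
        atd = traj["ATD"]
        pre = atd[traj.time <= 200.0]
        assert np.ptp(pre) < 1e-3
        assert atd[-1] > atd[0] + 1.0  # rising toward the 8 mM target

    def test_parameter_event(self, params):
        cfg = ScenarioConfig(duration=200.0, sample_dt=20.0,
                             events=[Event(100.0, "g_mKATP", 9000.0)])
        traj = bc.integrate(cfg, params)
        i_pre = traj.value_at("I_KATP", 90.0)
        i_post = traj.value_at("I_KATP", 110.0)
        assert abs(i_post) < abs(i_pre)

    def test_event_validation(self):
        cfg = ScenarioConfig(duration=100.0,
                             events=[Event(50.0, "Glu", 1.0),
                                     Event(50.0, "FFA", 1.0)])
        with pytest.raises(ValueError, match="strictly increasing"):
            cfg.validate()
        with pytest.raises(ValueError, match="duration"):
            ScenarioConfig(duration=-1.0).validate()

    def test_unknown_scenario_lists_presets(self):
        with pytest.raises(KeyError, match="fig3"):
            preset_scenario("nonsense")

    def test_preset_catalog(self):
        names = list_scenarios()
        assert {"fig3", "fig4", "fig9", "fig12", "glp1r_halved",
                "mr_tenfold_down"} <= set(names)
        cfg = preset_scenario("fig9")
        assert cfg.overrides["g_mNM3"] == 35000.0
        assert cfg.events[0].target == "AM3"
        assert cfg.events[0].value == pytest.approx(2.2)


class TestExport:
    def test_csv_round_trip(self, params, tmp_path):
        cfg = ScenarioConfig(duration=100.0, sample_dt=20.0,
                             events=[Event(50.0, "Glu", 8000.0)])
        traj = bc.integrate(cfg, params)
        out = tmp_path / "traj.csv"
        export_trajectory(traj, out, "csv")
        df = pd.read_csv(out)
        assert list(df.columns) == (["time"] + list(model.STATE_NAMES)
                                    + list(model.DERIVED_NAMES))
        np.testing.assert_allclose(df["Vp"].to_numpy(), traj["Vp"],
                                   rtol=0, atol=1e-12)

    def test_json_includes_events(self, params, tmp_path):
        import json
        cfg = ScenarioConfig(duration=60.0, sample_dt=20.0,
                             events=[Event(30.0, "GLP1", 6.2e-4)])
        traj = bc.integrate(cfg, params)
        out = tmp_path / "traj.json"
        export_trajectory(traj, out, "json")
        payload = json.loads(out.read_text())
        assert payload["events"] == [[30.0, "GLP1", 6.2e-4]]
        assert len(payload["rows"]) == len(traj.time)

    def test_unknown_format(self, params, tmp_path):
        cfg = ScenarioConfig(duration=30.0, sample_dt=10.0)
        traj = bc.integrate(cfg, params)
        with pytest.raises(ValueError, match="format"):
            export_trajectory(traj, tmp_path / "x", "parquet")


def test_conservation_closures_along_trajectory(params):
    """Receptor, G-protein, enzyme-pool and calmodulin totals hold at every
    sample of a stimulated trajectory (algebraic closure, so any drift in
    the bound species would surface here)."""
    cfg = ScenarioConfig(duration=600.0, sample_dt=50.0,
                         events=[Event(100.0, "GLP1", 6.2e-4),
                                 Event(300.0, "AM3", 2.2)])
    traj = bc.integrate(cfg, params)  # integrate() checks closures per sample
    s = traj.states
    bound_r1 = s["ReGLd"] + s["LR1"] + s["LRG1"]
    assert (bound_r1 <= params.Re_GLt + 1e-9).all()
    bound_g6 = s["RG6"] + s["LRG6"] + s["GaT6"] + s["GaD6"] + s["PLCM3"]
    assert (bound_g6 <= params.G6t + 1e-9).all()
    assert ((s[["ACGLP", "ACGIP", "ACAR"]].sum(axis=1))
            <= params.AC_pt + 1e-9).all()
    assert (s.drop(columns="Vp") >= -1e-9).all().all()
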