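import numpy as np
import pytest

import coregflux as cf
from coregflux.dfba import DFBAScenario, Phase, run_scenario, step


@pytest.fixture(scope="module")
def phase_models():
    """Diauxic toy constrained for the glucose and ethanol phases."""
    model = cf.make_toy_model("diauxic")
    acts = cf.diauxic_phase_activities()
    _, m_glc = cf.simulate(model, 0.0, predicted_expression=acts["glucose"],
                           return_model=True)
    _, m_eth = cf.simulate(model, 0.0, predicted_expression=acts["ethanol"],
                           return_model=True)
    return model, m_glc, m_eth


def diauxic_scenario(m_glc, m_eth, dt=0.02, max_time=24.0, glc0=5.0):
    return DFBAScenario(
        phases=[Phase(m_glc, "glucose", switch_metabolite="EX_glc",
                      switch_threshold=1e-6),
                Phase(m_eth, "ethanol")],
        initial_biomass=0.05,
        initial_concentrations={"EX_glc": glc0, "EX_eth": 0.0},
        vmax={"EX_glc": 1.0, "EX_eth": 0.5},
        dt=dt, max_time=max_time,
    )


class TestStep:
    def test_zero_growth_leaves_state_unchanged(self, chain_model):
        closed = chain_model.with_bounds({"UPTAKE": (0.0, 0.0)})
        mu, X, conc, _, infeasible = step(0.5, {}, closed, 0.01)
        assert mu == pytest.approx(0.0, abs=1e-9)
        assert X == pytest.approx(0.5)
        assert not infeasible

    def test_constant_mu_matches_discrete_and_exponential_forms(self, chain_model):
        # chain toy grows at mu = 10 (uptake bound) regardless of state
        dt, k, X0 = 1e-3, 100, 0.05
        X = X0
        for _ in range(k):
            mu, X, _, _, _ = step(X, {}, chain_model, dt)
            assert mu == pytest.approx(10.0, abs=1e-9)
        assert X == pytest.approx(X0 * (1 + mu * dt) ** k, rel=1e-9)
        assert X == pytest.approx(X0 * np.exp(mu * k * dt), rel=0.01)

    def test_uptake_cannot_overdraw_concentration(self, phase_models):
        model, _, _ = phase_models
        X, dt, conc = 1.0, 0.1, {"EX_glc": 0.01, "EX_eth": 0.0}
        mu, X2, conc2, exch, _ = step(X, conc, model, dt,
                                      vmax={"EX_glc": 1.0, "EX_eth": 0.5})
        # cap = C/(X dt) = 0.1 -> at most 0.01 mmol consumed this step
        assert exch["EX_glc"] >= -0.1 - 1e-9
        assert conc2["EX_glc"] >= 0.0

    def test_infeasible_lp_flags_and_freezes_state(self, chain_model):
        broken = chain_model.with_bounds({"UPTAKE": (5.0, 10.0),
                                          "R1": (0.0, 1.0)})
        mu, X, conc, _, infeasible = step(1.0, {}, broken, 0.01)
        assert infeasible and mu == 0.0 and X == 1.0


class TestRunScenario:
    def test_glucose_depletion_time_matches_analytic_batch_solution(self):
        # respiration fully open: constant mu while glucose lasts
        model = cf.make_toy_model("diauxic")
        model = model.with_bounds({"EX_eth": (0.0, 1000.0)})  # no ethanol uptake
        X0, C0, q = 0.1, 5.0, 1.0
        scen = DFBAScenario(
            phases=[Phase(model, "batch")],
            initial_biomass=X0,
            initial_concentrations={"EX_glc": C0},
            vmax={"EX_glc": q}, dt=0.01, max_time=4.0,
        )
        traj = run_scenario(scen)
        mu = traj.table.mu.iloc[0]
        assert mu == pytest.approx(14.0 / 6.0, abs=1e-9)
        depleted = traj.table[traj.table["EX_glc"] < 1e-6]
        t_sim = depleted.t.iloc[0]
        t_star = np.log(1 + mu * C0 / (q * X0)) / mu
        assert abs(t_sim - t_star) / t_star < 0.02

    def test_biomass_per_glucose_matches_stoichiometric_yield(self):
        model = cf.make_toy_model("diauxic")
        model = model.with_bounds({"EX_eth": (0.0, 1000.0)})
        scen = DFBAScenario(
            phases=[Phase(model, "batch")], initial_biomass=0.1,
            initial_concentrations={"EX_glc": 5.0},
            vmax={"EX_glc": 1.0}, dt=0.005, max_time=4.0,
        )
        traj = run_scenario(scen)
        dX = traj.final_biomass - 0.1
        # yield: 14/6 biomass per glucose (2 ATP glycolysis + 12 respiration)
        assert dX / 5.0 == pytest.approx(14.0 / 6.0, rel=0.02)

    def test_two_phase_diauxic_growth(self, phase_models):
        _, m_glc, m_eth = phase_models
        traj = run_scenario(diauxic_scenario(m_glc, m_eth)).table
        assert (traj.phase.diff().dropna() >= 0).all()
        phase2 = traj[traj.phase == 1]
        assert len(phase2) > 0, "second phase never entered"
        # ethanol accumulated during phase 1, consumed in phase 2
        switch_eth = phase2["EX_eth"].iloc[0]
        assert switch_eth > 1.0
        assert phase2["EX_eth"].iloc[-1] < switch_eth
        # biomass strictly increases while ethanol lasts
        growing = phase2[phase2["EX_eth"] > 1e-3]
        assert (np.diff(growing.biomass) > 0).all()

    def test_no_substrate_gives_flat_trajectory(self, phase_models):
        model, _, _ = phase_models
        scen = DFBAScenario(
            phases=[Phase(model, "starved")], initial_biomass=0.2,
            initial_concentrations={"EX_glc": 0.0, "EX_eth": 0.0},
            vmax={"EX_glc": 1.0, "EX_eth": 0.5}, dt=0.05, max_time=2.0,
        )
        traj = run_scenario(scen).table
        assert np.allclose(traj.biomass, 0.2)
        assert np.allclose(traj.mu, 0.0, atol=1e-9)

    def test_step_halving_converges(self, phase_models):
        _, m_glc, m_eth = phase_models
        coarse = run_scenario(diauxic_scenario(m_glc, m_eth, dt=0.02,
                                               max_time=8.0)).final_biomass
        fine = run_scenario(diauxic_scenario(m_glc, m_eth, dt=0.01,
                                             max_time=8.0)).final_biomass
        assert abs(coarse - fine) / fine < 0.01

    def test_concentrations_never_negative(self, phase_models):
        _, m_glc, m_eth = phase_models
        traj = run_scenario(diauxic_scenario(m_glc, m_eth)).table
        assert (traj["EX_glc"] >= 0).all()
        assert (traj["EX_eth"] >= 0).all()
        assert (traj.biomass > 0).all()

    def test_deterministic(self, phase_models):
        _, m_glc, m_eth = phase_models
        a = run_scenario(diauxic_scenario(m_glc, m_eth, max_time=3.0)).table
        b = run_scenario(diauxic_scenario(m_glc, m_eth, max_time=3.0)).table
        assert a.equals(b)

    def test_time_based_switch_supported(self, phase_models):
        _, m_glc, m_eth = phase_models
        scen = DFBAScenario(
            phases=[Phase(m_glc, "glucose", switch_time=1.0),
                    Phase(m_eth, "ethanol")],
            initial_biomass=0.05,
            initial_concentrations={"EX_glc": 5.0, "EX_eth": 0.0},
            vmax={"EX_glc": 1.0, "EX_eth": 0.5}, dt=0.05, max_time=2.0,
        )
        traj = run_scenario(scen).table
        assert (traj.loc[traj.t < 1.0, "phase"] == 0).all()
        assert (traj.loc[traj.t >= 1.0, "phase"] == 1).all()

    def test_scenario_validation(self, phase_models):
        model, _, _ = phase_models
        with pytest.raises(ValueError):
            DFBAScenario(phases=[], initial_biomass=0.1,
                         initial_concentrations={})
        with pytest.raises(ValueError):
            DFBAScenario(phases=[Phase(model)], initial_biomass=0.1,
                         initial_concentrations={"EX_glc": -1.0})
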