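import numpy as np
import pytest

import coregflux as cf
from coregflux.constraints import build_constraints

from _oracles import brute_force_lp_optimum


class TestSoftplus:
    def test_closed_form_values(self):
        assert cf.softplus_bound(0.0, 0.0) == pytest.approx(np.log(2), abs=1e-12)
        assert cf.softplus_bound(2.0, 3.0) == pytest.approx(5.0067153, abs=1e-6)

    def test_large_argument_no_overflow(self):
        b = cf.softplus_bound(500.0, 500.0)
        assert np.isfinite(b) and b == pytest.approx(1000.0, rel=1e-12)

    def test_very_negative_argument_stays_nonnegative_and_tiny(self):
        b = cf.softplus_bound(-50.0, 0.0)
        assert 0.0 <= b <= 1e-20

    def test_monotone_in_both_arguments(self):
        gs = np.linspace(-20, 20, 41)
        vals = [cf.softplus_bound(g, 0.3) for g in gs]
        assert np.all(np.diff(vals) > 0)


class TestApplyConstraints:
    def test_irreversible_upper_bound_tightened(self, chain_model):
        cs = cf.SoftplusConstraintSet(theta=0.0, bounds={"R1": 2.3})
        out = cf.apply_constraints(chain_model, cs)
        j = out.reaction_index("R1")
        assert out.ub[j] == 2.3 and out.lb[j] == 0.0
        # input untouched
        assert chain_model.ub[chain_model.reaction_index("R1")] == 1000.0

    def test_reversible_bound_mirrored(self, diauxic_model):
        cs = cf.SoftplusConstraintSet(theta=0.0, bounds={"EX_eth": 2.3})
        out = cf.apply_constraints(diauxic_model, cs)
        j = out.reaction_index("EX_eth")
        assert (out.lb[j], out.ub[j]) == (-2.3, 2.3)

    def test_loose_bound_never_relaxes_model(self, chain_model):
        cs = cf.SoftplusConstraintSet(theta=0.0, bounds={"UPTAKE": 5000.0})
        out = cf.apply_constraints(chain_model, cs)
        assert out.ub[out.reaction_index("UPTAKE")] == 10.0

    def test_undefined_gpr_reactions_keep_default_bounds(self, diauxic_model):
        cs = build_constraints(diauxic_model, {}, theta=0.0)
        assert cs.bounds == {}
        out = cf.apply_constraints(diauxic_model, cs)
        assert np.allclose(out.ub, diauxic_model.ub)


class TestSolveFBA:
    def test_chain_bottleneck(self, chain_model):
        sol = cf.solve_fba(chain_model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(10.0)

    def test_branch_matches_vertex_enumeration_oracle(self, branch_model):
        sol = cf.solve_fba(branch_model)
        assert sol.objective_value == pytest.approx(
            brute_force_lp_optimum(branch_model), abs=1e-6)

    def test_diauxic_matches_vertex_enumeration_oracle(self, diauxic_model):
        sol = cf.solve_fba(diauxic_model)
        assert sol.objective_value == pytest.approx(
            brute_force_lp_optimum(diauxic_model), abs=1e-6)

    def test_matches_cobrapy_on_toys(self, tmp_path, branch_model, diauxic_model):
        cobra = pytest.importorskip("cobra")
        import cobra.io
        for model in (branch_model, diauxic_model):
            path = tmp_path / f"{model.name}.xml"
            cf.write_metabolic_model(model, path)
            cmodel = cobra.io.read_sbml_model(str(path))
            expected = cmodel.slim_optimize()
            assert cf.solve_fba(model).objective_value == pytest.approx(
                expected, abs=1e-6)

    def test_closed_uptake_gives_zero(self, chain_model):
        m = chain_model.with_bounds({"UPTAKE": (0.0, 0.0)})
        assert cf.solve_fba(m).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_reported_not_raised(self, chain_model):
        m = chain_model.with_bounds({"UPTAKE": (5.0, 10.0), "R1": (0.0, 1.0)})
        sol = cf.solve_fba(m)
        assert sol.status == "infeasible"

    def test_steady_state_residual(self, diauxic_model):
        sol = cf.solve_fba(diauxic_model)
        v = np.array([sol.fluxes[r] for r in diauxic_model.reaction_ids])
        assert np.abs(diauxic_model.S @ v).max() <= 1e-6

    def test_minimization_sense(self, chain_model):
        assert cf.solve_fba(chain_model, "min").objective_value == pytest.approx(0.0, abs=1e-9)


class TestSimulate:
    def test_theta_plus_30_recovers_plain_fba(self, diauxic_model):
        acts = cf.diauxic_phase_activities()["glucose"]
        sol = cf.simulate(diauxic_model, 30.0, predicted_expression=acts)
        plain = cf.solve_fba(diauxic_model)
        assert sol.objective_value == pytest.approx(plain.objective_value, abs=1e-6)

    def test_theta_minus_30_closes_growth(self, diauxic_model):
        acts = cf.diauxic_phase_activities()["glucose"]
        sol = cf.simulate(diauxic_model, -30.0, predicted_expression=acts)
        assert sol.objective_value == pytest.approx(0.0, abs=1e-6)

    def test_objective_nondecreasing_in_theta(self, diauxic_model):
        acts = cf.diauxic_phase_activities()["glucose"]
        objs = [cf.simulate(diauxic_model, th, predicted_expression=acts).objective_value
                for th in np.linspace(-10, 10, 20)]
        assert np.all(np.diff(objs) >= -1e-9)
        assert objs[-1] <= cf.solve_fba(diauxic_model).objective_value + 1e-9

    def test_full_pipeline_route_equals_explicit_predictions(self, benchmark):
        b = benchmark
        cond = b.conditions[0]
        infl = cf.compute_influence(b.net, b.context_noisy)
        pred = cf.predict(b.lin_model, infl)
        via_pipeline = cf.simulate(b.model, 0.5, sample=cond,
                                   lin_model=b.lin_model, network=b.net,
                                   expression=b.context_noisy)
        via_pred = cf.simulate(b.model, 0.5, sample=cond,
                               predicted_expression=pred)
        assert via_pipeline.objective_value == pytest.approx(
            via_pred.objective_value, abs=1e-9)


class TestFoldChanges:
    def test_fold_change_filter_and_from_zero_marker(self):
        ref = cf.FluxSolution({"a": 1.0, "b": 2.0, "c": 0.0, "d": 0.0},
                              1.0, "optimal")
        alt = cf.FluxSolution({"a": 4.1, "b": 2.2, "c": 0.7, "d": 0.0},
                              1.0, "optimal")
        table = cf.flux_fold_changes(ref, alt, min_abs_log2=1.0)
        rows = {r.reaction: r for r in table.itertuples()}
        assert rows["a"].log2_fold_change == pytest.approx(np.log2(4.1))
        assert "b" not in rows  # below two-fold
        assert rows["c"].note == "from_zero"
        assert "d" not in rows  # zero in both
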