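import numpy as np
import pandas as pd
import pytest

import coregflux as cf
from coregflux.grn import discretize, mine_coregulators, score_local_grn

from _oracles import exhaustive_signed_sets


def disc_frame(rows: dict[str, list[int]]) -> pd.DataFrame:
    return pd.DataFrame(rows, dtype=int).T.set_axis(
        [f"S{i}" for i in range(len(next(iter(rows.values()))))], axis=1)


class TestDiscretize:
    def test_thresholding_after_centering(self):
        expr = pd.DataFrame({"S1": [1.2, -0.5], "S2": [-1.2, 0.5]},
                            index=["g1", "g2"])
        # genes are already mean-zero; threshold 1.0
        d = discretize(expr, 1.0)
        assert d.loc["g1"].tolist() == [1, -1]
        assert d.loc["g2"].tolist() == [0, 0]

    def test_constant_gene_all_zero(self):
        expr = pd.DataFrame({"S1": [5.0], "S2": [5.0], "S3": [5.0]}, index=["g"])
        assert (discretize(expr, 1.0) == 0).all().all()
        assert (discretize(expr, 1.0, per_gene_sd=True) == 0).all().all()

    def test_nonpositive_threshold_rejected(self):
        expr = pd.DataFrame({"S1": [1.0], "S2": [0.0]}, index=["g"])
        with pytest.raises(ValueError):
            discretize(expr, 0.0)


class TestMineCoregulators:
    def test_identical_profile_is_coactivator_with_full_support(self):
        d = disc_frame({"T": [1, -1, 0, 1], "R1": [1, -1, 0, 1],
                        "R2": [0, 1, -1, 0]})
        cands = mine_coregulators(d, "T", {"R1", "R2"}, 1, min_support=1.0)
        assert (frozenset({"R1"}), frozenset(), 1.0) in cands

    def test_sign_flip_is_corepressor_with_full_support(self):
        d = disc_frame({"T": [1, -1, 1], "R2": [-1, 1, -1]})
        cands = mine_coregulators(d, "T", {"R2"}, 1, min_support=1.0)
        assert (frozenset(), frozenset({"R2"}), 1.0) in cands

    def test_and_pair_recovered_and_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(5)
        r1 = rng.choice([-1, 0, 1], 40)
        r2 = rng.choice([-1, 0, 1], 40)
        target = np.minimum(r1, r2)  # AND-combination of the two activators
        d = disc_frame({"T": target.tolist(), "R1": r1.tolist(),
                        "R2": r2.tolist(), "R3": rng.choice([-1, 0, 1], 40).tolist()})
        regs = {"R1", "R2", "R3"}
        cands = mine_coregulators(d, "T", regs, 2, min_support=0.9)
        found = {(a, r) for a, r, _ in cands}
        assert (frozenset({"R1", "R2"}), frozenset()) in found
        assert found == exhaustive_signed_sets(d, "T", regs, 2, 0.9)

    def test_no_match_returns_empty_not_error(self):
        # a flat regulator profile matches the target in no nonzero sample
        d = disc_frame({"T": [1, 1, 1], "R1": [0, 0, 0]})
        assert mine_coregulators(d, "T", {"R1"}, 1, min_support=1.0) == []

    def test_support_monotonicity(self):
        rng = np.random.default_rng(9)
        rows = {f"R{i}": rng.choice([-1, 0, 1], 30).tolist() for i in range(4)}
        rows["T"] = rng.choice([-1, 0, 1], 30).tolist()
        d = disc_frame(rows)
        regs = {f"R{i}" for i in range(4)}
        loose = {(a, r) for a, r, _ in mine_coregulators(d, "T", regs, 2, 0.3)}
        tight = {(a, r) for a, r, _ in mine_coregulators(d, "T", regs, 2, 0.6)}
        assert tight <= loose

    def test_target_in_regulators_rejected(self):
        d = disc_frame({"T": [1, 0]})
        with pytest.raises(ValueError):
            mine_coregulators(d, "T", {"T"}, 1, 0.5)


class TestScoreLocalGRN:
    def test_exact_coactivator_min_gives_r2_one(self):
        rng = np.random.default_rng(2)
        r1, r2 = rng.normal(size=20), rng.normal(size=20)
        expr = pd.DataFrame(
            np.vstack([np.minimum(r1, r2), r1, r2]),
            index=["T", "R1", "R2"],
            columns=[f"S{i}" for i in range(20)],
        )
        assert score_local_grn(expr, "T", {"R1", "R2"}, set()) == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.normal(size=(3, 5)), index=["T", "R1", "R2"],
                            columns=[f"S{i}" for i in range(5)])
        got = score_local_grn(expr, "T", {"R1"}, {"R2"})
        # closed-form OLS with intercept on [min(act), min(rep)] covariates
        y = expr.loc["T"].to_numpy()
        X = np.column_stack([np.ones(5), expr.loc["R1"], expr.loc["R2"]])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert got == pytest.approx(r2, abs=1e-10)

    def test_noise_target_scores_low(self):
        rng = np.random.default_rng(11)
        expr = pd.DataFrame(rng.normal(size=(3, 50)), index=["T", "R1", "R2"],
                            columns=[f"S{i}" for i in range(50)])
        assert score_local_grn(expr, "T", {"R1"}, {"R2"}) < 0.2

    def test_too_few_samples_raises(self):
        expr = pd.DataFrame(np.ones((3, 3)), index=["T", "R1", "R2"],
                            columns=["S0", "S1", "S2"])
        with pytest.raises(ValueError, match="few"):
            score_local_grn(expr, "T", {"R1"}, {"R2"})


class TestInferNetwork:
    def test_planted_discrete_logic_recovery(self):
        net = cf.make_planted_network(8, 30, edges_per_target=2, seed=11)
        expr = cf.make_expression(net, 100, noise_sd=0.2,
                                  regime="discrete_logic", seed=11)
        inferred = cf.infer_network(expr, net.regulators)
        assert cf.edge_f1(net, inferred) >= 0.8

    def test_deterministic(self):
        net = cf.make_planted_network(4, 10, seed=1)
        expr = cf.make_expression(net, 60, regime="discrete_logic", seed=1)
        a = cf.infer_network(expr, net.regulators)
        b = cf.infer_network(expr, net.regulators)
        assert a.signed_edges() == b.signed_edges()

    def test_no_regulators_gives_empty_network(self, small_expression):
        net = cf.infer_network(small_expression, set())
        assert net.signed_edges() == set()

    def test_degenerate_evidence_weight_selects_by_evidence(self):
        net = cf.make_planted_network(4, 6, edges_per_target=1, seed=2,
                                      p_repressor=0.0)
        expr = cf.make_expression(net, 80, noise_sd=0.2,
                                  regime="discrete_logic", seed=2)
        ev = {(r, t): 1.0 for (r, t, s) in net.signed_edges()}
        inferred = cf.infer_network(expr, net.regulators, evidence=ev,
                                    evidence_weight=1.0, min_support=0.5,
                                    max_set_size=1)
        # with weight 1 the merged score is pure evidence: every selected
        # edge must be one of the evidence-1.0 (true) edges
        true_pairs = {(r, t) for r, t, _ in net.signed_edges()}
        got_pairs = {(r, t) for r, t, _ in inferred.signed_edges()}
        assert got_pairs <= true_pairs
        assert got_pairs  # and selection is non-empty
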