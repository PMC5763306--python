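"""Assembly of the planted end-to-end benchmark.

Ties every stage together on synthetic data: a planted signed network whose
first targets are the diauxic toy model's GPR genes, a background
expression compendium for training the influence-based predictor, a small
set of noise-free context conditions defining the "observed" exchange
fluxes, noisy realizations of the same conditions, and a per-condition
theta calibrated against the observed growth.  Tests and the reproduction
script both build on this, so the study conditions live in exactly one
place.

Design of the conditions: each regulator keeps several activated and
repressed targets (the influence statistic needs both classes, and its
robustness comes from pooling over many targets); genes carry fixed
baseline offsets as in real log-scale data; and the observed growth is
anchored at a typical exponential-phase yeast rate (0.35 1/h) by
calibrating theta on the noise-free context — mirroring a protocol where
each condition is a growing culture with a measured rate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import pandas as pd

from .calibration import CalibrationResult, calibrate_theta
from .constraints import simulate
from .influence import compute_influence
from .predictor import LinearInfluenceModel, fit
from .synthetic import make_expression, make_planted_network, make_toy_model
from .types import FluxSolution, MetabolicModel, RegulatoryNetwork

__all__ = ["PlantedBenchmark", "make_benchmark"]

OBSERVED_GROWTH = 0.35  # 1/h, typical yeast exponential-phase rate


@dataclass
class PlantedBenchmark:
    """All artifacts of one planted benchmark instance."""

    model: MetabolicModel
    net: RegulatoryNetwork
    expr_train: pd.DataFrame
    lin_model: LinearInfluenceModel
    context_true: pd.DataFrame   # noise-free context expression
    context_noisy: pd.DataFrame  # same latent states plus observation noise
    v_obs: dict[str, dict[str, float]]  # condition -> exchange fluxes
    v_obs_growth: dict[str, float]      # condition -> biomass flux
    theta: dict[str, float]             # condition -> calibrated theta
    calibrations: dict[str, CalibrationResult]

    @property
    def conditions(self) -> list[str]:
        return list(self.context_noisy.columns)

    def simulate_from_expression(
        self,
    ) -> Callable[[pd.DataFrame], dict[str, FluxSolution]]:
        """Pipeline closure used by the robustness protocol: runs every
        condition at its calibrated theta."""
        def run(expr: pd.DataFrame) -> dict[str, FluxSolution]:
            infl = compute_influence(self.net, expr)
            return {
                cond: simulate(self.model, self.theta[cond], sample=cond,
                               lin_model=self.lin_model, influences=infl)
                for cond in self.conditions
            }
        return run


def make_benchmark(
    seed: int = 0,
    n_regs: int = 6,
    n_targets: int = 120,
    edges_per_target: int = 3,
    p_repressor: float = 0.4,
    n_train: int = 100,
    n_conditions: int = 3,
    noise_sd: float = 0.2,
    baseline_sd: float = 2.0,
    observed_growth: float = OBSERVED_GROWTH,
) -> PlantedBenchmark:
    """Build the standard planted benchmark.

    The observed condition is generated by calibrating theta on each
    noise-free context column so the simulated growth equals
    ``observed_growth``, then recording the resulting exchange fluxes as
    the observations; the working thetas are re-calibrated per condition
    from the noisy context against those observed growth rates.
    """
    model = make_toy_model("diauxic")
    gene_targets = sorted(model.genes)
    net = make_planted_network(
        n_regs, n_targets, edges_per_target=edges_per_target, seed=seed,
        p_repressor=p_repressor, target_names=gene_targets,
    )
    gen = dict(noise_sd=noise_sd, regime="linear_influence",
               baseline_sd=baseline_sd)
    expr_train = make_expression(net, n_train, seed=seed + 1, **gen)
    infl_train = compute_influence(net, expr_train)
    lin_model = fit(net, infl_train, expr_train, targets=set(gene_targets))

    context_true = make_expression(net, n_conditions, noise_sd=0.0,
                                   regime="linear_influence",
                                   baseline_sd=baseline_sd, seed=seed + 2)
    context_noisy = make_expression(net, n_conditions, seed=seed + 2, **gen)

    v_obs: dict[str, dict[str, float]] = {}
    v_obs_growth: dict[str, float] = {}
    theta: dict[str, float] = {}
    calibrations: dict[str, CalibrationResult] = {}
    infl_true = compute_influence(net, context_true)
    infl_noisy = compute_influence(net, context_noisy)
    for cond in context_true.columns:
        anchor = calibrate_theta(
            lambda th: simulate(model, th, sample=cond, lin_model=lin_model,
                                influences=infl_true),
            observed_growth,
        )
        sol = simulate(model, anchor.theta_opt, sample=cond,
                       lin_model=lin_model, influences=infl_true)
        if sol.status != "optimal":
            raise RuntimeError(f"observed-condition simulation infeasible ({cond})")
        v_obs[cond] = {rid: sol.fluxes[rid] for rid in sorted(model.exchange)}
        v_obs_growth[cond] = sol.objective_value
        calib = calibrate_theta(
            lambda th: simulate(model, th, sample=cond, lin_model=lin_model,
                                influences=infl_noisy),
            v_obs_growth[cond],
        )
        theta[cond] = calib.theta_opt
        calibrations[cond] = calib
    return PlantedBenchmark(
        model=model, net=net, expr_train=expr_train, lin_model=lin_model,
        context_true=context_true, context_noisy=context_noisy,
        v_obs=v_obs, v_obs_growth=v_obs_growth, theta=theta,
        calibrations=calibrations,
    )
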