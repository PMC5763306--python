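"""Synthetic fixtures: toy metabolic models, planted regulatory networks
and expression matrices matching the method's generative assumptions.

Everything here is a pure function of its parameters and a seed, so every
pipeline stage is testable without external datasets.  The toy models are
deliberately small (4-8 reactions) with hand-checkable optima; the diauxic
model abstracts glucose fermentation/respiration and ethanol re-assimilation
with GPR rules on the regulated branches so that transcriptional constraints
can switch growth phases.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import MetabolicModel, RegulatoryNetwork
from .gpr import parse_gpr

__all__ = [
    "make_toy_model",
    "diauxic_phase_activities",
    "make_planted_network",
    "make_expression",
    "make_linear_target_data",
]


def make_toy_model(kind: str) -> MetabolicModel:
    """Build one of the toy stoichiometric models.

    ``chain``
        Linear pathway uptake -> A -> B -> biomass; the plain-FBA optimum
        equals the uptake upper bound (10).  The first conversion carries
        the GPR ``G1`` so softplus constraints can throttle growth.
    ``branch``
        Two substrates with yields 2 and 1 on a shared precursor; optimum
        2*10 + 1*5 = 25.  Each branch carries its own GPR.
    ``diauxic``
        Abstract yeast-like network: glucose -> 2 pyruvate + 2 ATP
        (glycolysis, ``G_HXK``); pyruvate -> ethanol (fermentation,
        ``G_PDC``); pyruvate -> 6 ATP (respiration, ``G_RESP1 and
        G_RESP2``); ethanol -> 0.5 pyruvate (re-assimilation, ``G_ADH2``);
        biomass costs 6 ATP.  With respiration open, growth is ~2.33 per
        unit glucose uptake and no ethanol is excreted; with respiration
        repressed (glucose phase), overflow fermentation excretes ethanol
        at ~2 per glucose.
    """
    if kind == "chain":
        return MetabolicModel(
            metabolite_ids=["A", "B", "P"],
            reaction_ids=["UPTAKE", "R1", "R2", "BIOMASS"],
            S=np.array([
                # UPTAKE  R1   R2  BIOMASS
                [1.0, -1.0, 0.0, 0.0],   # A
                [0.0, 1.0, -1.0, 0.0],   # B
                [0.0, 0.0, 1.0, -1.0],   # P
            ]),
            lb=np.zeros(4),
            ub=np.array([10.0, 1000.0, 1000.0, 1000.0]),
            objective_reaction="BIOMASS",
            gpr={"R1": parse_gpr("G1")},
            exchange={"UPTAKE", "BIOMASS"},
            name="toy_chain",
        )
    if kind == "branch":
        return MetabolicModel(
            metabolite_ids=["S1", "S2", "P"],
            reaction_ids=["EX1", "EX2", "R1", "R2", "BIOMASS"],
            S=np.array([
                # EX1  EX2   R1    R2  BIOMASS
                [1.0, 0.0, -1.0, 0.0, 0.0],   # S1
                [0.0, 1.0, 0.0, -1.0, 0.0],   # S2
                [0.0, 0.0, 2.0, 1.0, -1.0],   # P
            ]),
            lb=np.zeros(5),
            ub=np.array([10.0, 5.0, 1000.0, 1000.0, 1000.0]),
            objective_reaction="BIOMASS",
            gpr={"R1": parse_gpr("GA"), "R2": parse_gpr("GB")},
            exchange={"EX1", "EX2", "BIOMASS"},
            name="toy_branch",
        )
    if kind == "diauxic":
        mets = ["glc", "pyr", "eth", "atp"]
        rxns = ["EX_glc", "EX_eth", "GLYC", "FERM", "ETHOX", "RESP", "BIOMASS"]
        S = np.zeros((4, 7))
        m = {x: i for i, x in enumerate(mets)}
        r = {x: j for j, x in enumerate(rxns)}
        S[m["glc"], r["EX_glc"]] = -1.0      # negative flux = glucose uptake
        S[m["eth"], r["EX_eth"]] = -1.0      # positive flux = ethanol excretion
        S[m["glc"], r["GLYC"]] = -1.0
        S[m["pyr"], r["GLYC"]] = 2.0
        S[m["atp"], r["GLYC"]] = 2.0
        S[m["pyr"], r["FERM"]] = -1.0
        S[m["eth"], r["FERM"]] = 1.0
        S[m["eth"], r["ETHOX"]] = -1.0
        S[m["pyr"], r["ETHOX"]] = 0.5
        S[m["pyr"], r["RESP"]] = -1.0
        S[m["atp"], r["RESP"]] = 6.0
        S[m["atp"], r["BIOMASS"]] = -6.0
        lb = np.array([-1.0, -10.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        ub = np.array([0.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0, 1000.0])
        return MetabolicModel(
            metabolite_ids=mets,
            reaction_ids=rxns,
            S=S,
            lb=lb,
            ub=ub,
            objective_reaction="BIOMASS",
            gpr={
                "GLYC": parse_gpr("G_HXK"),
                "FERM": parse_gpr("G_PDC"),
                "ETHOX": parse_gpr("G_ADH2"),
                "RESP": parse_gpr("G_RESP1 and G_RESP2"),
            },
            exchange={"EX_glc", "EX_eth", "BIOMASS"},
            name="toy_diauxic",
        )
    raise ValueError(f"unknown toy model kind {kind!r}")


def diauxic_phase_activities() -> dict[str, dict[str, float]]:
    """Gene activities defining the two diauxic phases of the toy model.

    In the glucose phase respiration and ethanol oxidation are repressed
    (glucose repression), so flux overflows into fermentation and ethanol
    accumulates; in the ethanol phase fermentation is off and the
    respiratory/ethanol-oxidation genes are derepressed.  Values are on the
    centered log-expression scale the predictor emits.
    """
    return {
        "glucose": {"G_HXK": 2.0, "G_PDC": 2.0,
                    "G_RESP1": -4.0, "G_RESP2": -4.0, "G_ADH2": -4.0},
        "ethanol": {"G_HXK": -1.0, "G_PDC": -4.0,
                    "G_RESP1": 2.0, "G_RESP2": 2.0, "G_ADH2": 2.0},
    }


def make_planted_network(
    n_regs: int,
    n_targets: int,
    edges_per_target: int = 2,
    seed: int = 0,
    p_repressor: float = 0.3,
    target_names: list[str] | None = None,
) -> RegulatoryNetwork:
    """Random signed network with known ground truth.

    Regulators are ``R1..Rn``, targets ``G1..Gm`` (or ``target_names``,
    padded with ``Gk`` names if shorter than ``n_targets``).  Each target
    receives ``edges_per_target`` distinct regulators; the first is always
    an activator, the rest are repressors with probability ``p_repressor``.
    """
    if n_regs < 2:
        raise ValueError("need at least 2 regulators")
    if edges_per_target > n_regs:
        raise ValueError("edges_per_target cannot exceed n_regs")
    rng = np.random.default_rng(seed)
    regs = [f"R{i + 1}" for i in range(n_regs)]
    names = list(target_names or [])
    names += [f"G{k + 1}" for k in range(len(names), n_targets)]
    net = RegulatoryNetwork()
    for g in range(n_targets):
        target = names[g]
        chosen = rng.choice(regs, size=edges_per_target, replace=False)
        for k, reg in enumerate(chosen):
            sign = +1 if k == 0 or rng.random() >= p_repressor else -1
            net.add_edge(str(reg), target, sign)
    return net


def make_expression(
    net: RegulatoryNetwork,
    n_samples: int,
    noise_sd: float = 0.2,
    regime: str = "linear_influence",
    seed: int = 0,
    effect: float = 1.0,
    amplitude: float = 2.0,
    logic_threshold: float = 1.0,
    baseline_sd: float = 0.0,
) -> pd.DataFrame:
    """Generate a genes x samples expression matrix from a planted network.

    Regulator rows are i.i.d. standard-normal profiles.  Target rows follow
    one of two regimes:

    ``linear_influence``
        x = +effect * min(activator profiles) - effect * min(repressor
        profiles) + noise, so regulator influences are informative and the
        linear influence model holds approximately.
    ``discrete_logic``
        Regulator profiles are discretized at ``logic_threshold``; the
        target takes ``amplitude`` times the min-combined signed state plus
        noise — the generative model the local-GRN miner assumes.

    ``baseline_sd`` > 0 adds a fixed per-gene offset drawn from
    N(0, baseline_sd^2), emulating the gene-specific expression baselines
    of real log-scale data (seeded, constant across samples, applied to
    regulators and targets alike).  The default of 0 keeps the idealized
    centered regimes.
    """
    rng = np.random.default_rng(seed)
    regs = sorted(net.regulators)
    targets = sorted(net.targets - net.regulators)
    samples = [f"S{k + 1}" for k in range(n_samples)]
    Z = rng.standard_normal((len(regs), n_samples))
    z = {reg: Z[i] for i, reg in enumerate(regs)}
    rows = {reg: Z[i] for i, reg in enumerate(regs)}
    if regime == "discrete_logic":
        d = {reg: np.where(v > logic_threshold, 1,
                           np.where(v < -logic_threshold, -1, 0))
             for reg, v in z.items()}
    elif regime != "linear_influence":
        raise ValueError(f"unknown regime {regime!r}")
    for target in targets:
        activators = sorted(r for r in net.activated if target in net.activated[r])
        repressors = sorted(r for r in net.repressed if target in net.repressed[r])
        x = np.zeros(n_samples)
        if regime == "linear_influence":
            if activators:
                x = x + effect * np.min([z[r] for r in activators], axis=0)
            if repressors:
                x = x - effect * np.min([z[r] for r in repressors], axis=0)
        else:
            parts = [d[r] for r in activators] + [-d[r] for r in repressors]
            x = amplitude * np.min(parts, axis=0).astype(float)
        rows[target] = x + noise_sd * rng.standard_normal(n_samples)
    data = pd.DataFrame(
        np.vstack([rows[g] for g in regs + targets]),
        index=regs + targets,
        columns=samples,
    )
    if baseline_sd > 0:
        # per-gene baseline from a dedicated stream so the latent regulator
        # states match the baseline-free matrix at the same seed
        base_rng = np.random.default_rng(np.random.SeedSequence(
            entropy=seed, spawn_key=(1,)))
        data = data.add(baseline_sd * base_rng.standard_normal(data.shape[0]),
                        axis=0)
    return data


def make_linear_target_data(
    infl: pd.DataFrame,
    betas: dict[str, dict[str, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Expression constructed exactly linear in given influences.

    ``betas[gene][regulator]`` are the generating coefficients; every
    referenced regulator must be a row of ``infl``.  With ``noise_sd`` = 0
    the linear influence model is exactly identifiable from this data.
    """
    rng = np.random.default_rng(seed)
    rows = {}
    for gene, coef in betas.items():
        x = np.zeros(infl.shape[1])
        for reg, b in coef.items():
            x = x + b * infl.loc[reg].to_numpy(float)
        rows[gene] = x + (noise_sd * rng.standard_normal(infl.shape[1])
                          if noise_sd > 0 else 0.0)
    return pd.DataFrame(rows, index=infl.columns).T
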