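"""Softplus flux bounds from GPR activities, and the FBA linear program.

Predicted gene activities are folded through each reaction's GPR rule
(min/max semantics, see :mod:`coregflux.gpr`) and turned into a positive
flux bound through the softplus activation

    v_r <= ln(1 + exp(gpr_r(X_pred) + theta)),

where theta is a single condition-specific offset calibrated against
observed growth.  Softplus maps any real activity to (0, +inf), so the
bound is always usable; theta -> +inf recovers plain FBA, theta -> -inf
closes every GPR-associated reaction.

Bounds are combined with the model's existing bounds by min/max, never by
replacement, so thermodynamic irreversibility is never relaxed; for
reversible reactions the bound is mirrored to the lower side (enzyme
limitation is directionless).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .gpr import evaluate_gpr
from .influence import compute_influence
from .predictor import LinearInfluenceModel, predict
from .types import FluxSolution, MetabolicModel, RegulatoryNetwork

__all__ = [
    "softplus_bound",
    "SoftplusConstraintSet",
    "build_constraints",
    "apply_constraints",
    "solve_fba",
    "simulate",
    "flux_fold_changes",
]

FEASIBILITY_TOL = 1e-6


def softplus_bound(g: float, theta: float) -> float:
    """ln(1 + exp(g + theta)), computed overflow-safely.

    Monotone increasing in both arguments; strictly positive for any finite
    input (may underflow to 0.0 in double precision for g + theta << -700,
    which downstream treats as a closed reaction).
    """
    return float(np.logaddexp(0.0, g + theta))


@dataclass
class SoftplusConstraintSet:
    """Per-reaction softplus bounds at a given theta.

    Reactions whose GPR evaluation is undefined (all genes missing) are
    absent and keep their default model bounds.
    """

    theta: float
    bounds: dict[str, float] = field(default_factory=dict)
    gpr_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {r: b for r, b in self.bounds.items() if b < 0}
        if bad:
            raise ValueError(f"softplus bounds must be positive: {bad}")


def build_constraints(
    model: MetabolicModel,
    activities: Mapping[str, float],
    theta: float,
) -> SoftplusConstraintSet:
    """Evaluate every GPR over the gene activities and wrap in softplus."""
    cs = SoftplusConstraintSet(theta=theta)
    for rid, tree in model.gpr.items():
        g = evaluate_gpr(tree, activities)
        if g is None:
            continue
        cs.gpr_values[rid] = g
        cs.bounds[rid] = softplus_bound(g, theta)
    return cs


def apply_constraints(model: MetabolicModel, cs: SoftplusConstraintSet) -> MetabolicModel:
    """Tighten flux bounds with the softplus constraint set.

    For each constrained reaction: ub <- min(ub, b); if the reaction is
    reversible (lb < 0), lb <- max(lb, -b).  Returns a new model; the input
    is untouched.
    """
    out = model.copy()
    for rid, b in cs.bounds.items():
        j = out.reaction_index(rid)
        out.ub[j] = min(out.ub[j], b)
        if out.lb[j] < 0:
            out.lb[j] = max(out.lb[j], -b)
        assert out.lb[j] <= out.ub[j], f"bound inversion on {rid}"
    return out


def solve_fba(model: MetabolicModel, objective_sense: str = "max") -> FluxSolution:
    """Solve the FBA linear program max/min c·v s.t. S·v = 0, lb <= v <= ub.

    Uses the HiGHS solver via :func:`scipy.optimize.linprog`.  Infeasible or
    unbounded problems are reported through ``status``, never raised.
    """
    if objective_sense not in ("max", "min"):
        raise ValueError(f"objective_sense must be 'max' or 'min', got {objective_sense!r}")
    n = len(model.reaction_ids)
    c = np.zeros(n)
    c[model.reaction_index(model.objective_reaction)] = (
        -1.0 if objective_sense == "max" else 1.0
    )
    res = linprog(
        c,
        A_eq=model.S,
        b_eq=np.zeros(len(model.metabolite_ids)),
        bounds=list(zip(model.lb, model.ub)),
        method="highs",
        options={"primal_feasibility_tolerance": 1e-9,
                 "dual_feasibility_tolerance": 1e-9},
    )
    if res.status == 2:
        return FluxSolution(fluxes={}, objective_value=float("nan"), status="infeasible")
    if res.status == 3:
        return FluxSolution(fluxes={}, objective_value=float("inf"), status="unbounded")
    if res.status != 0:
        return FluxSolution(fluxes={}, objective_value=float("nan"), status="infeasible")
    v = res.x
    imbalance = np.abs(model.S @ v).max() if len(model.metabolite_ids) else 0.0
    assert imbalance <= FEASIBILITY_TOL, f"steady-state violation {imbalance:g}"
    obj = float(v[model.reaction_index(model.objective_reaction)])
    return FluxSolution(
        fluxes={rid: float(x) for rid, x in zip(model.reaction_ids, v)},
        objective_value=obj,
        status="optimal",
    )


def _resolve_activities(
    sample: str | None,
    predicted_expression: Mapping[str, float] | pd.DataFrame | None,
    lin_model: LinearInfluenceModel | None,
    influences: pd.DataFrame | None,
    network: RegulatoryNetwork | None,
    expression: pd.DataFrame | None,
    use_raw_expression: bool,
) -> dict[str, float]:
    """Produce the gene -> activity mapping for one context sample."""

    def _column(df: pd.DataFrame) -> dict[str, float]:
        if df.shape[1] == 1:
            col = df.columns[0]
        elif sample is not None:
            col = sample
        else:
            raise ValueError("multiple context samples: pass sample=...")
        return {g: float(v) for g, v in df[col].items() if v == v}

    if predicted_expression is not None:
        if isinstance(predicted_expression, pd.DataFrame):
            return _column(predicted_expression)
        return {g: float(v) for g, v in predicted_expression.items() if v == v}
    if use_raw_expression:
        if expression is None:
            raise ValueError("use_raw_expression requires expression=")
        return _column(expression)
    if lin_model is None:
        raise ValueError(
            "pass predicted_expression, or lin_model plus influences/(network, expression)"
        )
    if influences is None:
        if network is None or expression is None:
            raise ValueError("need influences= or both network= and expression=")
        influences = compute_influence(network, expression)
    return _column(predict(lin_model, influences))


def simulate(
    model: MetabolicModel,
    theta: float,
    *,
    sample: str | None = None,
    predicted_expression: Mapping[str, float] | pd.DataFrame | None = None,
    lin_model: LinearInfluenceModel | None = None,
    influences: pd.DataFrame | None = None,
    network: RegulatoryNetwork | None = None,
    expression: pd.DataFrame | None = None,
    use_raw_expression: bool = False,
    return_model: bool = False,
):
    """Run the full pipeline for one context sample and solve FBA.

    Gene activities come from, in order of precedence: an explicit
    ``predicted_expression`` mapping/matrix; the linear influence model
    applied to ``influences`` (computed from ``network`` + ``expression``
    if absent); or raw ``expression`` when ``use_raw_expression`` is set
    (ablation mode).  The activities feed GPR evaluation, softplus bounds
    at ``theta``, bound application and one FBA solve.
    """
    activities = _resolve_activities(
        sample, predicted_expression, lin_model, influences, network,
        expression, use_raw_expression,
    )
    cs = build_constraints(model, activities, theta)
    constrained = apply_constraints(model, cs)
    sol = solve_fba(constrained)
    if return_model:
        return sol, constrained
    return sol


def flux_fold_changes(
    reference: FluxSolution,
    alternative: FluxSolution,
    min_abs_log2: float = 1.0,
    zero_tol: float = 1e-9,
) -> pd.DataFrame:
    """Per-reaction log2 fold change between two flux solutions.

    Fold changes are computed on flux magnitudes (alternative over
    reference).  Reactions where the reference flux is (numerically) zero
    but the alternative is not are reported with the marker ``from_zero``
    instead of a number; both-zero reactions are omitted.  Only rows with
    |log2 fold| >= ``min_abs_log2`` (default: two-fold) or a marker are kept.
    """
    rows = []
    for rid in reference.fluxes:
        v0 = abs(reference.fluxes[rid])
        v1 = abs(alternative.fluxes.get(rid, 0.0))
        if v0 <= zero_tol and v1 <= zero_tol:
            continue
        if v0 <= zero_tol:
            rows.append({"reaction": rid, "log2_fold_change": np.nan,
                         "note": "from_zero", "reference_flux": reference.fluxes[rid],
                         "alternative_flux": alternative.fluxes.get(rid, 0.0)})
            continue
        if v1 <= zero_tol:
            rows.append({"reaction": rid, "log2_fold_change": -np.inf,
                         "note": "to_zero", "reference_flux": reference.fluxes[rid],
                         "alternative_flux": alternative.fluxes.get(rid, 0.0)})
            continue
        lfc = float(np.log2(v1 / v0))
        if abs(lfc) >= min_abs_log2:
            rows.append({"reaction": rid, "log2_fold_change": lfc, "note": "",
                         "reference_flux": reference.fluxes[rid],
                         "alternative_flux": alternative.fluxes.get(rid, 0.0)})
    return pd.DataFrame(rows, columns=["reaction", "log2_fold_change", "note",
                                       "reference_flux", "alternative_flux"])
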