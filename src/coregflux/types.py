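"""Core domain types shared by every pipeline stage.

Expression and influence matrices are plain :class:`pandas.DataFrame` objects
(genes/regulators on the index, samples on the columns); the classes here
cover the structured objects that have no canonical pandas representation:
gene-protein-reaction (GPR) parse trees, signed regulatory networks,
stoichiometric metabolic models and LP flux solutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

__all__ = [
    "GPRNode",
    "GPRLeaf",
    "GPRAnd",
    "GPROr",
    "RegulatoryNetwork",
    "MetabolicModel",
    "FluxSolution",
    "ValidationError",
]


class ValidationError(ValueError):
    """An input object violates a structural invariant."""


# ---------------------------------------------------------------------------
# GPR parse trees
# ---------------------------------------------------------------------------


class GPRNode:
    """Base class of GPR parse-tree nodes.

    Trees are immutable; AND/OR nodes are flat n-ary (chained same-operator
    sequences are collapsed), so evaluation is commutative and associative
    by construction.
    """

    def genes(self) -> set[str]:
        raise NotImplementedError


@dataclass(frozen=True)
class GPRLeaf(GPRNode):
    gene: str

    def genes(self) -> set[str]:
        return {self.gene}

    def __str__(self) -> str:
        return self.gene


@dataclass(frozen=True)
class _GPRBranch(GPRNode):
    children: tuple[GPRNode, ...]
    _op = ""

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValidationError(
                f"{type(self).__name__} requires >= 2 children, got {len(self.children)}"
            )

    def genes(self) -> set[str]:
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out

    def __str__(self) -> str:
        parts = (
            f"({c})" if isinstance(c, _GPRBranch) else str(c) for c in self.children
        )
        return f" {self._op} ".join(parts)


class GPRAnd(_GPRBranch):
    """Enzyme complex: evaluates to the minimum over its children."""

    _op = "and"


class GPROr(_GPRBranch):
    """Isoenzymes: evaluates to the maximum over its children."""

    _op = "or"


# ---------------------------------------------------------------------------
# Regulatory network
# ---------------------------------------------------------------------------


@dataclass
class RegulatoryNetwork:
    """Signed bipartite regulator -> target graph.

    Parameters
    ----------
    activated, repressed
        Mapping from regulator id to the set of targets it activates /
        represses.  A (regulator, target) pair may appear in at most one of
        the two relations.
    edge_scores
        Optional per-edge evidence scores in [0, 1], keyed by
        ``(regulator, target)``.
    """

    activated: dict[str, set[str]] = field(default_factory=dict)
    repressed: dict[str, set[str]] = field(default_factory=dict)
    edge_scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for reg in set(self.activated) & set(self.repressed):
            both = self.activated[reg] & self.repressed[reg]
            if both:
                raise ValidationError(
                    f"regulator {reg!r} lists {sorted(both)} as both activated and repressed"
                )
        for (reg, tgt), score in self.edge_scores.items():
            if not 0.0 <= score <= 1.0:
                raise ValidationError(
                    f"evidence score for edge ({reg}, {tgt}) outside [0, 1]: {score}"
                )

    @property
    def regulators(self) -> set[str]:
        return set(self.activated) | set(self.repressed)

    def targets_of(self, regulator: str) -> set[str]:
        return self.activated.get(regulator, set()) | self.repressed.get(regulator, set())

    def regulators_of(self, gene: str) -> set[str]:
        """Pa(gene): regulators having ``gene`` among their targets."""
        return {r for r in self.regulators if gene in self.targets_of(r)}

    @property
    def targets(self) -> set[str]:
        out: set[str] = set()
        for reg in self.regulators:
            out |= self.targets_of(reg)
        return out

    def signed_edges(self) -> set[tuple[str, str, int]]:
        """All edges as (regulator, target, sign) with sign in {+1, -1}."""
        edges: set[tuple[str, str, int]] = set()
        for reg, tgts in self.activated.items():
            edges |= {(reg, t, +1) for t in tgts}
        for reg, tgts in self.repressed.items():
            edges |= {(reg, t, -1) for t in tgts}
        return edges

    def add_edge(self, regulator: str, target: str, sign: int,
                 score: float | None = None) -> None:
        if sign not in (+1, -1):
            raise ValidationError(f"edge sign must be +1 or -1, got {sign}")
        other = self.repressed if sign == +1 else self.activated
        if target in other.get(regulator, set()):
            raise ValidationError(
                f"edge ({regulator}, {target}) already present with opposite sign"
            )
        side = self.activated if sign == +1 else self.repressed
        side.setdefault(regulator, set()).add(target)
        if score is not None:
            if not 0.0 <= score <= 1.0:
                raise ValidationError(f"evidence score outside [0, 1]: {score}")
            self.edge_scores[(regulator, target)] = score


# ---------------------------------------------------------------------------
# Metabolic model
# ---------------------------------------------------------------------------


@dataclass
class MetabolicModel:
    """Stoichiometric model: S·v = 0 with per-reaction flux bounds.

    ``S`` is metabolites x reactions.  Bounds are in the conventional flux
    units (mmol·gDW⁻¹·h⁻¹).  ``gpr`` maps reaction ids to parse trees for
    reactions that carry a rule; ``exchange`` flags reactions crossing the
    system boundary (by default those with a single nonzero stoichiometric
    entry).
    """

    metabolite_ids: list[str]
    reaction_ids: list[str]
    S: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    objective_reaction: str
    gpr: dict[str, GPRNode] = field(default_factory=dict)
    exchange: set[str] = field(default_factory=set)
    name: str = "model"

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        self.validate()

    def validate(self) -> None:
        n_met, n_rxn = len(self.metabolite_ids), len(self.reaction_ids)
        if self.S.shape != (n_met, n_rxn):
            raise ValidationError(
                f"S has shape {self.S.shape}, expected ({n_met}, {n_rxn})"
            )
        if len(set(self.reaction_ids)) != n_rxn:
            raise ValidationError("duplicate reaction ids")
        if len(set(self.metabolite_ids)) != n_met:
            raise ValidationError("duplicate metabolite ids")
        if self.lb.shape != (n_rxn,) or self.ub.shape != (n_rxn,):
            raise ValidationError("bound vectors must have one entry per reaction")
        bad = np.nonzero(self.lb > self.ub)[0]
        if bad.size:
            rid = self.reaction_ids[int(bad[0])]
            raise ValidationError(
                f"reaction {rid!r}: lb={self.lb[bad[0]]} > ub={self.ub[bad[0]]}"
            )
        if self.objective_reaction not in self.reaction_ids:
            raise ValidationError(
                f"objective reaction {self.objective_reaction!r} not in model"
            )
        unknown = set(self.gpr) - set(self.reaction_ids)
        if unknown:
            raise ValidationError(f"GPR rules for unknown reactions: {sorted(unknown)}")

    def reaction_index(self, reaction_id: str) -> int:
        return self.reaction_ids.index(reaction_id)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for tree in self.gpr.values():
            out |= tree.genes()
        return out

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolite_ids=list(self.metabolite_ids),
            reaction_ids=list(self.reaction_ids),
            S=self.S.copy(),
            lb=self.lb.copy(),
            ub=self.ub.copy(),
            objective_reaction=self.objective_reaction,
            gpr=dict(self.gpr),
            exchange=set(self.exchange),
            name=self.name,
        )

    def with_bounds(self, bounds: Mapping[str, tuple[float, float]]) -> "MetabolicModel":
        """Return a copy with (lb, ub) replaced for the listed reactions."""
        out = self.copy()
        for rid, (lo, hi) in bounds.items():
            i = out.reaction_index(rid)
            out.lb[i], out.ub[i] = lo, hi
        out.validate()
        return out


def detect_exchange_reactions(S: np.ndarray, reaction_ids: list[str]) -> set[str]:
    """Reactions with a single nonzero stoichiometric entry (boundary rule)."""
    nnz = np.count_nonzero(np.asarray(S), axis=0)
    return {rid for rid, k in zip(reaction_ids, nnz) if k == 1}


# ---------------------------------------------------------------------------
# Flux solution
# ---------------------------------------------------------------------------


@dataclass
class FluxSolution:
    """Outcome of one FBA solve."""

    fluxes: dict[str, float]
    objective_value: float
    status: str  # "optimal" | "infeasible" | "unbounded"

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.fluxes.items())

    def __getitem__(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]
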