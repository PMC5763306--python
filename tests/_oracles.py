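"""Independent reference implementations used to cross-check the package.

Everything here is deliberately written without reusing the package's code
paths: the Welch statistic comes from scipy.stats, GPR evaluation is a
separate recursion over nested tuples, and the LP oracle enumerates basic
solutions by brute force.  Keep it that way.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy import stats

from coregflux.types import GPRAnd, GPRLeaf, MetabolicModel


def welch_statistic(a, b) -> float:
    """Textbook two-sample Welch t statistic via scipy."""
    return float(stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                                 equal_var=False).statistic)


def gpr_to_tuples(tree):
    """Convert a parse tree to nested ('and'|'or', children) tuples."""
    if isinstance(tree, GPRLeaf):
        return tree.gene
    op = "and" if isinstance(tree, GPRAnd) else "or"
    return (op, tuple(gpr_to_tuples(c) for c in tree.children))


def naive_gpr_eval(node, values: dict) -> float | None:
    """Discard-then-evaluate recursion over the tuple form."""
    if isinstance(node, str):
        v = values.get(node)
        if v is None or v != v:
            return None
        return float(v)
    op, children = node
    got = [naive_gpr_eval(c, values) for c in children]
    got = [g for g in got if g is not None]
    if not got:
        return None
    return min(got) if op == "and" else max(got)


def random_gpr_tree(rng: np.random.Generator, genes: list[str], depth: int = 3):
    """Random tuple-form GPR tree (also renderable as a rule string)."""
    if depth == 0 or rng.random() < 0.3:
        return genes[rng.integers(len(genes))]
    op = "and" if rng.random() < 0.5 else "or"
    n = int(rng.integers(2, 4))
    return (op, tuple(random_gpr_tree(rng, genes, depth - 1) for _ in range(n)))


def tuples_to_rule(node) -> str:
    if isinstance(node, str):
        return node
    op, children = node
    return "(" + f" {op} ".join(tuples_to_rule(c) for c in children) + ")"


def brute_force_lp_optimum(model: MetabolicModel) -> float:
    """Maximum objective by enumeration of basic feasible solutions.

    Fixes (n - rank(S)) fluxes at a bound in every possible way, solves
    S v = 0 for the rest, and keeps the best feasible point.  Only sensible
    for toy models (few reactions).
    """
    S = model.S
    n = len(model.reaction_ids)
    rank = np.linalg.matrix_rank(S)
    n_fix = n - rank
    obj_idx = model.reaction_index(model.objective_reaction)
    best = -np.inf
    for fixed in combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        for bounds_choice in product(*[(model.lb[j], model.ub[j]) for j in fixed]):
            rhs = -S[:, list(fixed)] @ np.asarray(bounds_choice)
            A = S[:, free]
            sol, residual, rk, _ = np.linalg.lstsq(A, rhs, rcond=None)
            v = np.zeros(n)
            v[list(fixed)] = bounds_choice
            v[free] = sol
            if np.abs(S @ v).max() > 1e-8:
                continue
            if np.any(v < model.lb - 1e-9) or np.any(v > model.ub + 1e-9):
                continue
            best = max(best, v[obj_idx])
    return best


def exhaustive_signed_sets(disc, target, regulators, max_set_size, min_support):
    """All signed regulator subsets meeting the match-support threshold,
    by direct enumeration (no level-wise structure)."""
    t = disc.loc[target].to_numpy()
    nz = t != 0
    if not nz.any():
        return set()
    out = set()
    regs = sorted(regulators & set(disc.index))
    for size in range(1, max_set_size + 1):
        for combo in combinations(regs, size):
            for signs in product([+1, -1], repeat=size):
                parts = [s * disc.loc[r].to_numpy() for r, s in zip(combo, signs)]
                state = np.min(parts, axis=0)
                support = float(np.mean(state[nz] == t[nz]))
                if support >= min_support:
                    coact = frozenset(r for r, s in zip(combo, signs) if s == +1)
                    corep = frozenset(r for r, s in zip(combo, signs) if s == -1)
                    out.add((coact, corep))
    return out
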