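"""Simplified local-GRN inference (hLICORN-style).

For each target gene the procedure (i) mean-centers and discretizes
expression into {-1, 0, +1} at a threshold, (ii) enumerates small signed
regulator sets whose combined discrete signal — the elementwise min over
coactivator states and negated corepressor states — matches the target's
discrete state in a sufficient fraction of the samples where the target is
non-neutral, and (iii) scores each candidate by the R^2 of an ordinary
least-squares fit of the continuous target expression on two synthetic
covariates (min over coactivators' expression, min over corepressors').
The candidate with the best merged score (R^2, optionally blended with
external evidence scores) contributes its signed edges to the network.

This is a deliberate simplification of hLICORN: enumeration is plain
level-wise up to ``max_set_size`` with no support-based pruning, because
the match-support statistic is not anti-monotone under min-combination —
pruning could silently drop satisfying sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .types import RegulatoryNetwork

__all__ = [
    "discretize",
    "mine_coregulators",
    "score_local_grn",
    "LocalGRNCandidate",
    "infer_network",
]


def discretize(
    expr: pd.DataFrame,
    threshold: float = 1.0,
    per_gene_sd: bool = False,
) -> pd.DataFrame:
    """Center each gene and threshold into {-1, 0, +1}.

    Values above +threshold map to +1, below -threshold to -1, else 0.
    With ``per_gene_sd`` the threshold is expressed in units of each gene's
    standard deviation (genes with zero spread stay all-zero).
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    centered = expr.sub(expr.mean(axis=1), axis=0)
    if per_gene_sd:
        sd = centered.std(axis=1, ddof=1)
        cut = threshold * sd.to_numpy()[:, None]
        cut = np.where(cut > 0, cut, np.inf)  # constant genes -> all zero
    else:
        cut = threshold
    vals = centered.to_numpy()
    disc = np.zeros_like(vals, dtype=int)
    disc[vals > cut] = 1
    disc[vals < -cut] = -1
    out = pd.DataFrame(disc, index=expr.index, columns=expr.columns)
    out.attrs["threshold"] = threshold
    out.attrs["per_gene_sd"] = per_gene_sd
    return out


def _combined_state(disc: pd.DataFrame, coact: tuple[str, ...],
                    corep: tuple[str, ...]) -> np.ndarray:
    parts = [disc.loc[r].to_numpy() for r in coact]
    parts += [-disc.loc[r].to_numpy() for r in corep]
    return np.min(parts, axis=0)


def mine_coregulators(
    disc: pd.DataFrame,
    target: str,
    regulators: set[str],
    max_set_size: int = 2,
    min_support: float = 0.5,
) -> list[tuple[frozenset[str], frozenset[str], float]]:
    """Enumerate signed regulator sets matching the target's discrete state.

    Support of a candidate (A, R) is the fraction of samples with nonzero
    target state where min(states of A, negated states of R) equals the
    target state.  All signed subsets with 1..max_set_size regulators are
    enumerated level-wise; candidates with support >= ``min_support`` are
    returned sorted by (support desc, size, lexicographic).  A target that
    is never non-neutral, or no regulator matching, yields an empty list.
    """
    if target in regulators:
        raise ValueError(f"target {target!r} is itself listed as a regulator")
    if max_set_size < 1:
        raise ValueError("max_set_size must be >= 1")
    regs = sorted(regulators & set(disc.index))
    t = disc.loc[target].to_numpy()
    nz = t != 0
    if not nz.any() or not regs:
        return []
    t_nz = t[nz]
    out = []
    for size in range(1, max_set_size + 1):
        for combo in combinations(regs, size):
            # each member is independently a coactivator or corepressor
            for mask in range(2 ** size):
                coact = tuple(r for k, r in enumerate(combo) if not mask >> k & 1)
                corep = tuple(r for k, r in enumerate(combo) if mask >> k & 1)
                state = _combined_state(disc, coact, corep)[nz]
                support = float(np.mean(state == t_nz))
                if support >= min_support:
                    out.append((frozenset(coact), frozenset(corep), support))
    out.sort(key=lambda c: (-c[2], len(c[0]) + len(c[1]),
                            tuple(sorted(c[0])), tuple(sorted(c[1]))))
    return out


@dataclass
class LocalGRNCandidate:
    """One scored signed regulator set for a target gene."""

    target: str
    coactivators: frozenset[str]
    corepressors: frozenset[str]
    support: float
    r2: float
    merged_score: float

    def __post_init__(self) -> None:
        overlap = self.coactivators & self.corepressors
        if overlap:
            raise ValueError(f"regulators in both classes: {sorted(overlap)}")


def score_local_grn(
    expr: pd.DataFrame,
    target: str,
    coactivators: frozenset[str] | set[str],
    corepressors: frozenset[str] | set[str],
) -> float:
    """R^2 of OLS of the target on min-combined regulator expression.

    Covariates: elementwise min over the coactivators' expression and,
    separately, over the corepressors' (an empty class omits its
    covariate); an intercept is always included so R^2 is the usual
    coefficient of determination, clipped to [0, 1].
    """
    y = expr.loc[target].to_numpy(float)
    cols = []
    if coactivators:
        cols.append(np.min(expr.loc[sorted(coactivators)].to_numpy(float), axis=0))
    if corepressors:
        cols.append(np.min(expr.loc[sorted(corepressors)].to_numpy(float), axis=0))
    if not cols:
        raise ValueError("candidate has no regulators")
    X = np.column_stack([np.ones_like(y)] + cols)
    if len(y) < X.shape[1] + 1:
        raise ValueError(
            f"{len(y)} samples are too few for {X.shape[1]} coefficients"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return float(np.clip(r2, 0.0, 1.0))


def infer_network(
    expr: pd.DataFrame,
    regulators: set[str],
    *,
    threshold: float = 1.0,
    per_gene_sd: bool = True,
    max_set_size: int = 2,
    min_support: float = 0.6,
    evidence: dict[tuple[str, str], float] | None = None,
    evidence_weight: float = 0.0,
    min_score: float = 0.0,
    targets: set[str] | None = None,
) -> RegulatoryNetwork:
    """Infer a signed network by per-target best-candidate selection.

    For every target (every non-regulator gene unless ``targets`` is
    given), candidates from :func:`mine_coregulators` are scored by
    :func:`score_local_grn`; the merged score is
    ``(1 - w) * r2 + w * mean(edge evidence)`` with ``w =
    evidence_weight`` (missing evidence counts 0).  The maximum-score
    candidate is selected, ties broken by smallest regulator count then
    lexicographically, and its signed edges added to the network.
    Deterministic given its inputs.
    """
    if not regulators <= set(expr.index):
        missing = regulators - set(expr.index)
        raise ValueError(f"regulators absent from expression matrix: {sorted(missing)}")
    if not 0.0 <= evidence_weight <= 1.0:
        raise ValueError("evidence_weight must be in [0, 1]")
    evidence = evidence or {}
    disc = discretize(expr, threshold, per_gene_sd=per_gene_sd)
    if targets is None:
        targets = set(expr.index) - regulators
    net = RegulatoryNetwork()
    for target in sorted(targets):
        mined = mine_coregulators(disc, target, regulators,
                                  max_set_size=max_set_size,
                                  min_support=min_support)
        best: LocalGRNCandidate | None = None
        for coact, corep, support in mined:
            r2 = score_local_grn(expr, target, coact, corep)
            members = coact | corep
            ev = float(np.mean([evidence.get((r, target), 0.0) for r in members]))
            merged = (1.0 - evidence_weight) * r2 + evidence_weight * ev
            cand = LocalGRNCandidate(target, coact, corep, support, r2, merged)
            if best is None or _candidate_key(cand) < _candidate_key(best):
                best = cand
        if best is None or best.merged_score < min_score:
            continue
        for reg in best.coactivators:
            net.add_edge(reg, target, +1)
        for reg in best.corepressors:
            net.add_edge(reg, target, -1)
    return net


def _candidate_key(c: LocalGRNCandidate):
    return (
        -c.merged_score,
        len(c.coactivators) + len(c.corepressors),
        tuple(sorted(c.coactivators)),
        tuple(sorted(c.corepressors)),
    )
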