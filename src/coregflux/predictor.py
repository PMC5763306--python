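"""Linear prediction of metabolic-gene expression from regulator influences.

On a large background compendium, each target gene's expression is modelled
as a linear combination of the influences of its regulators,

    x_ik = sum_{j in Pa(i)} beta_j * I_jk        (no intercept by default),

so that in a new condition only the influence scores — not the full
expression profile — are needed to predict the activity of the metabolic
genes.  Fitting is per-gene ordinary least squares; an intercept and a
ridge penalty are available as options since real log-expression has a
nonzero baseline and large regulator sets can be ill-posed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import RegulatoryNetwork

__all__ = ["LinearInfluenceModel", "fit", "predict"]


@dataclass
class LinearInfluenceModel:
    """Per-gene regression coefficients on regulator influences.

    ``coefficients[gene][regulator]`` holds beta_j for j in Pa(gene);
    ``intercepts`` is populated only when fitted with an intercept.
    ``skipped`` records genes that could not be modelled and why.
    """

    coefficients: dict[str, dict[str, float]]
    intercepts: dict[str, float] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    n_train_samples: dict[str, int] = field(default_factory=dict)
    residual_sd: dict[str, float] = field(default_factory=dict)

    @property
    def genes(self) -> list[str]:
        return list(self.coefficients)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "coefficients": self.coefficients,
            "intercepts": self.intercepts,
            "skipped": self.skipped,
            "n_train_samples": self.n_train_samples,
            "residual_sd": self.residual_sd,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "LinearInfluenceModel":
        payload = json.loads(Path(path).read_text())
        return cls(**payload)


def fit(
    net: RegulatoryNetwork,
    infl_train: pd.DataFrame,
    expr_train: pd.DataFrame,
    targets: set[str] | None = None,
    intercept: bool = False,
    ridge: float = 0.0,
) -> LinearInfluenceModel:
    """Fit per-gene OLS of expression on the influences of Pa(gene).

    Samples are the columns shared between the two matrices; for each gene,
    samples where any required influence is undefined (NaN) are dropped.
    Genes with no regulator in the network, with no regulator present in
    the influence matrix, or with fewer usable samples than coefficients+1
    are skipped and recorded.  A rank-deficient design falls back to the
    minimum-norm solution with a warning.
    """
    samples = [s for s in expr_train.columns if s in set(infl_train.columns)]
    if not samples:
        raise ValueError("no shared samples between influence and expression matrices")
    if targets is None:
        targets = set(expr_train.index)
    model = LinearInfluenceModel(coefficients={})
    infl = infl_train[samples]
    for gene in sorted(targets):
        if gene not in expr_train.index:
            model.skipped[gene] = "not in expression matrix"
            continue
        pa = sorted(net.regulators_of(gene) & set(infl.index))
        if not pa:
            model.skipped[gene] = "no regulators in network/influence matrix"
            continue
        X = infl.loc[pa].to_numpy(float).T  # samples x |Pa|
        y = expr_train.loc[gene, samples].to_numpy(float)
        keep = ~np.isnan(X).any(axis=1) & ~np.isnan(y)
        X, y = X[keep], y[keep]
        n_coef = len(pa) + (1 if intercept else 0)
        if len(y) < n_coef + 1:
            model.skipped[gene] = (
                f"too few samples ({len(y)}) for {n_coef} coefficients"
            )
            continue
        D = np.column_stack([np.ones(len(y)), X]) if intercept else X
        if ridge > 0.0:
            beta = np.linalg.solve(D.T @ D + ridge * np.eye(D.shape[1]), D.T @ y)
        else:
            beta, _, rank, _ = np.linalg.lstsq(D, y, rcond=None)
            if rank < D.shape[1]:
                warnings.warn(
                    f"rank-deficient design for gene {gene!r}; "
                    "minimum-norm coefficients returned",
                    RuntimeWarning,
                    stacklevel=2,
                )
        if intercept:
            model.intercepts[gene] = float(beta[0])
            coef = beta[1:]
        else:
            coef = beta
        model.coefficients[gene] = {r: float(b) for r, b in zip(pa, coef)}
        resid = y - D @ beta
        model.n_train_samples[gene] = int(len(y))
        dof = max(len(y) - D.shape[1], 1)
        model.residual_sd[gene] = float(np.sqrt(resid @ resid / dof))
    return model


def predict(model: LinearInfluenceModel, infl_context: pd.DataFrame) -> pd.DataFrame:
    """Predict expression for every modelled gene in the context samples.

    The context influences must come from the same network the model was
    trained with.  Where a required regulator's influence is undefined in a
    sample, that gene/sample prediction is NaN (treated downstream as
    "expression not available" and discarded from GPR rules).
    """
    genes = model.genes
    out = np.full((len(genes), infl_context.shape[1]), np.nan)
    infl_index = set(infl_context.index)
    for i, gene in enumerate(genes):
        coef = model.coefficients[gene]
        if not set(coef) <= infl_index:
            continue  # regulator never scored in this context
        X = infl_context.loc[sorted(coef)].to_numpy(float)
        b = np.array([coef[r] for r in sorted(coef)])
        pred = b @ X
        if gene in model.intercepts:
            pred = pred + model.intercepts[gene]
        out[i, :] = pred  # NaN influences propagate to NaN predictions
    return pd.DataFrame(out, index=genes, columns=infl_context.columns)
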