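"""Per-sample regulator influence scores.

The influence of regulator *j* in sample *k* is the Welch two-sample
statistic comparing, within that sample, the expression of the regulator's
activated targets against its repressed targets:

    I_jk = (mean(A) - mean(R)) / sqrt(s_A^2/n_A + s_R^2/n_R)

with unbiased sample variances and the set sizes as n.  A strongly positive
influence means the activated program is on and the repressed program off —
a low-dimensional, noise-robust summary of the regulator's transcriptional
activity that downstream stages use in place of raw expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .types import RegulatoryNetwork

__all__ = ["compute_influence"]


def compute_influence(
    net: RegulatoryNetwork,
    expr: pd.DataFrame,
    min_targets: int = 2,
    center_genes: bool = False,
    clamp: float = 1e6,
) -> pd.DataFrame:
    """Compute the regulators x samples influence matrix.

    Parameters
    ----------
    net
        Signed regulatory network; targets absent from ``expr`` are dropped
        from the activated/repressed sets before computing.
    expr
        Genes x samples expression matrix (log scale by convention).
    min_targets
        Minimum surviving targets required in *each* class; entries for
        regulators below this are undefined (NaN).  The default of 2 is the
        smallest size with a defined sample variance.
    center_genes
        If set, each gene is mean-centered across samples first.
    clamp
        Zero-variance saturation: when both class variances are exactly 0
        but the means differ, the statistic is +/-inf; such entries are
        clamped to ``+/-clamp`` with a warning so downstream regressions
        stay finite.  Equal means with zero variances give 0.

    Returns
    -------
    pandas.DataFrame
        Regulators x samples; NaN marks undefined entries.
    """
    if min_targets < 2:
        raise ValueError("min_targets must be >= 2 (sample variance needs n >= 2)")
    values = expr.to_numpy(float)
    if center_genes:
        values = values - values.mean(axis=1, keepdims=True)
    gene_pos = {g: i for i, g in enumerate(expr.index)}

    regulators = sorted(net.regulators)
    out = np.full((len(regulators), expr.shape[1]), np.nan)
    n_clamped = 0
    for i, reg in enumerate(regulators):
        a_idx = [gene_pos[g] for g in net.activated.get(reg, set()) if g in gene_pos]
        r_idx = [gene_pos[g] for g in net.repressed.get(reg, set()) if g in gene_pos]
        if len(a_idx) < min_targets or len(r_idx) < min_targets:
            continue
        A, R = values[a_idx, :], values[r_idx, :]
        diff = A.mean(axis=0) - R.mean(axis=0)
        se2 = A.var(axis=0, ddof=1) / len(a_idx) + R.var(axis=0, ddof=1) / len(r_idx)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = diff / np.sqrt(se2)
        zero_se = se2 == 0
        stat[zero_se & (diff == 0)] = 0.0
        saturated = zero_se & (diff != 0)
        if saturated.any():
            n_clamped += int(saturated.sum())
            stat[saturated] = np.sign(diff[saturated]) * clamp
        out[i, :] = stat
    if n_clamped:
        warnings.warn(
            f"{n_clamped} influence entries had zero variance in both target "
            f"classes; clamped to +/-{clamp:g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return pd.DataFrame(out, index=regulators, columns=expr.columns)
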