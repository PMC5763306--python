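"""Readers and writers for the external formats.

Expression matrices and regulatory networks travel as TSV; metabolic models
as SBML Level 3 + FBC (via cobrapy) or as a two-file tabular layout defined
by this project:

* ``reactions.tsv`` — columns ``reaction``, ``lb``, ``ub``, ``gpr``
  (boolean rule string, may be empty) and ``objective`` (0/1, exactly one 1);
* ``stoichiometry.tsv`` — triplet columns ``reaction``, ``metabolite``,
  ``coefficient``.

Exchange reactions are detected structurally (single nonzero stoichiometric
entry) in both formats, overridable with an explicit list.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .gpr import parse_gpr
from .types import (
    MetabolicModel,
    RegulatoryNetwork,
    ValidationError,
    detect_exchange_reactions,
)

__all__ = [
    "read_expression",
    "write_expression",
    "read_network",
    "write_network",
    "read_metabolic_model",
    "write_metabolic_model",
    "read_regulator_list",
]


class FormatError(ValueError):
    """A file does not parse under the declared format."""


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, aggregate_duplicates: bool = False) -> pd.DataFrame:
    """Read a genes x samples expression TSV (header = sample ids,
    first column = gene ids).

    Duplicate gene ids are rejected unless ``aggregate_duplicates`` is set,
    in which case duplicated rows are averaged (replicate probes mapping to
    one ORF).  Missing/non-numeric cells raise with their coordinates.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression file") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"{path}: expression matrix has no genes or no samples")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: non-numeric value at gene {gene!r}, sample {col!r}"
            )
        if coerced.isna().any():
            gene = df.index[coerced.isna().to_numpy().nonzero()[0][0]]
            raise FormatError(f"{path}: missing value at gene {gene!r}, sample {col!r}")
        df[col] = coerced
    if df.index.has_duplicates:
        if aggregate_duplicates:
            df = df.groupby(level=0, sort=False).mean()
        else:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"{path}: duplicated gene ids {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated sample ids {dups}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df.astype(float)


def write_expression(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Regulatory networks
# ---------------------------------------------------------------------------


def read_network(path: str | Path) -> RegulatoryNetwork:
    """Read a signed network TSV with columns regulator, target, sign
    (+1/-1) and an optional 4th evidence-score column in [0, 1]."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty network file") from exc
    if df.shape[1] not in (3, 4):
        raise FormatError(f"{path}: expected 3 or 4 columns, got {df.shape[1]}")
    net = RegulatoryNetwork()
    for row in df.itertuples(index=False):
        reg, tgt = str(row[0]), str(row[1])
        try:
            sign = int(row[2])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-integer sign {row[2]!r}") from exc
        if sign not in (+1, -1):
            raise FormatError(f"{path}: sign must be +1 or -1, got {sign} "
                              f"for edge ({reg}, {tgt})")
        score = None
        if len(row) == 4 and not (isinstance(row[3], float) and math.isnan(row[3])):
            score = float(row[3])
        try:
            net.add_edge(reg, tgt, sign, score)
        except ValidationError as exc:
            raise ValidationError(f"{path}: {exc}") from exc
    return net


def write_network(net: RegulatoryNetwork, path: str | Path) -> None:
    rows = []
    for reg, tgt, sign in sorted(net.signed_edges()):
        row = {"regulator": reg, "target": tgt, "sign": sign}
        if net.edge_scores:
            row["score"] = net.edge_scores.get((reg, tgt), np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_regulator_list(path: str | Path) -> list[str]:
    """One regulator id per line; blank lines and '#' comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


# ---------------------------------------------------------------------------
# Metabolic models
# ---------------------------------------------------------------------------


def read_metabolic_model(
    path: str | Path,
    format: str | None = None,
    exchange_reactions: Iterable[str] | None = None,
) -> MetabolicModel:
    """Read a metabolic model from SBML (L3+FBC) or the tabular layout.

    ``format`` is ``"sbml"`` or ``"tabular"``; when omitted it is inferred
    (``.xml``/``.sbml`` -> SBML, a directory -> tabular).
    ``exchange_reactions`` overrides structural exchange detection.
    """
    path = Path(path)
    if format is None:
        format = "tabular" if path.is_dir() else "sbml"
    if format == "sbml":
        model = _read_sbml(path)
    elif format == "tabular":
        model = _read_tabular(path)
    else:
        raise ValueError(f"unknown model format {format!r}")
    if exchange_reactions is not None:
        model.exchange = set(exchange_reactions)
    return model


def _read_sbml(path: Path) -> MetabolicModel:
    import cobra.io
    from cobra.util.array import create_stoichiometric_matrix

    if not path.exists():
        raise FileNotFoundError(path)
    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:  # cobra raises heterogeneous errors
        raise FormatError(f"{path}: SBML parse failure: {exc}") from exc
    S = create_stoichiometric_matrix(cmodel)
    reaction_ids = [r.id for r in cmodel.reactions]
    metabolite_ids = [m.id for m in cmodel.metabolites]
    lb = np.array([r.lower_bound for r in cmodel.reactions], float)
    ub = np.array([r.upper_bound for r in cmodel.reactions], float)
    objective = [r.id for r in cmodel.reactions if r.objective_coefficient]
    if len(objective) != 1:
        raise FormatError(
            f"{path}: expected exactly one objective reaction, found {objective}"
        )
    gpr = {}
    for r in cmodel.reactions:
        rule = r.gene_reaction_rule
        if rule:
            gpr[r.id] = parse_gpr(rule)
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lb=lb,
        ub=ub,
        objective_reaction=objective[0],
        gpr=gpr,
        exchange=detect_exchange_reactions(S, reaction_ids),
        name=cmodel.id or path.stem,
    )


def _read_tabular(path: Path) -> MetabolicModel:
    rxn_path, sto_path = path / "reactions.tsv", path / "stoichiometry.tsv"
    for p in (rxn_path, sto_path):
        if not p.exists():
            raise FileNotFoundError(p)
    rxn = pd.read_csv(rxn_path, sep="\t", dtype={"reaction": str})
    sto = pd.read_csv(sto_path, sep="\t", dtype={"reaction": str, "metabolite": str})
    required = {"reaction", "lb", "ub", "gpr", "objective"}
    if not required.issubset(rxn.columns):
        raise FormatError(f"{rxn_path}: missing columns {required - set(rxn.columns)}")
    if not {"reaction", "metabolite", "coefficient"}.issubset(sto.columns):
        raise FormatError(f"{sto_path}: expected reaction/metabolite/coefficient columns")
    reaction_ids = rxn["reaction"].tolist()
    metabolite_ids = sorted(sto["metabolite"].unique().tolist())
    unknown = set(sto["reaction"]) - set(reaction_ids)
    if unknown:
        raise FormatError(f"{sto_path}: stoichiometry for unknown reactions {sorted(unknown)}")
    S = np.zeros((len(metabolite_ids), len(reaction_ids)))
    m_idx = {m: i for i, m in enumerate(metabolite_ids)}
    r_idx = {r: j for j, r in enumerate(reaction_ids)}
    for row in sto.itertuples(index=False):
        S[m_idx[row.metabolite], r_idx[row.reaction]] += float(row.coefficient)
    objective = rxn.loc[rxn["objective"].astype(int) == 1, "reaction"].tolist()
    if len(objective) != 1:
        raise FormatError(f"{rxn_path}: expected exactly one objective flag, got {objective}")
    gpr = {}
    for row in rxn.itertuples(index=False):
        rule = row.gpr
        if isinstance(rule, str) and rule.strip():
            gpr[row.reaction] = parse_gpr(rule)
    return MetabolicModel(
        metabolite_ids=metabolite_ids,
        reaction_ids=reaction_ids,
        S=S,
        lb=rxn["lb"].to_numpy(float),
        ub=rxn["ub"].to_numpy(float),
        objective_reaction=objective[0],
        gpr=gpr,
        exchange=detect_exchange_reactions(S, reaction_ids),
        name=path.name,
    )


def _to_cobra(model: MetabolicModel):
    import cobra

    cmodel = cobra.Model(model.name)
    mets = {m: cobra.Metabolite(m, compartment="c") for m in model.metabolite_ids}
    reactions = []
    for j, rid in enumerate(model.reaction_ids):
        rxn = cobra.Reaction(rid)
        # plain floats: libsbml's SWIG layer rejects numpy scalars
        rxn.lower_bound = float(model.lb[j])
        rxn.upper_bound = float(model.ub[j])
        coeffs = {
            mets[m]: float(model.S[i, j])
            for i, m in enumerate(model.metabolite_ids)
            if model.S[i, j] != 0
        }
        rxn.add_metabolites(coeffs)
        reactions.append(rxn)
    cmodel.add_reactions(reactions)
    for rid, tree in model.gpr.items():
        cmodel.reactions.get_by_id(rid).gene_reaction_rule = str(tree)
    cmodel.objective = model.objective_reaction
    return cmodel


def write_metabolic_model(model: MetabolicModel, path: str | Path,
                          format: str = "sbml") -> None:
    """Write a model as SBML (L3+FBC, via cobrapy) or the tabular layout
    (``path`` is then a directory)."""
    path = Path(path)
    if format == "sbml":
        import cobra.io

        cobra.io.write_sbml_model(_to_cobra(model), str(path))
    elif format == "tabular":
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for j, rid in enumerate(model.reaction_ids):
            rows.append({
                "reaction": rid,
                "lb": model.lb[j],
                "ub": model.ub[j],
                "gpr": str(model.gpr[rid]) if rid in model.gpr else "",
                "objective": int(rid == model.objective_reaction),
            })
        pd.DataFrame(rows).to_csv(path / "reactions.tsv", sep="\t", index=False)
        sto_rows = []
        for j, rid in enumerate(model.reaction_ids):
            for i, mid in enumerate(model.metabolite_ids):
                if model.S[i, j] != 0:
                    sto_rows.append({"reaction": rid, "metabolite": mid,
                                     "coefficient": model.S[i, j]})
        pd.DataFrame(sto_rows).to_csv(path / "stoichiometry.tsv", sep="\t", index=False)
    else:
        raise ValueError(f"unknown model format {format!r}")
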