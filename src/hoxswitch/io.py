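"""Readers and writers for the package's plain-text formats.

* QN models: JSON with ``variables`` (id, name, range_min, range_max,
  target expression string or null, optional clamp) and ``edges``
  (source, target, sign).  Reading validates all structural invariants and
  reports the offending field; write → read round-trips losslessly.
* Specification tables: TSV, first column the phenotype id, then the five
  genotype columns.
* Expression matrices: TSV, first column gene id, header row sample ids,
  values log2(TPM+1).
* Clinical tables: TSV with columns sample, time_days, event (1 = death,
  0 = censored).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Union

import pandas as pd

from .expr import ExpressionError, TargetExpression
from .genotypes import SPEC_COLUMNS, SpecificationTable
from .network import ModelError, QNEdge, QNModel, QNVariable

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Raised for malformed input files, with field-level context."""


# ---------------------------------------------------------------------------
# QN models


def model_from_dict(doc: dict) -> QNModel:
    if not isinstance(doc, dict):
        raise FormatError("model document must be a JSON object")
    for key in ("name", "variables", "edges"):
        if key not in doc:
            raise FormatError(f"model document missing field {key!r}")
    variables = []
    for i, raw in enumerate(doc["variables"]):
        where = f"variables[{i}]"
        if "id" not in raw:
            raise FormatError(f"{where}: missing 'id'")
        target = None
        if raw.get("target") is not None:
            try:
                target = TargetExpression.parse(raw["target"])
            except ExpressionError as exc:
                raise FormatError(f"{where} ({raw['id']}): bad target: {exc}") from exc
        try:
            variables.append(
                QNVariable(
                    id=raw["id"],
                    name=raw.get("name", raw["id"]),
                    range_min=int(raw.get("range_min", 0)),
                    range_max=int(raw.get("range_max", 2)),
                    target=target,
                    clamp=None if raw.get("clamp") is None else int(raw["clamp"]),
                )
            )
        except ModelError as exc:
            raise FormatError(f"{where}: {exc}") from exc
    edges = []
    for i, raw in enumerate(doc["edges"]):
        where = f"edges[{i}]"
        for key in ("source", "target", "sign"):
            if key not in raw:
                raise FormatError(f"{where}: missing {key!r}")
        try:
            edges.append(QNEdge(source=raw["source"], target=raw["target"], sign=raw["sign"]))
        except ModelError as exc:
            raise FormatError(f"{where}: {exc}") from exc
    try:
        return QNModel(name=doc["name"], variables=tuple(variables), edges=tuple(edges))
    except ModelError as exc:
        raise FormatError(str(exc)) from exc


def model_to_dict(model: QNModel) -> dict:
    return {
        "name": model.name,
        "variables": [
            {
                "id": v.id,
                "name": v.name,
                "range_min": v.range_min,
                "range_max": v.range_max,
                "target": None if v.target is None else v.target.source,
                **({"clamp": v.clamp} if v.clamp is not None else {}),
            }
            for v in model.variables
        ],
        "edges": [
            {"source": e.source, "target": e.target, "sign": e.sign} for e in model.edges
        ],
    }


def read_model(path: PathLike) -> QNModel:
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    try:
        return model_from_dict(doc)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_model(model: QNModel, path: PathLike) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Specification tables


def read_specification_table(path: PathLike) -> SpecificationTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in SPEC_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: specification table missing columns {missing}")
    expected: Dict[tuple, int] = {}
    for phen, row in df.iterrows():
        for col in SPEC_COLUMNS:
            try:
                expected[(str(phen), col)] = int(row[col])
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path}: cell ({phen}, {col}) is not an integer level"
                ) from exc
    return SpecificationTable(phenotypes=tuple(str(p) for p in df.index), expected=expected)


def write_specification_table(spec: SpecificationTable, path: PathLike) -> None:
    df = pd.DataFrame(
        {col: [spec.level(p, col) for p in spec.phenotypes] for col in SPEC_COLUMNS},
        index=pd.Index(spec.phenotypes, name="phenotype"),
    )
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Expression and clinical tables


def read_expression(path: PathLike) -> pd.DataFrame:
    """Genes x samples matrix of log2(TPM+1) values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise FormatError(f"{path}: expression matrix contains missing values")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: log2(TPM+1) values must be non-negative")
    return df.astype(float)


def write_expression(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.rename_axis("gene").to_csv(path, sep="\t")


def read_clinical(path: PathLike) -> pd.DataFrame:
    """Survival table indexed by sample, columns time_days and event."""
    df = pd.read_csv(path, sep="\t")
    for col in ("sample", "time_days", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: clinical table missing column {col!r}")
    if df["sample"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids in clinical table")
    df = df.set_index("sample")
    if (df["time_days"] < 0).any():
        raise FormatError(f"{path}: negative survival times")
    if not df["event"].isin([0, 1]).all():
        raise FormatError(f"{path}: event must be 0 (censored) or 1 (death)")
    return df[["time_days", "event"]].astype({"time_days": float, "event": int})


def write_clinical(clinical: pd.DataFrame, path: PathLike) -> None:
    clinical.rename_axis("sample").to_csv(path, sep="\t")
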