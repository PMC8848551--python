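"""Model (JSON) and dataset (CSV) serialization.

Models are stored as human-auditable JSON: one entry per node with its id,
arity, ancestor ids (canonical order) and row-major conditional table, plus
the topological ordering and free-form metadata.  Floats round-trip
bit-exactly (shortest-repr encoding on write, exact parse on read), so
write -> read -> write is byte-stable.

Datasets are plain CSV: a header row of node labels and 0-based integer
states, no index column.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cpt import BayesNetModel, ConditionalTable
from .errors import DataIntegrityError, InvalidArgumentError, ModelFormatError
from .graphs import DagStructure
from .sampling import Dataset

__all__ = ["write_model", "read_model", "write_dataset", "read_dataset"]

_SCHEMA_VERSION = 1


def model_to_dict(model: BayesNetModel) -> dict:
    """JSON-ready dictionary form of a model."""
    nodes = []
    for v in range(model.n_nodes):
        table = model.tables[v]
        nodes.append(
            {
                "id": model.labels[v],
                "arity": model.arities[v],
                "ancestors": [model.labels[p] for p in model.parents(v)],
                "table": [list(map(float, row)) for row in table.columns],
            }
        )
    return {
        "schema_version": _SCHEMA_VERSION,
        "nodes": nodes,
        "order": [model.labels[v] for v in model.structure.order],
        "meta": model.meta,
    }


def write_model(model: BayesNetModel, path) -> None:
    """Serialize a model to JSON (lossless float round-trip)."""
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


def model_from_dict(doc: dict) -> BayesNetModel:
    """Rebuild and validate a model from its dictionary form."""
    if not isinstance(doc, dict) or "nodes" not in doc or "order" not in doc:
        raise ModelFormatError("model file must contain 'nodes' and 'order'")
    nodes = doc["nodes"]
    ids = [n.get("id") for n in nodes]
    if len(set(ids)) != len(ids) or any(i is None for i in ids):
        raise ModelFormatError("node ids must be present and unique")
    index = {node_id: i for i, node_id in enumerate(ids)}
    if sorted(doc["order"]) != sorted(ids):
        raise ModelFormatError(
            "'order' must list exactly the node ids once each"
        )
    order = tuple(index[i] for i in doc["order"])
    edges = set()
    arities = []
    tables = []
    for v, n in enumerate(nodes):
        arity = n.get("arity")
        if not isinstance(arity, int) or arity < 2:
            raise ModelFormatError(f"node {n['id']!r}: arity must be an int >= 2")
        arities.append(arity)
        for anc in n.get("ancestors", []):
            if anc not in index:
                raise ModelFormatError(
                    f"node {n['id']!r}: unknown ancestor id {anc!r}"
                )
            edges.add((index[anc], v))
    try:
        structure = DagStructure(
            n_nodes=len(nodes), order=order, edges=frozenset(edges)
        )
    except InvalidArgumentError as exc:
        raise ModelFormatError(f"invalid structure: {exc}") from exc
    for v, n in enumerate(nodes):
        expected_anc = [ids[p] for p in structure.parents(v)]
        if list(n.get("ancestors", [])) != expected_anc:
            raise ModelFormatError(
                f"node {n['id']!r}: ancestors must be listed in canonical "
                f"(topological-position) order {expected_anc}"
            )
        try:
            table = ConditionalTable(
                child_arity=arities[v],
                ancestor_arities=tuple(
                    arities[p] for p in structure.parents(v)
                ),
                columns=np.asarray(n["table"], dtype=float),
            )
        except (InvalidArgumentError, KeyError, ValueError) as exc:
            raise ModelFormatError(f"node {n['id']!r}: {exc}") from exc
        tables.append(table)
    try:
        return BayesNetModel(
            structure=structure,
            arities=tuple(arities),
            tables=tuple(tables),
            labels=tuple(ids),
            meta=doc.get("meta", {}),
        )
    except InvalidArgumentError as exc:
        raise ModelFormatError(str(exc)) from exc


def read_model(path) -> BayesNetModel:
    """Read and validate a model from JSON."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ModelFormatError(f"not valid JSON: {exc}") from exc
    return model_from_dict(doc)


def write_dataset(dataset: Dataset, path) -> None:
    """Write a dataset as CSV: header of node labels, 0-based int states."""
    dataset.to_frame().to_csv(path, index=False)


def read_dataset(path, model: BayesNetModel | None = None) -> Dataset:
    """Read a dataset CSV, optionally validating against a model.

    With a model given, columns are reordered by header match (unknown
    headers are an error) and every state is checked against the node's
    arity, reporting the offending row.
    """
    frame = pd.read_csv(path)
    if frame.shape[0] == 0:
        raise DataIntegrityError(f"{path}: empty dataset (no data rows)")
    if model is not None:
        unknown = [c for c in frame.columns if c not in model.labels]
        missing = [c for c in model.labels if c not in frame.columns]
        if unknown or missing:
            raise DataIntegrityError(
                f"{path}: headers do not match model nodes "
                f"(unknown {unknown}, missing {missing})"
            )
        frame = frame[list(model.labels)]
        values = frame.to_numpy(dtype=np.int64)
        for j, a in enumerate(model.arities):
            bad = np.nonzero((values[:, j] < 0) | (values[:, j] >= a))[0]
            if bad.size:
                raise DataIntegrityError(
                    f"{path}: row {int(bad[0])}: state "
                    f"{int(values[bad[0], j])} of node {model.labels[j]} "
                    f"outside [0, {a})"
                )
    else:
        values = frame.to_numpy(dtype=np.int64)
    return Dataset(values=values, columns=tuple(frame.columns))
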