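"""Readers and writers for the package's on-disk formats.

All tables are UTF-8 tab-separated with explicit identifier columns; floats
are written with ``repr`` precision so every round trip is bitwise exact.

Schemas
-------
phenotypes.tsv : subject_id, age, gender, mean_fd, <one column per metric>
edges.tsv      : subject_id, e000000, e000001, ...  (canonical edge order)
atlas.tsv      : node_id, node_label, network_label
weights.tsv    : edge_id, weight
nodes.tsv      : node_id, weight
cells.tsv      : net_a, net_b, mean_weight, positive_sum_normalized,
                 negative_sum_normalized, edge_count
model.json     : target_name, n_components, training_n, atlas_hash,
                 intercept, coefficients
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Atlas
from .exceptions import SchemaError

__all__ = [
    "read_atlas",
    "read_edges",
    "read_phenotypes",
    "write_atlas",
    "write_edges",
    "write_phenotypes",
    "read_json",
    "write_json",
    "write_weight_table",
    "write_network_cells",
]

_PHENOTYPE_REQUIRED = ("subject_id", "age", "gender", "mean_fd")


def _require_columns(df: pd.DataFrame, required, path) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")


def write_phenotypes(df: pd.DataFrame, path) -> None:
    _require_columns(df, _PHENOTYPE_REQUIRED, path)
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, _PHENOTYPE_REQUIRED, path)
    return df


def write_edges(edges: np.ndarray, subject_ids, path) -> None:
    edges = np.asarray(edges, dtype=float)
    cols = [f"e{k:06d}" for k in range(edges.shape[1])]
    df = pd.DataFrame(edges, columns=cols)
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False)


def read_edges(path) -> tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if "subject_id" not in df.columns:
        raise SchemaError(f"{path}: missing required column 'subject_id'")
    edge_cols = [c for c in df.columns if c.startswith("e") and c[1:].isdigit()]
    if not edge_cols:
        raise SchemaError(f"{path}: no edge columns (e000000, ...) found")
    edge_cols.sort()
    return df[edge_cols].to_numpy(dtype=float), df["subject_id"].tolist()


def write_atlas(atlas: Atlas, path) -> None:
    atlas.to_dataframe().to_csv(path, sep="\t", index=False)


def read_atlas(path) -> Atlas:
    df = pd.read_csv(path, sep="\t")
    return Atlas.from_dataframe(df)


def write_weight_table(values: np.ndarray, path, *, id_col: str = "edge_id") -> None:
    pd.DataFrame(
        {id_col: np.arange(len(values)), "weight": np.asarray(values, dtype=float)}
    ).to_csv(path, sep="\t", index=False)


def write_network_cells(cells: pd.DataFrame, path) -> None:
    cells.to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())
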