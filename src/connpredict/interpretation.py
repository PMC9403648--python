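"""Weight-map interpretation at connection, node, and network level.

A fitted model's per-edge coefficient vector (averaged over the 2000 fold
models of a 200 × 10 cross-validation) is the connection-level representation.
The node-level representation sums the weights of every edge incident to each
node.  The network-level representation aggregates edges into the
``K·(K+1)/2`` network-pair cells (36 for eight networks): per cell the mean
weight, plus positive and negative weight sums each normalized by the cell's
edge count so that network size does not dominate.

Similarity between two models' maps is a Pearson correlation with a
permutation null obtained by shuffling the entries of one map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import Atlas, edge_pairs
from .exceptions import IncompatibleMapsError, InvalidParameterError

__all__ = [
    "NetworkCellSummary",
    "OverlapResult",
    "WeightMap",
    "average_maps",
    "network_summary",
    "node_summary",
    "overlap",
]

_LEVELS = ("connection", "node", "network")


@dataclass(frozen=True)
class WeightMap:
    """A weight vector at one spatial level."""

    level: str
    values: np.ndarray
    n_models_averaged: int = 1
    source: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in _LEVELS:
            raise InvalidParameterError(f"level must be one of {_LEVELS}")
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=float).ravel()
        )


@dataclass(frozen=True)
class NetworkCellSummary:
    """Per-network-pair weight aggregation.

    ``cells`` has one row per pair in canonical order with columns
    ``net_a, net_b, mean_weight, positive_sum_normalized,
    negative_sum_normalized, edge_count``.
    """

    cells: pd.DataFrame

    @property
    def mean_weights(self) -> np.ndarray:
        return self.cells["mean_weight"].to_numpy()


@dataclass(frozen=True)
class OverlapResult:
    """Pearson similarity of two weight maps with a permutation p-value."""

    level: str
    r: float
    p: float
    n_perm: int


def average_maps(fold_maps, source: dict | None = None) -> WeightMap:
    """Elementwise mean of fold-level coefficient vectors."""
    if isinstance(fold_maps, np.ndarray) and fold_maps.ndim == 1:
        fold_maps = [fold_maps]
    maps = [np.asarray(m, dtype=float).ravel() for m in fold_maps]
    if len(maps) == 0:
        raise InvalidParameterError("no maps to average")
    length = maps[0].shape[0]
    if any(m.shape[0] != length for m in maps):
        raise InvalidParameterError("fold maps have mixed lengths")
    stacked = np.vstack(maps)
    return WeightMap(
        level="connection",
        values=stacked.mean(axis=0),
        n_models_averaged=stacked.shape[0],
        source=source or {},
    )


def _check_connection_map(wmap: WeightMap, atlas: Atlas) -> None:
    if wmap.level != "connection":
        raise IncompatibleMapsError(f"expected a connection-level map, got {wmap.level}")
    expected = atlas.n_nodes * (atlas.n_nodes - 1) // 2
    if wmap.values.shape[0] != expected:
        raise IncompatibleMapsError(
            f"map length {wmap.values.shape[0]} does not match atlas "
            f"({expected} edges)"
        )


def node_summary(wmap: WeightMap, atlas: Atlas, *, signed: bool = True) -> WeightMap:
    """Per-node sum of incident edge weights.

    With ``signed=True`` (default, matching signed node contributions) raw
    weights are summed, so the node total equals twice the edge total (every
    edge is incident to two nodes).  ``signed=False`` sums absolute weights.
    """
    _check_connection_map(wmap, atlas)
    iu, ju = edge_pairs(atlas.n_nodes)
    w = wmap.values if signed else np.abs(wmap.values)
    out = np.zeros(atlas.n_nodes)
    np.add.at(out, iu, w)
    np.add.at(out, ju, w)
    return WeightMap(
        level="node",
        values=out,
        n_models_averaged=wmap.n_models_averaged,
        source={**wmap.source, "signed": signed},
    )


def network_summary(
    wmap: WeightMap, atlas: Atlas
) -> tuple[NetworkCellSummary, WeightMap]:
    """Aggregate a connection-level map into network-pair cells.

    Per pair: the mean weight over its edges, and the positive and negative
    weight sums each divided by the pair's total edge count (size
    normalization).  The network-level map vector holds the mean values in
    canonical pair order.
    """
    _check_connection_map(wmap, atlas)
    eclass = atlas.edge_class_index()
    n_pairs = atlas.n_network_pairs
    counts = atlas.pair_edge_counts().astype(float)
    w = wmap.values
    total = np.bincount(eclass, weights=w, minlength=n_pairs)
    pos = np.bincount(eclass, weights=np.where(w > 0, w, 0.0), minlength=n_pairs)
    neg = np.bincount(eclass, weights=np.where(w < 0, w, 0.0), minlength=n_pairs)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, total / counts, np.nan)
        pos_norm = np.where(counts > 0, pos / counts, np.nan)
        neg_norm = np.where(counts > 0, neg / counts, np.nan)
    pairs = atlas.network_pairs
    cells = pd.DataFrame(
        {
            "net_a": [p[0] for p in pairs],
            "net_b": [p[1] for p in pairs],
            "mean_weight": mean,
            "positive_sum_normalized": pos_norm,
            "negative_sum_normalized": neg_norm,
            "edge_count": counts.astype(int),
        }
    )
    net_map = WeightMap(
        level="network",
        values=mean,
        n_models_averaged=wmap.n_models_averaged,
        source=dict(wmap.source),
    )
    return NetworkCellSummary(cells), net_map


def overlap(
    map_a: WeightMap,
    map_b: WeightMap,
    *,
    n_perm: int = 10000,
    seed: int = 0,
) -> OverlapResult:
    """Pearson correlation between two same-level maps with permutation p.

    The null randomly permutes the entries of ``map_b`` each iteration; the
    two-sided p-value is ``(1 + #{|null r| >= |r|}) / (1 + n_perm)``.
    """
    if map_a.level != map_b.level:
        raise IncompatibleMapsError(
            f"cannot compare {map_a.level}-level with {map_b.level}-level maps"
        )
    a, b = map_a.values, map_b.values
    if a.shape != b.shape:
        raise IncompatibleMapsError("maps have different lengths")
    if n_perm < 1:
        raise InvalidParameterError("n_perm must be >= 1")
    r_obs = float(np.corrcoef(a, b)[0, 1])
    rng = np.random.default_rng(seed)
    ac = a - a.mean()
    denom_a = np.sqrt((ac**2).sum())
    null = np.empty(n_perm)
    for k in range(n_perm):
        bp = rng.permutation(b)
        bc = bp - bp.mean()
        null[k] = float(ac @ bc / (denom_a * np.sqrt((bc**2).sum())))
    p = (1 + int(np.sum(np.abs(null) >= abs(r_obs)))) / (1 + n_perm)
    return OverlapResult(level=map_a.level, r=r_obs, p=p, n_perm=n_perm)
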