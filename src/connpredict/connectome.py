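"""Connectome construction and atlas bookkeeping.

A functional connectome is the matrix of pairwise Pearson correlations between
parcellated brain regions' time series, Fisher z-transformed and stored as the
vectorized upper triangle.  The canonical edge layout used everywhere in this
package is the row-major upper triangle (``i < j``), 0-based — the ordering
returned by :func:`numpy.triu_indices`.

An :class:`Atlas` assigns every node to exactly one functional network (eight
canonical networks by default: VIS, SMN, DAN, VAN, LIM, FPN, DMN, SUB) and
defines the ``K·(K+1)/2`` unordered network pairs used for network-level weight
summaries — 36 pairs when K = 8.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateInputError,
    InvalidAtlasError,
    InvalidInputError,
)

__all__ = [
    "Atlas",
    "Connectome",
    "ParcellatedTimeSeries",
    "compute_connectome",
    "devectorize",
    "edge_pairs",
    "edge_position",
    "fisher_z",
    "inverse_fisher_z",
    "load_default_atlas",
    "n_edges",
    "vectorize",
]

#: correlations are clipped to ``1 - R_CLIP`` in magnitude before arctanh so
#: that edges stay finite while ordering is preserved
R_CLIP = 1e-7


def n_edges(n_nodes: int) -> int:
    """Number of unique edges (unordered node pairs) in an ``n_nodes`` graph.

    A 246-node parcellation yields 30 135 edges.
    """
    if n_nodes < 2:
        raise InvalidInputError(f"need at least 2 nodes, got {n_nodes}")
    return n_nodes * (n_nodes - 1) // 2


def edge_pairs(n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of each edge in canonical (row-major upper) order."""
    if n_nodes < 2:
        raise InvalidInputError(f"need at least 2 nodes, got {n_nodes}")
    return np.triu_indices(n_nodes, k=1)


def edge_position(i: int, j: int, n_nodes: int) -> int:
    """Vector position of edge ``(i, j)``, ``i < j``, in canonical order."""
    if not 0 <= i < j < n_nodes:
        raise InvalidInputError(f"invalid node pair ({i}, {j}) for {n_nodes} nodes")
    return i * (2 * n_nodes - i - 1) // 2 + (j - i - 1)


def vectorize(matrix: np.ndarray, *, tol: float = 1e-8) -> np.ndarray:
    """Extract the upper-triangle (``i < j``) entries of a symmetric matrix."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise InvalidInputError(f"expected a square matrix, got shape {matrix.shape}")
    if not np.allclose(matrix, matrix.T, atol=tol, rtol=0.0):
        raise InvalidInputError("matrix is not symmetric within tolerance")
    iu, ju = edge_pairs(matrix.shape[0])
    return matrix[iu, ju].copy()


def devectorize(edges: np.ndarray) -> np.ndarray:
    """Rebuild the symmetric matrix from an edge vector; diagonal set to zero."""
    edges = np.asarray(edges, dtype=float)
    m = edges.shape[0]
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise InvalidInputError(f"edge vector of length {m} is not triangular")
    out = np.zeros((n, n))
    iu, ju = edge_pairs(n)
    out[iu, ju] = edges
    out[ju, iu] = edges
    return out


def fisher_z(r: np.ndarray | float, *, clip: float = R_CLIP) -> np.ndarray | float:
    """Fisher z-transform ``arctanh(r)`` with ``|r|`` clipped to ``1 - clip``."""
    return np.arctanh(np.clip(r, -(1.0 - clip), 1.0 - clip))


def inverse_fisher_z(z: np.ndarray | float) -> np.ndarray | float:
    """Inverse of the Fisher transform, ``tanh(z)``."""
    return np.tanh(z)


@dataclass(frozen=True)
class ParcellatedTimeSeries:
    """Node × timepoint activity matrix for one subject."""

    subject_id: str
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise InvalidInputError("time series must be a node × timepoint matrix")
        object.__setattr__(self, "data", data)

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class Connectome:
    """Vectorized Fisher-z connectome for one subject.

    ``edge_values[k]`` is the Fisher-z correlation of the k-th node pair in
    canonical row-major upper-triangle order.
    """

    edge_values: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.edge_values, dtype=float)
        if values.ndim != 1:
            raise InvalidInputError("edge_values must be a 1-d vector")
        if not np.all(np.isfinite(values)):
            raise InvalidInputError("edge values must be finite (clip |r|=1 first)")
        # validates triangular length
        devectorize_len_check(values.shape[0])
        object.__setattr__(self, "edge_values", values)

    @property
    def n_nodes(self) -> int:
        m = self.edge_values.shape[0]
        return int(round((1 + np.sqrt(1 + 8 * m)) / 2))

    @property
    def n_edges(self) -> int:
        return self.edge_values.shape[0]

    def to_matrix(self) -> np.ndarray:
        return devectorize(self.edge_values)


def devectorize_len_check(m: int) -> int:
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n * (n - 1) // 2 != m:
        raise InvalidInputError(f"edge vector of length {m} is not triangular")
    return n


def compute_connectome(ts: ParcellatedTimeSeries) -> Connectome:
    """Pearson-correlate all node pairs and Fisher z-transform.

    ``|r|`` is clipped to ``1 - 1e-7`` before ``arctanh`` so perfectly
    (anti)correlated pairs map to large finite edges.

    Raises
    ------
    DegenerateInputError
        If any node has a constant time series (zero variance), naming it.
    InvalidInputError
        If fewer than 3 timepoints are available.
    """
    if ts.n_timepoints < 3:
        raise InvalidInputError(
            f"need at least 3 timepoints, got {ts.n_timepoints}"
        )
    sd = ts.data.std(axis=1)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        raise DegenerateInputError(
            f"zero-variance time series at node(s) {dead.tolist()} "
            f"for subject {ts.subject_id!r}"
        )
    r = np.corrcoef(ts.data)
    return Connectome(fisher_z(vectorize(r)), subject_id=ts.subject_id)


@dataclass(frozen=True)
class Atlas:
    """Node → network assignment for a parcellation.

    Network order is the order of first appearance in ``networks``; the shipped
    default lists them as VIS, SMN, DAN, VAN, LIM, FPN, DMN, SUB.  Network
    pairs are ordered row-major over the upper triangle *including* the
    diagonal of the K × K network grid, i.e. (0,0), (0,1), ..., (K-1,K-1).
    """

    node_ids: tuple
    node_labels: tuple
    networks: tuple
    _cache: dict = field(default_factory=dict, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not (len(self.node_ids) == len(self.node_labels) == len(self.networks)):
            raise InvalidAtlasError("node_ids, node_labels, networks must align")
        if len(self.node_ids) < 2:
            raise InvalidAtlasError("atlas needs at least 2 nodes")
        for nid, net in zip(self.node_ids, self.networks):
            if net is None or (isinstance(net, float) and np.isnan(net)) or net == "":
                raise InvalidAtlasError(f"node {nid!r} has no network assignment")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def network_names(self) -> tuple:
        if "names" not in self._cache:
            seen: dict = {}
            for net in self.networks:
                seen.setdefault(net, None)
            self._cache["names"] = tuple(seen)
        return self._cache["names"]

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    @property
    def network_index(self) -> np.ndarray:
        """Per-node index into :attr:`network_names`."""
        if "nidx" not in self._cache:
            lut = {name: k for k, name in enumerate(self.network_names)}
            self._cache["nidx"] = np.array([lut[n] for n in self.networks])
        return self._cache["nidx"]

    @property
    def network_sizes(self) -> np.ndarray:
        return np.bincount(self.network_index, minlength=self.n_networks)

    @property
    def network_pairs(self) -> tuple:
        """The K·(K+1)/2 unordered network pairs in canonical order."""
        names = self.network_names
        return tuple(
            (names[a], names[b])
            for a in range(len(names))
            for b in range(a, len(names))
        )

    @property
    def n_network_pairs(self) -> int:
        k = self.n_networks
        return k * (k + 1) // 2

    def pair_position(self, a: int, b: int) -> int:
        """Canonical position of the unordered network pair (a, b)."""
        a, b = min(a, b), max(a, b)
        k = self.n_networks
        return a * k - a * (a - 1) // 2 + (b - a)

    def edge_class_index(self) -> np.ndarray:
        """Per-edge index of its network pair, canonical edge order."""
        if "eclass" not in self._cache:
            iu, ju = edge_pairs(self.n_nodes)
            nidx = self.network_index
            a = np.minimum(nidx[iu], nidx[ju])
            b = np.maximum(nidx[iu], nidx[ju])
            k = self.n_networks
            self._cache["eclass"] = a * k - a * (a - 1) // 2 + (b - a)
        return self._cache["eclass"]

    def pair_edge_counts(self) -> np.ndarray:
        """Edge count per network pair; sums to ``n_edges(n_nodes)``."""
        return np.bincount(self.edge_class_index(), minlength=self.n_network_pairs)

    def edge_classes(self) -> pd.DataFrame:
        """Table of network pairs with their edge counts."""
        pairs = self.network_pairs
        counts = self.pair_edge_counts()
        return pd.DataFrame(
            {
                "net_a": [p[0] for p in pairs],
                "net_b": [p[1] for p in pairs],
                "edge_count": counts,
            }
        )

    def content_hash(self) -> str:
        """Stable hash of the node/network layout, used to guard transfer."""
        h = hashlib.sha256()
        for nid, net in zip(self.node_ids, self.networks):
            h.update(f"{nid}\t{net}\n".encode())
        return h.hexdigest()[:16]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node_id": self.node_ids,
                "node_label": self.node_labels,
                "network_label": self.networks,
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "Atlas":
        for col in ("node_id", "node_label", "network_label"):
            if col not in df.columns:
                raise InvalidAtlasError(f"atlas table missing column {col!r}")
        bad = df["network_label"].isna() | (df["network_label"].astype(str) == "")
        if bad.any():
            rows = df.index[bad].tolist()
            raise InvalidAtlasError(f"unassigned network for node row(s) {rows}")
        return cls(
            node_ids=tuple(df["node_id"].astype(str)),
            node_labels=tuple(df["node_label"].astype(str)),
            networks=tuple(df["network_label"].astype(str)),
        )


def edge_classes(atlas: Atlas) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-edge network-pair index plus the per-pair edge-count table."""
    return atlas.edge_class_index(), atlas.edge_classes()


def load_default_atlas() -> Atlas:
    """Load the packaged 246-node, 8-network atlas.

    The node → network table is a synthetic stand-in with Brainnetome-like
    proportions (210 cortical nodes across the seven Yeo networks plus 36
    subcortical nodes); it defines the default edge space and the 36 network
    pairs but carries no real anatomical labels.
    """
    ref = resources.files("connpredict.data") / "atlas246_8net_synthetic.tsv"
    with ref.open("r") as fh:
        df = pd.read_csv(fh, sep="\t")
    return Atlas.from_dataframe(df)
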