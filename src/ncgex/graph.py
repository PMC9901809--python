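"""Gene interaction graphs: loading, sparsification and connectivity queries.

The interaction graph is an undirected, weighted graph over genes.  Edge
scores follow the STRING convention of integer evidence scores (typically
0-1000); a score threshold turns the weighted graph into the binary
adjacency that defines each gene's neighbourhood, and from that adjacency
the model layers derive their connectivity mask (neighbours plus self) and
the symmetrically normalised adjacency used by graph convolutions.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeightedGeneGraph",
    "BinaryGeneGraph",
    "ThresholdConfig",
    "ConnectivityMask",
    "load_edge_list",
    "save_edge_list",
    "restrict_to_nodes",
    "threshold_graph",
    "build_mask",
    "degree_and_normalize",
]


class GraphFormatError(ValueError):
    """Raised when an edge-list file cannot be parsed as requested."""


class GeneMappingError(KeyError):
    """Raised when an identifier has no entry in a supplied mapping."""


@dataclass
class WeightedGeneGraph:
    """Undirected gene graph with non-negative association scores.

    Parameters
    ----------
    gene_ids : list of str
        Ordered node identifiers; the order fixes the row/column layout of
        every array derived from the graph.
    weights : ndarray of shape (d, d)
        Symmetric score matrix with a zero diagonal.
    """

    gene_ids: list[str]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.weights = np.asarray(self.weights, dtype=float)
        d = len(self.gene_ids)
        if d < 1:
            raise ValueError("graph needs at least one node")
        if len(set(self.gene_ids)) != d:
            raise ValueError("duplicate gene identifiers")
        if self.weights.shape != (d, d):
            raise ValueError(f"weights shape {self.weights.shape} != ({d}, {d})")
        if not np.allclose(self.weights, self.weights.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diagonal(self.weights) != 0):
            raise ValueError("diagonal must be zero (no self-edges)")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.weights, 1)))

    def edge_records(self) -> list[tuple[str, str, float]]:
        """Edges as (node_a, node_b, score) with a < b, lexicographic order."""
        ii, jj = np.nonzero(np.triu(self.weights, 1))
        recs = []
        for i, j in zip(ii, jj):
            a, b = sorted((self.gene_ids[i], self.gene_ids[j]))
            recs.append((a, b, float(self.weights[i, j])))
        recs.sort()
        return recs


@dataclass
class BinaryGeneGraph:
    """Thresholded adjacency with per-node neighbour sets ``N(i)``."""

    gene_ids: list[str]
    adjacency: np.ndarray
    neighbor_sets: list[set[int]] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = list(self.gene_ids)
        self.adjacency = np.asarray(self.adjacency)
        d = len(self.gene_ids)
        if self.adjacency.shape != (d, d):
            raise ValueError("adjacency shape mismatch")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diagonal(self.adjacency) != 0):
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = self.adjacency.astype(np.int8)
        if self.neighbor_sets is None:
            self.neighbor_sets = [
                set(np.nonzero(self.adjacency[i])[0].tolist()) for i in range(d)
            ]

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)


@dataclass
class ThresholdConfig:
    """Score threshold delta; edges with score strictly above delta survive."""

    delta: float = 0.0
    candidate_set: Sequence[float] = ()

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class ConnectivityMask:
    """Binary mask with ``mask[i, j] = 1`` iff ``j in N(i) | {i}``."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask)
        if self.mask.ndim != 2 or self.mask.shape[0] != self.mask.shape[1]:
            raise ValueError("mask must be square")
        if np.any(np.diagonal(self.mask) != 1):
            raise ValueError("mask diagonal must be one (self-connection)")
        if not np.array_equal(self.mask, self.mask.T):
            raise ValueError("mask must be symmetric")
        self.mask = self.mask.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.mask.shape[0]


def load_edge_list(
    path: str | Path | io.TextIOBase,
    id_map: dict[str, str] | None = None,
    weight_column: str | None = None,
) -> WeightedGeneGraph:
    """Read a STRING-style edge list into a :class:`WeightedGeneGraph`.

    The file is whitespace- or tab-delimited with a header line; the first
    two columns name the endpoints and ``weight_column`` selects the score
    column (default: the first column after the endpoints).  Self-edges are
    dropped, duplicate edges keep the maximum score, and edges are
    symmetrised.  ``id_map`` optionally translates raw identifiers (e.g.
    STRING protein ids) to gene symbols and must cover every identifier
    used.
    """
    df = pd.read_csv(path, sep=r"\s+")
    if df.shape[1] < 3:
        raise GraphFormatError("edge list needs two node columns and a score column")
    node_a_col, node_b_col = df.columns[:2]
    if weight_column is None:
        weight_column = df.columns[2]
    if weight_column not in df.columns:
        raise GraphFormatError(f"weight column {weight_column!r} not in header")

    a = df[node_a_col].astype(str)
    b = df[node_b_col].astype(str)
    w = pd.to_numeric(df[weight_column], errors="coerce")
    if w.isna().any():
        raise GraphFormatError(f"non-numeric value in weight column {weight_column!r}")

    if id_map is not None:
        for ident in pd.concat([a, b]).unique():
            if ident not in id_map:
                raise GeneMappingError(f"identifier {ident!r} missing from mapping")
        a = a.map(id_map)
        b = b.map(id_map)

    gene_ids = sorted(set(a) | set(b))
    index = {g: i for i, g in enumerate(gene_ids)}
    d = len(gene_ids)
    weights = np.zeros((d, d))
    for ga, gb, score in zip(a, b, w):
        i, j = index[ga], index[gb]
        if i == j:
            continue  # weighted self-edges are discarded; build_mask re-adds self
        if score > weights[i, j]:
            weights[i, j] = weights[j, i] = score
    return WeightedGeneGraph(gene_ids, weights)


def save_edge_list(
    graph: WeightedGeneGraph,
    path: str | Path,
    weight_column: str = "score",
) -> None:
    """Write the graph in the same edge-list dialect, lexicographic order."""
    with open(path, "w") as fh:
        fh.write(f"node1\tnode2\t{weight_column}\n")
        for a, b, score in graph.edge_records():
            s = int(score) if float(score).is_integer() else score
            fh.write(f"{a}\t{b}\t{s}\n")


def load_id_map(path: str | Path) -> dict[str, str]:
    """Two-column tab-delimited (source_id, gene_symbol) mapping file."""
    df = pd.read_csv(path, sep="\t", header=None, names=["source", "symbol"])
    return dict(zip(df["source"].astype(str), df["symbol"].astype(str)))


def restrict_to_nodes(
    graph: WeightedGeneGraph, keep: Sequence[str]
) -> WeightedGeneGraph:
    """Induced subgraph on ``keep``; node order follows ``keep``."""
    index = {g: i for i, g in enumerate(graph.gene_ids)}
    try:
        idx = [index[g] for g in keep]
    except KeyError as exc:
        raise KeyError(f"gene {exc.args[0]!r} not in graph") from None
    return WeightedGeneGraph(list(keep), graph.weights[np.ix_(idx, idx)])


def threshold_graph(
    graph: WeightedGeneGraph, config: ThresholdConfig | float
) -> BinaryGeneGraph:
    """Binarise: keep edge (i, j) iff ``weights[i, j] > delta`` (strict).

    Scores exactly equal to delta are dropped, so raising the threshold can
    only shrink the edge set.
    """
    if not isinstance(config, ThresholdConfig):
        config = ThresholdConfig(delta=float(config))
    adjacency = (graph.weights > config.delta).astype(np.int8)
    np.fill_diagonal(adjacency, 0)
    return BinaryGeneGraph(graph.gene_ids, adjacency)


def build_mask(graph: BinaryGeneGraph) -> ConnectivityMask:
    """Connectivity mask ``N(i) | {i}``: adjacency with unit diagonal."""
    mask = graph.adjacency.copy()
    np.fill_diagonal(mask, 1)
    return ConnectivityMask(mask)


def degree_and_normalize(graph: BinaryGeneGraph) -> tuple[np.ndarray, np.ndarray]:
    """Self-loop degrees and the symmetrically normalised adjacency.

    Returns ``(deg, P)`` where ``deg[i] = sum_j (A + I)[i, j]`` and
    ``P = D^{-1/2} (A + I) D^{-1/2}``.  The self-loop guarantees every
    degree is at least one, so isolated nodes are safe.
    """
    a_tilde = graph.adjacency.astype(float)
    np.fill_diagonal(a_tilde, 1.0)
    deg = a_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(deg)
    normalized = a_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
    return deg, normalized
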