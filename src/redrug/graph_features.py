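"""Adjacency construction and precomputed neighborhood features.

The encoder never does message passing at train time: instead the
symmetric-normalized adjacency Ã = D^(-1/2) A D^(-1/2) is applied to the
pretrained entity embeddings K times up front, yielding the stack
[X, ÃX, ..., Ã^K X].  Compound-treats-disease edges — the edges the model
is trained to predict — are removed from A before normalization so the
features carry no label leakage.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import scipy.sparse as sp

from .kg_io import KnowledgeGraph, Triple, is_treats_relation

__all__ = [
    "AdjacencyMatrix",
    "NormalizedAdjacency",
    "NeighborhoodFeatures",
    "build_adjacency",
    "normalize_adjacency",
    "neighborhood_features",
    "save_features",
    "load_features",
]


@dataclass
class AdjacencyMatrix:
    """Sparse symmetric binary adjacency with zero diagonal."""

    A: sp.csr_matrix
    n: int


@dataclass
class NormalizedAdjacency:
    """Ã = D^(-1/2) A D^(-1/2); isolated nodes get all-zero rows."""

    A_norm: sp.csr_matrix
    degree: np.ndarray


@dataclass
class NeighborhoodFeatures:
    """stack[k] = Ã^k X; stack[0] is the raw embedding matrix."""

    K: int
    stack: list[np.ndarray]

    @property
    def dim(self) -> int:
        return self.stack[0].shape[1]

    @property
    def n(self) -> int:
        return self.stack[0].shape[0]


def build_adjacency(
    graph: KnowledgeGraph,
    exclude: Callable[[Triple], bool] | None = None,
) -> AdjacencyMatrix:
    """Undirected, binarized adjacency over all non-excluded triples.

    ``exclude`` defaults to the compound-treats-disease relation family
    (the prediction target).  Parallel triples collapse to a single edge;
    self-loops are dropped.
    """
    if exclude is None:
        exclude = lambda t: is_treats_relation(t.relation)
    n = graph.n_entities
    rows, cols = [], []
    for t in graph.triples:
        if exclude(t):
            continue
        u = graph.index[t.head.raw_id]
        v = graph.index[t.tail.raw_id]
        if u == v:
            continue
        rows.extend((u, v))
        cols.extend((v, u))
    data = np.ones(len(rows), dtype=np.float64)
    A = sp.coo_matrix((data, (rows, cols)), shape=(n, n)).tocsr()
    A.data[:] = 1.0  # binarize duplicate entries summed by coo->csr
    return AdjacencyMatrix(A=A, n=n)


def normalize_adjacency(adj: AdjacencyMatrix) -> NormalizedAdjacency:
    """Symmetric degree normalization with a 0-degree-row convention.

    Ã[u,v] = A[u,v] / sqrt(deg(u) deg(v)); rows and columns of isolated
    nodes are left all-zero rather than NaN, so filtered subgraphs that
    strand entities stay well-defined.
    """
    degree = np.asarray(adj.A.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = 1.0 / np.sqrt(degree)
    inv_sqrt[~np.isfinite(inv_sqrt)] = 0.0
    D = sp.diags(inv_sqrt)
    return NormalizedAdjacency(A_norm=(D @ adj.A @ D).tocsr(), degree=degree)


def neighborhood_features(
    norm: NormalizedAdjacency,
    X: np.ndarray,
    K: int = 2,
) -> NeighborhoodFeatures:
    """Iteratively propagate X: stack[k] = Ã · stack[k-1].

    Ã^k is never materialized; each step is one sparse-dense product, so
    the cost is K · nnz(Ã) · dim.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    X = np.asarray(X, dtype=np.float64)
    if X.shape[0] != norm.A_norm.shape[0]:
        raise ValueError(
            f"embedding rows ({X.shape[0]}) do not match adjacency size ({norm.A_norm.shape[0]})"
        )
    stack = [X]
    for k in range(1, K + 1):
        nxt = norm.A_norm @ stack[-1]
        if not np.all(np.isfinite(nxt)):
            raise FloatingPointError(f"non-finite values in propagated features at power k={k}")
        stack.append(nxt)
    return NeighborhoodFeatures(K=K, stack=stack)


def save_features(path: str | Path, graph: KnowledgeGraph, feats: NeighborhoodFeatures) -> None:
    """Archive the feature stack with entity IDs so training can reload it."""
    arrays = {f"power_{k}": m for k, m in enumerate(feats.stack)}
    np.savez(
        Path(path),
        ids=np.asarray([e.raw_id for e in graph.entities]),
        K=np.asarray(feats.K),
        **arrays,
    )


def load_features(path: str | Path) -> tuple[list[str], NeighborhoodFeatures]:
    with np.load(Path(path), allow_pickle=False) as archive:
        K = int(archive["K"])
        ids = [str(x) for x in archive["ids"]]
        stack = [np.asarray(archive[f"power_{k}"], dtype=np.float64) for k in range(K + 1)]
    return ids, NeighborhoodFeatures(K=K, stack=stack)
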