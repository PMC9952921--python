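"""Sample- and feature-side connectivity graphs and their Laplacians.

The factorization penalizes Tr(U^T L_u U) over the gene graph (m x m) and
Tr(V L_v V^T) over the sample graph (n x n), encouraging connected genes to
share loadings and connected samples to share embeddings. Affinities come
from symmetric k-nearest-neighbor graphs on Euclidean distance; binary
weights are the default, with heat-kernel and non-negative-correlation
weights as options. All affinities are non-negative, which keeps the
multiplicative update numerators non-negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ParameterError, ValidationError
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

Weighting = Literal["binary", "heat-kernel", "correlation"]


@dataclass
class ConnectivityGraph:
    """A symmetric non-negative affinity matrix with degree and Laplacian views.

    ``S`` is the p x p affinity (zero diagonal), ``degrees`` the row sums,
    ``D = diag(degrees)`` and ``L = D - S`` the combinatorial graph Laplacian,
    which is positive semidefinite for symmetric non-negative ``S``.
    """

    S: np.ndarray
    node_ids: list[str]

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.ndim != 2 or self.S.shape[0] != self.S.shape[1]:
            raise ValidationError(f"affinity must be square, got {self.S.shape}")
        if len(self.node_ids) != self.S.shape[0]:
            raise ValidationError(
                f"{len(self.node_ids)} node ids for {self.S.shape[0]} nodes"
            )
        if not np.array_equal(self.S, self.S.T):
            raise ValidationError("affinity matrix is not exactly symmetric")
        if (self.S < 0).any():
            raise ValidationError("affinity matrix has negative entries")
        if np.diagonal(self.S).any():
            raise ValidationError("affinity matrix has self-loops")

    @property
    def n_nodes(self) -> int:
        return self.S.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.S.sum(axis=1)

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.degrees)

    @property
    def L(self) -> np.ndarray:
        return self.D - self.S


def _knn_adjacency(dist: np.ndarray, k_neighbors: int) -> np.ndarray:
    """Directed kNN adjacency; ties broken deterministically by lower index."""
    q = dist.shape[0]
    adj = np.zeros((q, q), dtype=bool)
    for j in range(q):
        order = np.argsort(dist[j], kind="stable")
        order = order[order != j][:k_neighbors]
        adj[j, order] = True
    return adj


def build_knn_graph(
    points: np.ndarray,
    k_neighbors: int = 5,
    weighting: Weighting = "binary",
    bandwidth: float | Literal["auto"] = "auto",
    node_ids: list[str] | None = None,
) -> ConnectivityGraph:
    """Build a symmetric kNN graph over the rows of ``points``.

    An edge (i, j) is kept if i is among j's ``k_neighbors`` nearest
    Euclidean neighbors or vice versa (symmetrization by max). Weights:

    binary
        1 on kept edges.
    heat-kernel
        ``exp(-d_ij^2 / sigma^2)`` on kept edges; ``bandwidth='auto'`` sets
        sigma to the median kept-edge distance (scale-free default).
    correlation
        ``max(0, Pearson(x_i, x_j))`` on kept edges; a zero-variance point's
        edges fall back to binary with a logged warning.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    q = points.shape[0]
    if k_neighbors >= q:
        raise ParameterError(f"k_neighbors={k_neighbors} must be < number of points {q}")
    if k_neighbors < 1:
        raise ParameterError("k_neighbors must be >= 1")

    dist = cdist(points, points)
    kept = _knn_adjacency(dist, k_neighbors)
    kept = kept | kept.T

    if weighting == "binary":
        S = kept.astype(float)
    elif weighting == "heat-kernel":
        edge_d = dist[kept]
        if bandwidth == "auto":
            sigma = float(np.median(edge_d)) if edge_d.size else 1.0
            sigma = max(sigma, np.finfo(float).tiny)
        else:
            sigma = float(bandwidth)
            if sigma <= 0:
                raise ParameterError("bandwidth must be positive")
        S = np.where(kept, np.exp(-(dist**2) / sigma**2), 0.0)
    elif weighting == "correlation":
        sd = points.std(axis=1)
        constant = sd == 0
        if constant.any():
            logger.warning(
                "%d zero-variance points: their edges fall back to binary weights",
                int(constant.sum()),
            )
        centered = points - points.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(centered, axis=1)
        safe = np.where(norms > 0, norms, 1.0)
        corr = (centered / safe[:, None]) @ (centered / safe[:, None]).T
        weights = np.maximum(corr, 0.0)
        fallback = constant[:, None] | constant[None, :]
        S = np.where(kept, np.where(fallback, 1.0, weights), 0.0)
    else:
        raise ParameterError(f"unknown weighting {weighting!r}")

    np.fill_diagonal(S, 0.0)
    S = np.maximum(S, S.T)  # exact symmetry despite fp
    if node_ids is None:
        node_ids = [f"node_{i}" for i in range(q)]
    return ConnectivityGraph(S=S, node_ids=list(node_ids))


def laplacian_pair_for(
    X: ExpressionMatrix,
    k_feat: int = 5,
    k_sample: int = 5,
    weighting: Weighting = "binary",
    bandwidth: float | Literal["auto"] = "auto",
) -> tuple[ConnectivityGraph, ConnectivityGraph]:
    """Build the (feature_graph, sample_graph) pair for a matrix.

    The feature graph is m x m over the gene rows (genes as points in
    sample space); the sample graph is n x n over the sample columns
    (samples as points in gene space), so that Tr(U^T L_u U) and
    Tr(V L_v V^T) are well formed for U (m x k) and V (k x n).
    """
    m, n = X.shape
    if k_feat >= m:
        raise ParameterError(f"k_feat={k_feat} must be < number of genes {m}")
    if k_sample >= n:
        raise ParameterError(f"k_sample={k_sample} must be < number of samples {n}")
    feature_graph = build_knn_graph(
        X.values, k_feat, weighting, bandwidth, node_ids=X.gene_ids
    )
    sample_graph = build_knn_graph(
        X.values.T, k_sample, weighting, bandwidth, node_ids=X.sample_ids
    )
    return feature_graph, sample_graph


def write_edge_list(graph: ConnectivityGraph, path: str | Path) -> None:
    """Export the upper-triangle edges as TSV (node_id_1, node_id_2, weight)."""
    rows = []
    i_idx, j_idx = np.nonzero(np.triu(graph.S, k=1))
    for i, j in zip(i_idx, j_idx):
        rows.append((graph.node_ids[i], graph.node_ids[j], graph.S[i, j]))
    pd.DataFrame(rows, columns=["node_id_1", "node_id_2", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path: str | Path, node_ids: list[str]) -> ConnectivityGraph:
    """Import an edge-list TSV (e.g. an externally built PPI-derived graph)."""
    frame = pd.read_csv(path, sep="\t")
    index = {name: i for i, name in enumerate(node_ids)}
    S = np.zeros((len(node_ids), len(node_ids)))
    for a, b, w in frame.itertuples(index=False):
        if str(a) not in index or str(b) not in index:
            raise ValidationError(f"edge references unknown node: {a!r} or {b!r}")
        i, j = index[str(a)], index[str(b)]
        if i == j:
            continue
        S[i, j] = S[j, i] = float(w)
    return ConnectivityGraph(S=S, node_ids=list(node_ids))
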