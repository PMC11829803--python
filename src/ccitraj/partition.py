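"""Louvain partitioning of the cell graph and its PAGA-style abstraction.

The abstraction replaces cells by partitions: nodes are Louvain communities
and the edge weight between partitions i and j is the connectivity ratio

    theta_ij = e_ij / ehat_ij,    ehat_ij = E_total * n_i * n_j / C(n, 2),

the observed inter-partition edge count over the count expected if the
E_total edges were placed uniformly at random over all cell pairs; the
ratio is clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, ClusterMixin


@dataclass
class Partitioning:
    labels: np.ndarray  # per-cell partition id, contiguous from 0
    resolution: float
    modularity: float

    @property
    def n_partitions(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_partitions)


@dataclass
class PartitionGraph:
    """Partitions as nodes; symmetric connectivity matrix theta (zero diagonal)."""

    theta: np.ndarray  # (P, P) symmetric, zero diagonal
    sizes: np.ndarray

    @property
    def n_partitions(self) -> int:
        return len(self.sizes)

    def edges(self):
        P = self.n_partitions
        for i in range(P):
            for j in range(i + 1, P):
                if self.theta[i, j] > 0:
                    yield i, j, self.theta[i, j]


def _to_nx(adj: sparse.spmatrix) -> nx.Graph:
    adj = sparse.csr_matrix(adj)
    g = nx.Graph()
    g.add_nodes_from(range(adj.shape[0]))
    coo = sparse.coo_matrix(sparse.triu(adj, k=1))
    g.add_weighted_edges_from(
        (int(i), int(j), float(v)) for i, j, v in zip(coo.row, coo.col, coo.data) if v > 0
    )
    return g


class LouvainPartitioner(ClusterMixin, BaseEstimator):
    """Louvain community detection on a weighted adjacency matrix.

    Parameters
    ----------
    resolution : float, default 1.0
        Resolution of the modularity objective; higher values give more,
        smaller communities.
    random_state : int
        Seed controlling the (otherwise arbitrary) node scan order.
    """

    def __init__(self, resolution: float = 1.0, random_state: int = 0):
        self.resolution = resolution
        self.random_state = random_state

    def fit(self, X, y=None):
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        adj = sparse.csr_matrix(X)
        if adj.shape[0] == 0:
            raise ValueError("empty graph")
        if (abs(adj - adj.T) > 1e-12 * max(1.0, abs(adj).max())).nnz:
            raise ValueError("adjacency must be symmetric")
        g = _to_nx(adj)
        comms = nx.community.louvain_communities(
            g, weight="weight", resolution=self.resolution, seed=self.random_state
        )
        # stable relabeling: communities ordered by their smallest member
        comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
        labels = np.empty(adj.shape[0], dtype=int)
        for pid, members in enumerate(comms):
            labels[members] = pid
        mod = nx.community.modularity(
            g, [set(c) for c in comms], weight="weight", resolution=self.resolution
        ) if g.number_of_edges() else 0.0
        self.labels_ = labels
        self.modularity_ = float(mod)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def louvain_partition(adj: sparse.spmatrix, resolution: float = 1.0,
                      seed: int = 0) -> Partitioning:
    est = LouvainPartitioner(resolution=resolution, random_state=seed).fit(adj)
    return Partitioning(est.labels_, resolution, est.modularity_)


def paga_connectivity(adj: sparse.spmatrix, part: Partitioning,
                      weighted: bool = False) -> PartitionGraph:
    """Connectivity ratio between partitions on the binary edge support.

    ``weighted=True`` replaces edge counts by summed edge weights in both
    the observed and expected terms.
    """
    labels = np.asarray(part.labels)
    adj = sparse.csr_matrix(adj)
    n = adj.shape[0]
    if len(labels) != n:
        raise ValueError("partitioning does not cover the graph")
    P = part.n_partitions
    sizes = part.sizes()
    if (sizes == 0).any():
        raise ValueError("partition of size 0")

    coo = sparse.coo_matrix(sparse.triu(adj, k=1))
    w = coo.data if weighted else np.ones_like(coo.data)
    e_total = w.sum()
    inter = np.zeros((P, P))
    for i, j, v in zip(labels[coo.row], labels[coo.col], w):
        if i != j:
            inter[i, j] += v
            inter[j, i] += v

    theta = np.zeros((P, P))
    n_pairs = n * (n - 1) / 2.0
    for i in range(P):
        for j in range(i + 1, P):
            expected = e_total * sizes[i] * sizes[j] / n_pairs
            if expected > 0 and inter[i, j] > 0:
                theta[i, j] = theta[j, i] = min(1.0, inter[i, j] / expected)
    return PartitionGraph(theta, sizes)
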