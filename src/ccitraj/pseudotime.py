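"""Diffusion pseudotime on the cell graph, aware of disconnected topologies.

Pseudotime is the random-walk distance from a root cell in diffusion-map
space.  From the symmetric edge weights W the kernel is density-normalised
(Q_ij = W_ij / (d_i d_j), removing the sampling-density bias), row-normalised
into a transition matrix T, and eigendecomposed through its symmetric
conjugate.  The accumulated operator rescales each non-stationary
eigenvector psi_s by lambda_s / (1 - lambda_s); the pseudotime of cell c is
the Euclidean distance between rows of this operator at the root and at c.
Cells outside the root's connected component get +infinity.

The root cell is the highest-entropy cell inside the partition with the
highest stable-state entropy — the most plastic cell of the most
undifferentiated partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator

from .partition import Partitioning


@dataclass
class PseudotimeResult:
    root_cell: int
    pseudotime: np.ndarray  # per-cell, np.inf off the root component
    n_dcs: int


def select_root_cell(entropy: np.ndarray, sse: np.ndarray, part: Partitioning) -> int:
    """Index of the maximal-entropy cell within the maximal-sse partition.

    Ties at either level resolve to the lowest index.
    """
    entropy = np.asarray(entropy, dtype=float)
    sse = np.asarray(sse, dtype=float)
    root_part = int(np.argmax(sse))  # argmax returns the first maximum
    members = np.flatnonzero(part.labels == root_part)
    return int(members[np.argmax(entropy[members])])


def _diffusion_operator(W: np.ndarray, n_dcs: int) -> np.ndarray:
    """Rows of the accumulated diffusion operator for a connected graph."""
    d = W.sum(axis=1)
    d = np.where(d > 0, d, 1.0)
    Q = W / np.outer(d, d)  # density normalisation
    z = Q.sum(axis=1)
    z = np.where(z > 0, z, 1.0)
    inv_sqrt_z = 1.0 / np.sqrt(z)
    S = Q * np.outer(inv_sqrt_z, inv_sqrt_z)  # symmetric conjugate of T
    evals, evecs = np.linalg.eigh(S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # drop the stationary eigenvalue(s); guard numerical lambda >= 1
    keep = evals < 1.0 - 1e-10
    evals, evecs = evals[keep], evecs[:, keep]
    n_use = min(n_dcs, len(evals))
    evals, evecs = evals[:n_use], evecs[:, :n_use]
    psi = evecs * inv_sqrt_z[:, None]  # right eigenvectors of T
    psi /= np.linalg.norm(psi, axis=0, keepdims=True)  # scale-free components
    return psi * (evals / (1.0 - evals))[None, :]


def diffusion_pseudotime(
    adj: sparse.spmatrix | np.ndarray, root: int, n_dcs: int = 10
) -> PseudotimeResult:
    """Diffusion pseudotime from ``root``; +inf for disconnected cells."""
    if n_dcs < 2:
        raise ValueError("n_dcs must be >= 2")
    A = sparse.csr_matrix(adj)
    n = A.shape[0]
    if not 0 <= root < n:
        raise ValueError("root not in graph")
    if (abs(A - A.T) > 1e-12 * max(1.0, abs(A).max())).nnz:
        raise ValueError("adjacency must be symmetric")

    n_comp, comp = connected_components(A, directed=False)
    in_comp = comp == comp[root]
    pt = np.full(n, np.inf)
    pt[root] = 0.0
    if in_comp.sum() == 1:
        warnings.warn("root cell is isolated; all other cells get infinite pseudotime")
        return PseudotimeResult(root, pt, n_dcs)

    idx = np.flatnonzero(in_comp)
    W = A[np.ix_(idx, idx)].toarray()
    M = _diffusion_operator(W, n_dcs)
    local_root = int(np.flatnonzero(idx == root)[0])
    diff = M - M[local_root]
    pt[idx] = np.sqrt((diff**2).sum(axis=1))
    pt[root] = 0.0
    return PseudotimeResult(root, pt, min(n_dcs, M.shape[1]))


class DiffusionPseudotime(BaseEstimator):
    """Estimator form: ``fit(adjacency, root=...)`` sets ``pseudotime_``.

    Parameters
    ----------
    n_dcs : int, default 10
        Number of diffusion components of the accumulated operator.
    """

    def __init__(self, n_dcs: int = 10):
        self.n_dcs = n_dcs

    def fit(self, X, y=None, root: int = 0):
        res = diffusion_pseudotime(X, root, self.n_dcs)
        self.root_cell_ = res.root_cell
        self.pseudotime_ = res.pseudotime
        self.n_dcs_ = res.n_dcs
        return self
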