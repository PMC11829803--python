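"""CCI-augmented fuzzy k-nearest-neighbour cell graph.

Each cell i gets membership probabilities over its k nearest neighbours in
PCA space,

    p_{i|j} = exp(-(d(x_i, x_j) - rho_i) / sigma_i),

with rho_i the distance to the nearest neighbour (so the closest neighbour
always has probability 1, keeping every cell locally connected) and sigma_i
calibrated by binary search so that sum_j p_{i|j} = log2(k) — the smooth-kNN
normalisation used by fuzzy simplicial set constructions.  Directed
memberships are symmetrised by probabilistic union

    p_ij = p_{i|j} + p_{j|i} - p_{i|j} p_{j|i},

and communication augments edge weights additively on the existing support:

    p_hat_ij = p_ij + K * S_ij.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .preprocessing import ExpressionMatrix

_MAX_SIGMA_ITER = 64


@dataclass
class Embedding:
    coords: np.ndarray
    explained_variance: np.ndarray


def pca_embed(matrix: ExpressionMatrix | np.ndarray, n_components: int = 50,
              seed: int = 0) -> Embedding:
    """Top principal-component scores of the (gene-centred) expression matrix."""
    X = matrix.values if isinstance(matrix, ExpressionMatrix) else np.asarray(matrix, float)
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    cap = min(X.shape)
    if n_components > cap:
        warnings.warn(f"n_components={n_components} clamped to {cap}")
        n_components = cap
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    coords = pca.fit_transform(X)
    return Embedding(coords, pca.explained_variance_)


def _calibrate_sigma(dists: np.ndarray, rho: float, target: float) -> tuple[float, bool]:
    """Binary-search sigma so that sum_j exp(-max(0, d_j - rho)/sigma) = target.

    Returns (sigma, converged).  The sum is nondecreasing in sigma; the
    bracket is expanded upward first.  A flat sum (all neighbours
    equidistant) cannot reach the target and saturates at a bracket end.
    """
    shifted = np.maximum(dists - rho, 0.0)

    def total(sig: float) -> float:
        return float(np.exp(-shifted / sig).sum())

    lo, hi = 1e-12, 1.0
    for _ in range(_MAX_SIGMA_ITER):
        if total(hi) >= target:
            break
        hi *= 2.0
    else:
        return hi, False
    for _ in range(_MAX_SIGMA_ITER):
        mid = 0.5 * (lo + hi)
        if total(mid) < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-12 * max(hi, 1.0):
            break
    sigma = 0.5 * (lo + hi)
    return sigma, abs(total(sigma) - target) < 1e-5


def conditional_probabilities(
    emb: Embedding | np.ndarray, k: int = 10
) -> tuple[sparse.csr_matrix, np.ndarray, np.ndarray]:
    """Directed fuzzy-kNN membership matrix with per-cell (rho, sigma).

    Returns ``(p_cond, rho, sigma)`` where ``p_cond[i, j]`` is the membership
    of neighbour j in cell i's fuzzy neighbourhood (zero off the kNN support).
    """
    coords = emb.coords if isinstance(emb, Embedding) else np.asarray(emb, float)
    n = len(coords)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError("k must be < number of cells")
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute").fit(coords)
    dists, idx = nn.kneighbors(coords)
    dists, idx = dists[:, 1:], idx[:, 1:]  # drop self

    rho = dists[:, 0].copy()
    sigma = np.empty(n)
    target = np.log2(k)
    rows, cols, vals = [], [], []
    n_unconverged = 0
    for i in range(n):
        sig, ok = _calibrate_sigma(dists[i], rho[i], target)
        if not ok:
            n_unconverged += 1
        sigma[i] = max(sig, 1e-12)
        p = np.exp(-np.maximum(dists[i] - rho[i], 0.0) / sigma[i])
        rows.extend([i] * k)
        cols.extend(idx[i])
        vals.extend(p)
    if n_unconverged:
        warnings.warn(f"sigma search saturated for {n_unconverged} cells; best value kept")
    p_cond = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return p_cond, rho, sigma


def joint_probabilities(p_cond: sparse.spmatrix) -> sparse.csr_matrix:
    """Probabilistic union p_ij = p_{i|j} + p_{j|i} - p_{i|j} p_{j|i} on the
    union of the two directed supports; symmetric with entries in [0, 1]."""
    p = sparse.csr_matrix(p_cond)
    pt = p.T.tocsr()
    joint = p + pt - p.multiply(pt)
    return sparse.csr_matrix(joint)


def apply_cci_weights(
    p_joint: sparse.spmatrix, S: sparse.spmatrix | None, K: float
) -> sparse.csr_matrix:
    """p_hat = p_joint + K * S restricted to the existing edge support."""
    if K < 0:
        raise ValueError("K must be >= 0")
    p_joint = sparse.csr_matrix(p_joint)
    if S is None or K == 0:
        return p_joint.copy()
    S = sparse.csr_matrix(S)
    if S.shape != p_joint.shape:
        raise ValueError("CCI matrix shape mismatch")
    support = p_joint.copy()
    support.data = np.ones_like(support.data)
    return sparse.csr_matrix(p_joint + S.multiply(support) * K)


class FuzzyKNNGraph(TransformerMixin, BaseEstimator):
    """Transformer from an expression matrix to a weighted cell-graph adjacency.

    ``fit`` computes the PCA embedding, the calibrated conditional
    probabilities and the symmetric joint probabilities; ``transform``
    (and the fitted attribute ``p_hat_``) return the adjacency after CCI
    augmentation with weight ``cci_weight``.

    Parameters
    ----------
    n_pcs : int, default 50
        Number of principal components for the distance space.
    n_neighbors : int, default 10
        Neighbourhood size k of the fuzzy kNN graph.
    cci_weight : float, default 0.0
        Additive weight K of the symmetrised CCI matrix.
    random_state : int
        Seed for the PCA solver (sign convention only; the fit is exact).
    """

    def __init__(self, n_pcs: int = 50, n_neighbors: int = 10, cci_weight: float = 0.0,
                 random_state: int = 0):
        self.n_pcs = n_pcs
        self.n_neighbors = n_neighbors
        self.cci_weight = cci_weight
        self.random_state = random_state

    def fit(self, X, y=None, cci: sparse.spmatrix | None = None):
        emb = pca_embed(X, self.n_pcs, self.random_state)
        self.embedding_ = emb.coords
        self.explained_variance_ = emb.explained_variance
        self.p_cond_, self.rho_, self.sigma_ = conditional_probabilities(emb, self.n_neighbors)
        self.p_joint_ = joint_probabilities(self.p_cond_)
        self.cci_ = cci
        self.p_hat_ = apply_cci_weights(self.p_joint_, cci, self.cci_weight)
        return self

    def transform(self, X=None) -> sparse.csr_matrix:
        return self.p_hat_

    def reweight(self, K: float) -> sparse.csr_matrix:
        """Recompute p_hat for a new CCI weight without redoing the kNN search."""
        return apply_cci_weights(self.p_joint_, self.cci_, K)


def write_edge_list(p_joint: sparse.spmatrix, p_hat: sparse.spmatrix,
                    cell_ids: list[str], path) -> None:
    """Write the upper-triangle edges as TSV (cell_i, cell_j, p_joint, p_hat)."""
    import pandas as pd

    pj = sparse.coo_matrix(sparse.triu(p_hat, k=1))
    pj_lookup = sparse.csr_matrix(p_joint)
    rows = [
        (cell_ids[i], cell_ids[j], pj_lookup[i, j], v)
        for i, j, v in zip(pj.row, pj.col, pj.data)
    ]
    pd.DataFrame(rows, columns=["cell_i", "cell_j", "p_joint", "p_hat"]).to_csv(
        path, sep="\t", index=False
    )
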