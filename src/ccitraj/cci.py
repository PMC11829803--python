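"""Ligand-receptor cell-cell communication scoring.

Communication between cell groups is modelled by the law of mass action with
Hill-type saturation: for a ligand-receptor pair (L, R) and groups i -> j,

    C^k_{i,j} = (Lbar_i * Rbar_j) / (kh + Lbar_i * Rbar_j)

where Lbar_i is the mean ligand expression over the sender group and Rbar_j
the mean receptor expression over the receiver group.  Group-level scores are
projected to single-cell resolution: a sender cell p in group i communicates
with a receiver cell q in group j through pair k only when both cells validly
express (strictly above a threshold, default 1) the ligand resp. receptor;
the per-cell-pair probability P_{p,q} sums C^k over all valid pairs.

When no grouping is supplied, groups come from k-means with the number of
clusters chosen by the Gap statistic (Tibshirani et al. rule).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_random_state

from .preprocessing import ExpressionMatrix


@dataclass
class LigandReceptorTable:
    """Table of ligand-receptor gene pairs.

    Genes absent from the expression matrix simply score zero; they are not
    an error, so a generic resource table can be applied to any dataset.
    """

    pairs: pd.DataFrame  # columns: ligand, receptor, pair_id

    def __post_init__(self) -> None:
        required = {"ligand", "receptor", "pair_id"}
        if not required.issubset(self.pairs.columns):
            raise ValueError(f"LR table must have columns {sorted(required)}")
        if self.pairs["pair_id"].duplicated().any():
            raise ValueError("pair_ids must be unique")

    @classmethod
    def from_csv(cls, path: str | Path) -> "LigandReceptorTable":
        df = pd.read_csv(path)
        if "pair_id" not in df.columns:
            df["pair_id"] = [f"{l}_{r}" for l, r in zip(df["ligand"], df["receptor"])]
        return cls(df[["ligand", "receptor", "pair_id"]])

    def to_csv(self, path: str | Path) -> None:
        self.pairs.to_csv(path, index=False)

    def __len__(self) -> int:
        return len(self.pairs)


class GapKMeans(ClusterMixin, BaseEstimator):
    """K-means with the cluster number selected by the Gap statistic.

    For k = 1..k_max the within-cluster dispersion W_k (k-means inertia) is
    compared against ``n_ref`` reference datasets drawn uniformly over the
    bounding box of the data:  Gap(k) = mean_ref log(W_k^ref) - log(W_k).
    The chosen k is the smallest k with Gap(k) >= Gap(k+1) - s_{k+1}, where
    s_k is the reference standard deviation inflated by sqrt(1 + 1/n_ref).

    Parameters
    ----------
    k_max : int
        Largest cluster number to consider.
    n_ref : int
        Number of uniform reference draws.
    n_pcs : int or None
        If set, cluster on a PCA reduction of the input (the reference
        bounding box is taken in the same PCA space).
    random_state : int
        Seed for k-means and the reference draws.
    """

    def __init__(self, k_max: int = 10, n_ref: int = 20, n_pcs: int | None = 50,
                 random_state: int = 0):
        self.k_max = k_max
        self.n_ref = n_ref
        self.n_pcs = n_pcs
        self.random_state = random_state

    @staticmethod
    def _inertia(X: np.ndarray, k: int, rng_seed: int) -> tuple[float, np.ndarray]:
        if k == 1:
            mu = X.mean(axis=0)
            return float(((X - mu) ** 2).sum()), np.zeros(len(X), dtype=int)
        km = KMeans(n_clusters=k, n_init=5, random_state=rng_seed)
        labels = km.fit_predict(X)
        return float(km.inertia_), labels

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        k_max = min(self.k_max, len(X))
        rng = check_random_state(self.random_state)
        if self.n_pcs is not None and min(X.shape) > self.n_pcs:
            X = PCA(n_components=self.n_pcs, random_state=self.random_state).fit_transform(X)
        lo, hi = X.min(axis=0), X.max(axis=0)

        log_w = np.empty(k_max)
        labels_per_k = []
        for k in range(1, k_max + 1):
            w, lab = self._inertia(X, k, rng.randint(2**31 - 1))
            log_w[k - 1] = np.log(max(w, 1e-300))
            labels_per_k.append(lab)

        log_w_ref = np.empty((self.n_ref, k_max))
        for b in range(self.n_ref):
            ref = rng.uniform(lo, hi, size=X.shape)
            for k in range(1, k_max + 1):
                w, _ = self._inertia(ref, k, rng.randint(2**31 - 1))
                log_w_ref[b, k - 1] = np.log(max(w, 1e-300))

        gap = log_w_ref.mean(axis=0) - log_w
        sk = log_w_ref.std(axis=0) * np.sqrt(1.0 + 1.0 / self.n_ref)

        chosen = k_max
        for k in range(1, k_max):
            if gap[k - 1] >= gap[k] - sk[k]:
                chosen = k
                break
        self.n_clusters_ = chosen
        self.gap_ = gap
        self.sk_ = sk
        self.labels_ = labels_per_k[chosen - 1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def assign_groups(
    matrix: ExpressionMatrix,
    labels=None,
    k_max: int = 10,
    n_ref: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell group labels: provided labels verbatim, else Gap-statistic k-means
    on the (already log-transformed) matrix."""
    if labels is not None:
        labels = np.asarray(labels)
        if len(labels) != matrix.n_cells:
            raise ValueError("label length does not match cell count")
        return labels
    est = GapKMeans(k_max=k_max, n_ref=n_ref, random_state=seed)
    return est.fit_predict(matrix.values)


@dataclass
class ClusterCommunication:
    """Group x group x pair tensor of communication probabilities."""

    C: np.ndarray  # (n_groups, n_groups, n_pairs)
    group_names: list
    pair_ids: list


def cluster_communication(
    matrix: ExpressionMatrix,
    groups: np.ndarray,
    lr: LigandReceptorTable,
    kh: float = 0.5,
) -> ClusterCommunication:
    """Hill-saturated mass-action communication between all ordered group pairs."""
    if kh <= 0:
        raise ValueError("kh must be > 0")
    groups = np.asarray(groups)
    group_names = sorted(pd.unique(groups).tolist())
    for g in group_names:
        if (groups == g).sum() == 0:
            raise ValueError(f"empty group {g}")
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}

    n_g, n_k = len(group_names), len(lr)
    means = np.zeros((n_g, matrix.n_genes))
    for gi, g in enumerate(group_names):
        means[gi] = matrix.values[groups == g].mean(axis=0)

    C = np.zeros((n_g, n_g, n_k))
    for ki, row in enumerate(lr.pairs.itertuples(index=False)):
        li = gene_index.get(row.ligand)
        ri = gene_index.get(row.receptor)
        if li is None or ri is None:
            continue  # absent gene -> zero communication for this pair
        prod = np.outer(means[:, li], means[:, ri])
        C[:, :, ki] = prod / (kh + prod)
    return ClusterCommunication(C, group_names, list(lr.pairs["pair_id"]))


def build_cci_matrix(
    matrix: ExpressionMatrix,
    groups: np.ndarray,
    comm: ClusterCommunication,
    lr: LigandReceptorTable,
    expr_threshold: float = 1.0,
) -> sparse.csr_matrix:
    """Project cluster communication to the directed cells x cells CCI matrix.

    P[p, q] sums C^k over pairs k whose ligand is validly expressed
    (strictly above ``expr_threshold``) in sender p and whose receptor is
    validly expressed in receiver q.  The diagonal is forced to zero.
    """
    if expr_threshold < 0:
        raise ValueError("expr_threshold must be >= 0")
    groups = np.asarray(groups)
    if len(groups) != matrix.n_cells:
        raise ValueError("group labels do not match cell count")
    if comm.C.shape[0] != len(comm.group_names):
        raise ValueError("communication tensor inconsistent with group names")
    gidx = {g: i for i, g in enumerate(comm.group_names)}
    try:
        cell_group = np.array([gidx[g] for g in groups])
    except KeyError as e:  # pragma: no cover
        raise ValueError(f"group {e} missing from communication tensor") from e
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}

    n = matrix.n_cells
    P = np.zeros((n, n))
    for ki, row in enumerate(lr.pairs.itertuples(index=False)):
        li = gene_index.get(row.ligand)
        ri = gene_index.get(row.receptor)
        if li is None or ri is None:
            continue
        senders = matrix.values[:, li] > expr_threshold
        receivers = matrix.values[:, ri] > expr_threshold
        if not senders.any() or not receivers.any():
            continue
        # C^k indexed by (sender group, receiver group) of each valid cell pair
        contrib = comm.C[np.ix_(cell_group, cell_group, [ki])][:, :, 0]
        P += contrib * np.outer(senders, receivers)
    np.fill_diagonal(P, 0.0)
    return sparse.csr_matrix(P)


def symmetrize_cci(P: sparse.spmatrix | np.ndarray, scale: bool = True) -> sparse.csr_matrix:
    """Undirected CCI: S = (P + P.T) / 2, optionally min-max scaled to [0, 1]
    by the global maximum (skipped when the matrix is all zero)."""
    P = sparse.csr_matrix(P)
    if P.shape[0] != P.shape[1]:
        raise ValueError("CCI matrix must be square")
    S = (P + P.T) * 0.5
    if scale and S.nnz:
        m = S.max()
        if m > 0:
            S = S / m
    return sparse.csr_matrix(S)
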