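"""Entropy-based lineage orientation and the maximum spanning arborescence.

Differentiation potency is scored by a functional-group activation entropy:
for each cell, genes are grouped (by a user-supplied annotation, or each gene
its own group), a group's activation a_f is the fraction of its genes
expressed above a threshold, and the entropy is the Shannon entropy of the
normalised activation distribution p_f = a_f / sum a_f.  High entropy means
broad, unconstrained expression — a plastic, uncommitted state; entropy
drops as cells commit.

Each partition is summarised by its "stable-state" entropy: the mean entropy
over the core cells with the lowest entropy (top 25% lowest by default),
which screens out transition-state cells.  Undirected partition edges are
oriented from higher to lower stable-state entropy, and the lineage tree is
the maximum-weight spanning arborescence (Chu-Liu/Edmonds) rooted at the
highest-entropy partition of each connected component.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .partition import PartitionGraph, Partitioning
from .preprocessing import ExpressionMatrix

# ---------------------------------------------------------------------------
# entropy


def cell_entropy(
    matrix: ExpressionMatrix,
    gene_groups: dict[str, str] | None = None,
    threshold: float = 1.0,
) -> np.ndarray:
    """Per-cell functional-group activation entropy (natural log).

    With ``gene_groups`` mapping gene -> group, activation of group f in a
    cell is the fraction of f's genes expressed strictly above ``threshold``;
    without it each gene forms its own group, and the entropy reduces to
    ln(number of expressed genes).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    expressed = matrix.values > threshold
    if gene_groups is None:
        counts = expressed.sum(axis=1)
        ent = np.where(counts > 0, np.log(np.maximum(counts, 1)), 0.0)
        if (counts == 0).any():
            warnings.warn("cells with no expressed gene assigned entropy 0")
        return ent.astype(float)

    groups: dict[str, list[int]] = {}
    for j, g in enumerate(matrix.gene_ids):
        f = gene_groups.get(g)
        if f is not None:
            groups.setdefault(f, []).append(j)
    if not groups:
        raise ValueError("no matrix gene appears in gene_groups")
    act = np.stack(
        [expressed[:, idx].mean(axis=1) for idx in groups.values()], axis=1
    )  # (cells, groups)
    total = act.sum(axis=1, keepdims=True)
    ent = np.zeros(matrix.n_cells)
    ok = total[:, 0] > 0
    if (~ok).any():
        warnings.warn("cells with zero activation in all groups assigned entropy 0")
    p = np.where(total > 0, act / np.where(total > 0, total, 1.0), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    ent[ok] = -plogp[ok].sum(axis=1)
    return ent


def read_gene_groups(path) -> dict[str, str]:
    """Two-column TSV (gene, group), no header required."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "group"], dtype=str)
    if df.iloc[0, 0].lower() == "gene":
        df = df.iloc[1:]
    return dict(zip(df["gene"], df["group"]))


def stable_state_entropy(
    entropy: np.ndarray,
    part: Partitioning,
    core_fraction: float = 0.25,
    aggregate: str = "mean",
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Per-partition stable-state entropy over the lowest-entropy core.

    The core of a partition of size n is its ceil(core_fraction * n)
    lowest-entropy cells (ties broken by cell index).  Returns the
    per-partition values and the core member indices.
    """
    if not 0 < core_fraction <= 1:
        raise ValueError("core_fraction must be in (0, 1]")
    entropy = np.asarray(entropy, dtype=float)
    agg = {"mean": np.mean, "median": np.median}[aggregate]
    values = np.empty(part.n_partitions)
    cores: list[np.ndarray] = []
    for pid in range(part.n_partitions):
        members = np.flatnonzero(part.labels == pid)
        if len(members) == 0:
            raise ValueError(f"empty partition {pid}")
        n_core = math.ceil(core_fraction * len(members))
        order = members[np.lexsort((members, entropy[members]))]
        core = order[:n_core]
        cores.append(core)
        values[pid] = float(agg(entropy[core]))
    return values, cores


# ---------------------------------------------------------------------------
# orientation and arborescence


@dataclass
class LineageTree:
    """Directed forest over partitions: parent -> child edges with weights."""

    root_partitions: set[int]
    edges: list[tuple[int, int, float]] = field(default_factory=list)

    def parents(self) -> dict[int, int]:
        return {c: p for p, c, _ in self.edges}

    def total_weight(self) -> float:
        return sum(w for _, _, w in self.edges)

    def to_edge_frame(self):
        import pandas as pd

        return pd.DataFrame(self.edges, columns=["parent", "child", "theta"])

    def to_dot(self) -> str:
        lines = ["digraph lineage {"]
        for r in sorted(self.root_partitions):
            lines.append(f'  {r} [shape=doublecircle];')
        for p, c, w in self.edges:
            lines.append(f'  {p} -> {c} [label="{w:.3f}"];')
        lines.append("}")
        return "\n".join(lines)


def orient_partition_graph(
    pg: PartitionGraph, sse: np.ndarray
) -> list[tuple[int, int, float]]:
    """Directed partition edges, higher stable-state entropy pointing to lower.

    Exact ties are directed from the lower partition id to the higher.
    Weights are the unchanged connectivity values.
    """
    sse = np.asarray(sse, dtype=float)
    if len(sse) != pg.n_partitions:
        raise ValueError("sse does not cover all partitions")
    directed = []
    for i, j, w in pg.edges():
        if sse[i] > sse[j] or (sse[i] == sse[j] and i < j):
            directed.append((i, j, w))
        else:
            directed.append((j, i, w))
    return directed


def _chu_liu(nodes: list[int], edges: list[tuple[int, int, float]], root: int
             ) -> list[tuple[int, int, float]]:
    """Maximum-weight spanning arborescence rooted at ``root``.

    Classic Chu-Liu/Edmonds: pick each node's best incoming edge; if the
    selection is acyclic it is optimal, otherwise contract a cycle, adjust
    the weights of edges entering it and recurse.  Assumes every non-root
    node is reachable from the root.
    """
    non_root = [v for v in nodes if v != root]
    if not non_root:
        return []
    best_in: dict[int, tuple[int, int, float]] = {}
    for u, v, w in edges:
        if v == root or u == v:
            continue
        if v not in best_in or w > best_in[v][2]:
            best_in[v] = (u, v, w)
    for v in non_root:
        if v not in best_in:
            raise ValueError(f"node {v} has no incoming edge")

    # cycle detection on the best-in-edge selection
    cycle = None
    color = {v: 0 for v in nodes}
    for start in non_root:
        if color[start]:
            continue
        path, v = [], start
        while True:
            if color.get(v, 2) == 1:
                cycle = path[path.index(v):]
                break
            if color.get(v, 2) == 2 or v == root:
                break
            color[v] = 1
            path.append(v)
            v = best_in[v][0]
        for u in path:
            color[u] = 2
        if cycle:
            break
    if cycle is None:
        return [best_in[v] for v in non_root]

    cyc_set = set(cycle)
    cyc_edge_into = {v: best_in[v] for v in cycle}
    super_node = max(nodes) + 1
    new_nodes = [v for v in nodes if v not in cyc_set] + [super_node]
    new_edges: list[tuple[int, int, float]] = []
    # remember how contracted edges map back
    origin: dict[tuple[int, int, float], tuple[int, int, float]] = {}
    for u, v, w in edges:
        if u in cyc_set and v in cyc_set:
            continue
        if v in cyc_set:
            nw = w - cyc_edge_into[v][2]
            e = (u if u not in cyc_set else super_node, super_node, nw)
            if u in cyc_set:
                continue
            origin[e] = (u, v, w)
            new_edges.append(e)
        elif u in cyc_set:
            e = (super_node, v, w)
            origin[e] = (u, v, w)
            new_edges.append(e)
        else:
            e = (u, v, w)
            origin[e] = (u, v, w)
            new_edges.append(e)

    sub = _chu_liu(new_nodes, new_edges, root)
    result: list[tuple[int, int, float]] = []
    entering = None
    for e in sub:
        orig = origin[e]
        if e[1] == super_node:
            entering = orig
        result.append(orig)
    # keep all cycle edges except the one displaced by the entering edge
    assert entering is not None, "contracted cycle unreachable from root"
    for v in cycle:
        if v != entering[1]:
            result.append(cyc_edge_into[v])
    return result


def max_arborescence(
    directed_edges: list[tuple[int, int, float]],
    sse: np.ndarray,
    n_partitions: int | None = None,
) -> LineageTree:
    """Maximum spanning arborescence forest over the directed partition graph.

    Each weakly connected component is rooted at its highest stable-state-
    entropy partition (ties: lowest id).  Nodes a root cannot reach are
    reported as orphan roots of their own subtrees, with a warning.
    """
    sse = np.asarray(sse, dtype=float)
    n = n_partitions if n_partitions is not None else len(sse)
    if any(w < 0 for _, _, w in directed_edges):
        raise ValueError("edge weights must be >= 0")

    # weakly connected components
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v, _ in directed_edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    comps: dict[int, list[int]] = {}
    for v in range(n):
        comps.setdefault(find(v), []).append(v)

    tree = LineageTree(root_partitions=set())
    out_edges = {}
    for u, v, w in directed_edges:
        out_edges.setdefault(u, []).append((u, v, w))

    for members in comps.values():
        remaining = set(members)
        while remaining:
            root = min(remaining, key=lambda v: (-sse[v], v))
            if len(remaining) < len(members):
                warnings.warn(
                    f"partition {root} not reachable from its component root; "
                    "treated as an orphan root"
                )
            # nodes reachable from root within remaining
            reach = {root}
            stack = [root]
            while stack:
                u = stack.pop()
                for _, v, _ in out_edges.get(u, []):
                    if v in remaining and v not in reach:
                        reach.add(v)
                        stack.append(v)
            sub_edges = [
                (u, v, w) for u, v, w in directed_edges if u in reach and v in reach
            ]
            tree.root_partitions.add(root)
            tree.edges.extend(_chu_liu(sorted(reach), sub_edges, root))
            remaining -= reach
    tree.edges.sort()
    return tree


def infer_lineage(
    pg: PartitionGraph, sse: np.ndarray
) -> tuple[LineageTree, list[tuple[int, int, float]]]:
    """Orient the partition graph by entropy and extract the arborescence."""
    directed = orient_partition_graph(pg, sse)
    return max_arborescence(directed, sse, pg.n_partitions), directed
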