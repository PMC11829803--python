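"""Synthetic branching lineages with planted ligand-receptor structure.

The generator emulates an FPKM-scale scRNA-seq snapshot of an asynchronous
differentiation process:

* cells sit uniformly along a rooted segment tree (one trunk; for two or
  more terminal branches the trunk splits at t = 0.5);
* a large pool of "potency" genes is expressed early and switches off at
  gene-specific times, so the expressed-gene count — and with it the
  activation entropy — decreases along true time;
* each segment carries marker genes that ramp up inside the segment (away
  from the segment entry, so expression stays continuous across the branch
  point) and stay on in its descendants;
* for every parent->child segment adjacency, dedicated ligand genes are
  expressed in a stage window around the branch point (so mainly in
  late-parent cells) and the matching receptor genes ramp on inside the
  child, so ligand-receptor communication is informative about lineage
  adjacency without introducing expression steps at the boundary;
* housekeeping genes are expressed everywhere (keeping library complexity
  bounded away from zero), and all expression carries multiplicative
  lognormal noise.

This emulates a smooth, dropout-free expression profile; it does not model
UMI counting noise, dropout or library-size variation beyond the lognormal
term, so downstream results on it speak to the method's logic, not to its
robustness on raw droplet data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cci import LigandReceptorTable
from .lineage import LineageTree
from .preprocessing import ExpressionMatrix

_AMPLITUDE_LOG_MEAN = np.log(20.0)  # FPKM-scale expression amplitude
_AMPLITUDE_LOG_SD = 0.3
_SWITCH_STEEPNESS = 0.03  # width of on/off sigmoids on the t in [0,1] axis
_LR_PAIRS_PER_EDGE = 2
_BRANCH_POINT = 0.5


@dataclass
class SyntheticLineage:
    matrix: ExpressionMatrix
    true_time: np.ndarray
    branch: np.ndarray  # per-cell segment name
    lr_table: LigandReceptorTable
    params: dict = field(default_factory=dict)

    def external_labels(self, n_bins: int = 4) -> np.ndarray:
        """Ordinal stage labels: quantile bins of true time (0 = earliest)."""
        edges = np.quantile(self.true_time, np.linspace(0, 1, n_bins + 1)[1:-1])
        return np.searchsorted(edges, self.true_time, side="right")

    def segment_adjacency(self) -> set[tuple[str, str]]:
        n_branches = self.params["n_branches"]
        if n_branches == 1:
            return set()
        return {("trunk", f"branch_{b}") for b in range(1, n_branches + 1)}

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cell_id": self.matrix.cell_ids,
                "true_time": self.true_time,
                "branch": self.branch,
            }
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


def generate_lineage(
    n_cells: int = 600,
    n_genes: int = 200,
    n_branches: int = 2,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> SyntheticLineage:
    """Branching-lineage expression matrix with ground-truth time and branches.

    ``n_branches`` counts terminal branches: 1 gives a linear lineage, b >= 2
    gives a trunk splitting into b children at t = 0.5.
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    if n_genes < 10 * n_branches:
        raise ValueError("need at least 10 genes per branch")
    n_segments = 1 if n_branches == 1 else n_branches + 1
    if n_cells < 20 * n_segments:
        raise ValueError("too few cells for the requested branch structure")
    rng = np.random.default_rng(seed)

    # --- cell placement ----------------------------------------------------
    t = rng.uniform(0.0, 1.0, size=n_cells)
    if n_branches == 1:
        branch = np.array(["trunk"] * n_cells)
    else:
        branch = np.where(
            t < _BRANCH_POINT,
            "trunk",
            np.array([f"branch_{b}" for b in rng.integers(1, n_branches + 1, n_cells)]),
        ).astype(object)
        for name in ["trunk"] + [f"branch_{b}" for b in range(1, n_branches + 1)]:
            if (branch == name).sum() < 10:
                raise ValueError("a branch received fewer than 10 cells; increase n_cells")
    segment_names = ["trunk"] + (
        [f"branch_{b}" for b in range(1, n_branches + 1)] if n_branches > 1 else []
    )

    # --- gene budget -------------------------------------------------------
    n_edges = len(segment_names) - 1
    n_lr_genes = 2 * _LR_PAIRS_PER_EDGE * n_edges
    n_hk = max(5, int(0.06 * n_genes))
    n_potency = int(0.65 * n_genes)
    n_marker_total = n_genes - n_hk - n_potency - n_lr_genes
    if n_marker_total < 3 * len(segment_names):
        raise ValueError("gene budget too small for markers; increase n_genes")
    marker_per_seg = n_marker_total // len(segment_names)

    def amplitudes(k: int) -> np.ndarray:
        return rng.lognormal(_AMPLITUDE_LOG_MEAN, _AMPLITUDE_LOG_SD, size=k)

    cols: list[np.ndarray] = []
    gene_ids: list[str] = []

    # housekeeping: always on
    cols.append(np.tile(amplitudes(n_hk), (n_cells, 1)))
    gene_ids.extend(f"HK_{i}" for i in range(n_hk))

    # potency pool: on early, off after gene-specific switch times; the off
    # switch is sharp so the expressed-gene count starts falling at t = 0
    tau = rng.uniform(0.0, 1.0, size=n_potency)
    amp = amplitudes(n_potency)
    pot_vals = amp[None, :] * _sigmoid((tau[None, :] - t[:, None]) / (_SWITCH_STEEPNESS / 3))
    cols.append(pot_vals)
    gene_ids.extend(f"POT_{i}" for i in range(n_potency))

    # segment markers: ramp up inside the segment (activation onsets kept away
    # from the segment entry so expression is continuous at the branch point),
    # stay on in descendants
    in_lineage = {}
    for name in segment_names:
        if name == "trunk":
            in_lineage[name] = np.ones(n_cells, dtype=bool)
        else:
            in_lineage[name] = branch == name
    seg_span = {"trunk": (0.0, _BRANCH_POINT if n_branches > 1 else 1.0)}
    for name in segment_names[1:]:
        seg_span[name] = (_BRANCH_POINT, 1.0)
    repressed_used: set[int] = set()
    for name in segment_names:
        t0, t1 = seg_span[name]
        span = t1 - t0
        amp = amplitudes(marker_per_seg)
        if name == "trunk":
            t_on = rng.uniform(t0 + 0.15 * span, t0 + 0.85 * span, size=marker_per_seg)
            ramp = _sigmoid((t[:, None] - t_on[None, :]) / _SWITCH_STEEPNESS)
        else:
            # fate programs ramp linearly from exactly zero at staggered
            # onsets, so expression is continuous across the branch point
            # and the siblings diverge from commitment onwards; each marker
            # activation is paired with the repression of a still-active
            # shared potency gene in this child (commitment both activates
            # the fate program and shuts down the alternative one), which
            # keeps the expressed-gene count — hence entropy — monotone
            t_on = rng.uniform(t0, t0 + 0.5 * span, size=marker_per_seg)
            ramp_len = rng.uniform(0.1, 0.3, size=marker_per_seg)
            ramp = np.clip((t[:, None] - t_on[None, :]) / ramp_len[None, :], 0.0, 1.0)
            still_active = [j for j in np.argsort(tau)[::-1] if j not in repressed_used]
            partners = still_active[:marker_per_seg]
            repressed_used.update(partners)
            child = in_lineage[name]
            for g, on in zip(partners, t_on):
                off = 1.0 - np.clip((t - on) / max(0.02, 0.1 * float(np.mean(ramp_len))), 0, 1)
                pot_vals[child, g] *= off[child]
        cols.append(amp[None, :] * ramp * in_lineage[name][:, None])
        gene_ids.extend(f"MK_{name}_{i}" for i in range(marker_per_seg))

    # ligand/receptor genes per parent->child adjacency: the ligand is a
    # stage bump around the branch point shared by every lineage (peaking in
    # late-parent cells), the receptor ramps on inside the child only
    lr_rows = []
    tb = _BRANCH_POINT
    lig_bump = _sigmoid((t - (tb - 0.15)) / 0.05) * _sigmoid(((tb + 0.15) - t) / 0.05)
    for name in segment_names[1:]:
        child_cells = branch == name
        rec_ramp = np.clip((t - (tb + 0.05)) / 0.15, 0.0, 1.0) * child_cells
        for p in range(_LR_PAIRS_PER_EDGE):
            lig, rec = f"LIG_{name}_{p}", f"REC_{name}_{p}"
            cols.append((amplitudes(1) * lig_bump[:, None]).astype(float))
            gene_ids.append(lig)
            cols.append((amplitudes(1) * rec_ramp[:, None]).astype(float))
            gene_ids.append(rec)
            lr_rows.append((lig, rec, f"{lig}:{rec}"))
    if not lr_rows:  # linear lineage: self-communication pair on housekeeping genes
        lr_rows.append(("HK_0", "HK_1", "HK_0:HK_1"))

    # filler genes to reach the exact budget: low uniform background
    n_fill = n_genes - len(gene_ids)
    if n_fill > 0:
        cols.append(rng.uniform(0.0, 0.5, size=(n_cells, n_fill)))
        gene_ids.extend(f"BG_{i}" for i in range(n_fill))

    values = np.concatenate(cols, axis=1)
    if noise_sd > 0:
        values = values * rng.lognormal(0.0, noise_sd, size=values.shape)
    values[values < 1e-9] = 0.0

    matrix = ExpressionMatrix(
        values,
        [f"cell_{i:05d}" for i in range(n_cells)],
        gene_ids,
    )
    lr = LigandReceptorTable(pd.DataFrame(lr_rows, columns=["ligand", "receptor", "pair_id"]))
    return SyntheticLineage(
        matrix,
        t,
        np.asarray(branch, dtype=object),
        lr,
        {
            "n_cells": n_cells,
            "n_genes": n_genes,
            "n_branches": n_branches,
            "noise_sd": noise_sd,
            "seed": seed,
        },
    )


def generate_null(n_cells: int = 200, n_genes: int = 100, seed: int = 0) -> SyntheticLineage:
    """No-lineage negative control: i.i.d. lognormal noise, random stage labels."""
    if n_cells < 2 or n_genes < 2:
        raise ValueError("sizes must be >= 2")
    rng = np.random.default_rng(seed)
    values = rng.lognormal(np.log(5.0), 1.0, size=(n_cells, n_genes))
    matrix = ExpressionMatrix(
        values, [f"cell_{i:05d}" for i in range(n_cells)], [f"G_{j}" for j in range(n_genes)]
    )
    lr = LigandReceptorTable(
        pd.DataFrame([("G_0", "G_1", "G_0:G_1")], columns=["ligand", "receptor", "pair_id"])
    )
    return SyntheticLineage(
        matrix,
        rng.uniform(0.0, 1.0, size=n_cells),
        np.asarray(["null"] * n_cells, dtype=object),
        lr,
        {"n_cells": n_cells, "n_genes": n_genes, "n_branches": 0, "noise_sd": 1.0, "seed": seed},
    )


def lineage_recovered(
    tree: LineageTree,
    partition_labels: np.ndarray,
    branch: np.ndarray,
    planted: set[tuple[str, str]],
) -> bool:
    """Does an inferred partition tree reproduce the planted segment tree?

    Each partition maps to the set of planted segments with substantial
    presence in it (at least 5 cells and 20% of the partition) — partitions
    straddling the branch point legitimately carry several segments.
    Recovery requires (a) every tree edge to connect partitions sharing a
    segment or linked by a planted parent->child pair, and (b) every planted
    adjacency to be realised, by such an edge or inside a single partition.
    """
    partition_labels = np.asarray(partition_labels)
    branch = np.asarray(branch, dtype=object)
    seg_sets: dict[int, set] = {}
    for pid in np.unique(partition_labels):
        segs, counts = np.unique(branch[partition_labels == pid], return_counts=True)
        n = counts.sum()
        sub = {s for s, c in zip(segs, counts) if c >= max(5, 0.2 * n)}
        seg_sets[int(pid)] = sub if sub else {segs[np.argmax(counts)]}

    def compatible(sp: set, sc: set) -> bool:
        return bool(sp & sc) or any((a, b) in planted for a in sp for b in sc)

    for p, c, _ in tree.edges:
        if not compatible(seg_sets[p], seg_sets[c]):
            return False
    for u, v in planted:
        by_edge = any(
            u in seg_sets[p] and v in seg_sets[c] for p, c, _ in tree.edges
        )
        by_merge = any(u in s and v in s for s in seg_sets.values())
        if not (by_edge or by_merge):
            return False
    return True
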