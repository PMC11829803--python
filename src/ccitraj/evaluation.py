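"""Ordering accuracy of pseudotime against external ordinal labels.

The pseudotime accuracy score (PAS) compares every unordered cell pair with
distinct external labels (cell-type rank, sampling stage, ...): a pair is
concordant when the cell that comes earlier in pseudotime also carries the
earlier label, discordant when it carries the later label, and neutral when
the two pseudotimes are tied (two infinite pseudotimes count as a tie).

    PAS = (concordant - discordant) / comparable  in [-1, 1].

This is Kendall's tau-a restricted to label-distinct pairs, so it is
invariant under any strictly monotone transform of pseudotime.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class PASReport:
    pas: float
    n_comparable: int
    n_concordant: int
    n_discordant: int
    n_tied_pseudotime: int


def pas(pseudotime: np.ndarray, external: np.ndarray) -> PASReport:
    """Pseudotime accuracy score over label-distinct cell pairs."""
    pt = np.asarray(pseudotime, dtype=float)
    lab = np.asarray(external, dtype=float)
    if len(pt) != len(lab):
        raise ValueError("pseudotime and labels differ in length")
    if len(pt) < 2:
        raise ValueError("need at least two cells")

    dl = lab[:, None] - lab[None, :]
    with np.errstate(invalid="ignore"):
        dp = pt[:, None] - pt[None, :]
        sign_p = np.nan_to_num(np.sign(dp))  # inf - inf pairs are pseudotime ties
    sign_l = np.sign(dl)

    iu = np.triu_indices(len(pt), k=1)
    comparable = sign_l[iu] != 0
    m = int(comparable.sum())
    if m == 0:
        raise ValueError("no comparable pairs")
    prod = (sign_p[iu] * sign_l[iu])[comparable]
    conc = int((prod > 0).sum())
    disc = int((prod < 0).sum())
    tied = m - conc - disc
    return PASReport((conc - disc) / m, m, conc, disc, tied)


@dataclass
class SweepResult:
    grid: np.ndarray
    pas_per_k: np.ndarray  # NaN where a run failed
    best_k: float
    best_pas: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"K": self.grid, "PAS": self.pas_per_k})


def default_grid(k_min: float = 0.0, k_max: float = 10.0, k_step: float = 0.1) -> np.ndarray:
    n = int(round((k_max - k_min) / k_step))
    return np.round(k_min + k_step * np.arange(n + 1), 10)


def sweep_cci_weight(model, grid: np.ndarray, external: np.ndarray) -> SweepResult:
    """Rerun the CCI-weighted part of a fitted pipeline over a grid of K.

    ``model`` must be a fitted pipeline exposing ``refit_cci_weight(K)``
    returning a per-cell pseudotime array (the kNN skeleton and the CCI
    matrix are cached inside the model and reused).  Ties in the best PAS
    resolve to the smallest K.
    """
    grid = np.asarray(grid, dtype=float)
    if len(grid) == 0:
        raise ValueError("empty grid")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    scores = np.full(len(grid), np.nan)
    for i, k in enumerate(grid):
        try:
            pt = model.refit_cci_weight(float(k))
            scores[i] = pas(pt, external).pas
        except Exception as e:  # noqa: BLE001 - a single K may legitimately fail
            warnings.warn(f"K={k} failed: {e}")
    if np.all(np.isnan(scores)):
        raise RuntimeError("every K in the sweep failed")
    best_i = int(np.nanargmax(scores))  # nanargmax takes the first maximum
    return SweepResult(grid, scores, float(grid[best_i]), float(scores[best_i]))
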