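# ccitraj

Trajectory inference for single-cell RNA-seq that weights the cell graph
with ligand–receptor cell–cell communication.

Trajectory inference orders cells along differentiation paths ("pseudotime")
from expression similarity alone, which is noisy and usually needs the user
to point out the root of the trajectory. `ccitraj` adds two sources of
biology to fix both problems:

1. **Cell–cell interaction (CCI) weighting.** Cells whose clusters exchange
   ligand–receptor signals are more likely to be developmentally related.
   Cluster-level communication probabilities are projected to a per-cell-pair
   matrix and added to the neighbour-graph edge weights.
2. **Entropy ordering.** A cell's functional-group activation entropy
   measures its differentiation potency: plastic progenitors activate many
   programs (high entropy), committed cells few (low entropy). Partition
   entropy orients the lineage and selects the root automatically — no
   prior biological annotation needed.

## The model

For a ligand–receptor pair *k* = (L, R), communication from cluster *i* to
cluster *j* follows saturating mass action with cluster-mean expressions,

```
C^k_ij = (L̄_i · R̄_j) / (k_h + L̄_i · R̄_j),          k_h = 0.5
```

and projects to cells: `P_pq = Σ_k C^k_ij` over pairs whose ligand is
validly expressed (> 1) in sender *p* ∈ *i* and receptor in receiver
*q* ∈ *j*. The fuzzy kNN graph in 50-PC space uses per-cell calibrated
memberships

```
p_{i|j} = exp(−(d(x_i, x_j) − ρ_i) / σ_i),   Σ_j p_{i|j} = log2(k)
p_ij    = p_{i|j} + p_{j|i} − p_{i|j} p_{j|i}
p̂_ij   = p_ij + K · P_ij
```

with ρ_i the nearest-neighbour distance and K ≥ 0 the CCI weight. The p̂
graph is Louvain-partitioned and abstracted (partition connectivity
θ_ij = observed / expected inter-edges, clipped to [0, 1]); partitions are
ordered by stable-state entropy (mean entropy of the 25 % lowest-entropy
core cells), edges directed high→low entropy, and the lineage tree is the
maximum-weight spanning arborescence (Chu–Liu/Edmonds) rooted at the
highest-entropy partition. Diffusion pseudotime from the highest-entropy
cell handles disconnected graphs by assigning +∞ outside the root's
component. Orderings are scored against external ordinal labels with the
pseudotime accuracy score

```
PAS = (concordant − discordant) / comparable  ∈ [−1, 1],
```

Kendall concordance restricted to label-distinct pairs.

## Worked example

```python
import numpy as np
from ccitraj import CCITrajectory, generate_lineage

sim = generate_lineage(n_cells=600, n_genes=200, n_branches=2,
                       noise_sd=0.2, seed=2)
model = CCITrajectory(cci_weight=0.0, random_state=2)
model.fit(sim.matrix, lr_table=sim.lr_table, external=sim.external_labels())
print("PAS at K=0:", round(model.pas_report_.pas, 4))

res = model.sweep(grid=np.arange(0.0, 11.0, 1.0))
print("best K:", res.best_k, " best PAS:", round(res.best_pas, 4))
print(model.results_frame().head(3).to_string(index=False))
```

prints

```
PAS at K=0: 0.9801
best K: 10.0  best PAS: 0.9919
   cell_id  partition  entropy  pseudotime
cell_00000          0 4.852030  191.111976
cell_00001          0 4.859812  219.265696
cell_00002          1 4.158883 2168.081159
```

Without communication the ordering already scores PAS 0.98 against the
held-out stage labels; adding the CCI term raises it to 0.99. The per-cell
table gives each cell's partition, activation entropy (high = early) and
diffusion pseudotime in arbitrary units (`inf` marks cells disconnected
from the root's graph component).

The same pipeline is available from the shell:

```sh
ccitraj simulate --n-cells 600 --n-genes 200 --seed 2 --out sim/
ccitraj sweep --matrix sim/matrix.mtx --genes sim/genes.txt --cells sim/cells.txt \
              --lr-table sim/lr_pairs.csv --metadata sim/meta.tsv --out out/
ccitraj run   --matrix expr.tsv --lr-table pairs.csv -K 5.4 --resolution 1.4 --out out/
ccitraj pas   --pseudotime out/pseudotime.tsv --metadata meta.tsv
```

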