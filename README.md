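# ncgex

Graph-masked neural networks for landmark-to-target gene expression
inference.

Whole-transcriptome profiling is expensive, so large compendia measure
only ~1,000 *landmark* genes and infer the remaining *target* genes
computationally (the L1000 setting). Fully connected networks do this
well but are order-blind: they ignore which landmark genes are
biologically related. `ncgex` implements the **neighbour-connection
network (NCNN)**, which injects a gene interaction graph (e.g. STRING
co-expression scores) into the first layer as a hard sparsity pattern
with *untied* per-edge weights:

    H_i,m = σ( Σ_k Σ_{j ∈ N(i) ∪ {i}} W_ij^{m,k} X_j,k + b_i^m )

Node `i`'s hidden features depend only on its graph neighbourhood
`N(i) ∪ {i}`, and every (edge, feature) pair has its own trainable
weight — unlike a graph convolution `σ(D̃^{-1/2}ÃD̃^{-1/2} X W1 + X W2)`,
which shares `W1, W2` across all nodes. The NC features are flattened and
fed to a dense head; everything trains with L1 loss, early-stopped on
validation MAE.

The package also provides the comparators (GCN, dense MLP, linear
regression), score-threshold graph sparsification, per-gene MAE
evaluation with gene-wise model comparison, a fully deterministic
synthetic generator of graph-structured expression data, and the
`ncgraph-gex` command line. It targets computational biologists studying
expression inference and anyone probing when graph priors help
regression. Audience-facing formats are plain text: STRING-style edge
lists, TSV/GCT v1.2 expression matrices, tab-delimited reports.

## Worked example

```python
import numpy as np
from ncgex import (SimulationConfig, make_dataset, build_ncnn, build_mlp,
                   TrainConfig, split_data, standardize, train_model,
                   evaluate_mae, compare_genewise)

sim = SimulationConfig(d=30, n_targets=60, n_samples=800, mean_degree=5,
                       rho=0.5, noise_sd=0.1, seed=0)
data = make_dataset(sim)                      # graph + X (800×30) + Y (800×60)
split = split_data(sim.n_samples, (0.8, 0.1, 0.1), seed=0)
(x_tr, x_val, x_te), _ = standardize(data.X[split.train], data.X[split.val],
                                     data.X[split.test])
(y_tr, y_val, y_te), _ = standardize(data.Y[split.train], data.Y[split.val],
                                     data.Y[split.test])
x = np.concatenate([x_tr, x_val, x_te]); y = np.concatenate([y_tr, y_val, y_te])
order = type(split)(np.arange(640), np.arange(640, 720), np.arange(720, 800))
cfg = TrainConfig(learning_rate=3e-3, batch_size=64, max_epochs=60,
                  patience=12, seed=0)

ncnn = build_ncnn(data.graph, sim.n_targets, H=300, L=2, seed=0)
mlp = build_mlp(sim.d, sim.n_targets, H=300, L=2, seed=0)
for model in (ncnn, mlp):
    train_model(model, x, y, order, cfg)
rep_nc = evaluate_mae(ncnn, x_te, y_te, gene_ids=data.target_ids)
rep_mlp = evaluate_mae(mlp, x_te, y_te, gene_ids=data.target_ids)
print(rep_nc.summary())
print(rep_mlp.summary())
print(f"NCNN better on {compare_genewise(rep_nc, rep_mlp).fraction_a_better:.1%} of genes")
```

Output:

```
NCNN: MAE 0.2673 ± 0.0889
MLP: MAE 0.2879 ± 0.0684
NCNN better on 56.7% of genes
```

The summaries are mean ± SD of the per-gene test MAE (in standardized
expression units) across the 60 target genes: on data whose targets truly
are functions of graph neighbourhoods, the graph-masked layer attains the
lower error at matched width (the margin grows with more samples and a
larger gene panel — see the five-seed benchmark, where the mean MAE gap
to the dense baseline is ~0.03 over 240 genes). The same pipeline is
available from the shell:

```sh
ncgraph-gex simulate --config sim.yaml --seed 0 --out data/
ncgraph-gex threshold --graph string_links.tsv --delta 137 --out sparse.tsv
ncgraph-gex train --model ncnn --expression data/expression.tsv \
    --landmark-file landmarks.txt --target-file targets.txt \
    --graph data/graph_edges.tsv --seed 0 --out run/
ncgraph-gex compare --report-a run/test_report.tsv --report-b run_mlp/test_report.tsv \
    --out cmp.tsv
```

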