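# scsketch

Unsupervised clustering for single-cell RNA-seq built from two pieces:

1. **Distance-preserving embedding** (`scsketch.embedding`) — an imputation
   autoencoder trained jointly with an encoder whose low-dimensional output
   preserves Euclidean distances between *imputed* expression profiles.
   Training runs in two stages (reconstruction pre-training, then joint
   tuning of `L_rec + alpha * L_dist`) over mini-batches of cell pairs.
   Implemented in NumPy (manual backprop + Adam), CPU-only.
2. **Sketch-initialized k-means** (`scsketch.sketch`) — k-means whose initial
   centers come from a weighted *skeleton* built by iterative
   locality-sensitive hashing (p-stable random projections,
   `h(v) = floor((a·v + b)/w)`). Same-bucket points merge into weighted
   centroids, so large populations shrink far more than small ones and rare
   clusters survive seeding. Optional radius- and size-based bucket
   corrections, and weighted-BIC selection of the cluster number.

Downstream analysis (`scsketch.annotation`): Wilcoxon rank-sum marker genes
with fold-change filtering, hypergeometric enrichment cell-type assignment
against reference marker sets, and a complete-linkage dendrogram over cluster
mean embeddings. Synthetic data (`scsketch.synthetic`): gamma-Poisson counts
with group DE and logistic-in-log-mean dropout, rare spike-in mixtures, and
Gaussian mixture fixtures. Partition metrics (`scsketch.metrics`): ARI, NMI,
rare-population detection F1.

## CLI

Each stage reads the previous stage's files:

```bash
scsketch simulate  --cells 1000 --genes 500 --groups 0.6,0.3,0.1 \
                   --seed 1 --outdir sim/
scsketch preprocess --input sim/matrix.mtx --out lognorm.tsv
scsketch embed      --input lognorm.tsv --latent-dim 64 --hidden 256,128 \
                    --pretrain-steps 500 --max-joint-steps 5000 --out emb.tsv
scsketch estimate-k --embedding emb.tsv --k-min 2 --k-max 8
scsketch cluster    --embedding emb.tsv --k 3 --out run
scsketch annotate   --matrix lognorm.tsv --labels run_labels.tsv \
                    --embedding emb.tsv --reference markers.tsv --outdir anno/
scsketch score      run_labels.tsv sim/labels.tsv
scsketch run        --input sim/matrix.mtx --k 3 --outdir full_run/   # everything
```

Reference marker files are two-column delimited text (`cell_type`, `gene`).
Expression input is Matrix Market (10x orientation, with `barcodes.tsv` and
`genes.tsv`/`features.tsv` sidecars) or dense CSV/TSV with gene-id header and
cell-id first column.

## Library use

```python
import numpy as np
import scsketch as sk

m = sk.read_expression("matrix.mtx")
m = sk.filter_min_count(m, 1)
ln = sk.normalize_and_log(m, 1e4)

model = sk.train_embedding(ln, sk.EmbeddingConfig(latent_dim=64, seed=0))
z = sk.embed(model, ln)

result = sk.sketch_kmeans(z, k=8, cfg=sk.SketchConfig(seed=0))
markers = sk.rank_sum_markers(ln, result.labels, p_max=1e-6, fc_min=1.5)
```
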