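"""Post-clustering biology: marker genes, cell-type calls, cluster dendrogram.

Markers are genes significantly up-regulated in one cluster versus all
remaining cells (one-sided rank-sum test) with a minimum fold change of
group-mean ratios. Cell types are assigned by overlapping each cluster's
marker set with reference gene sets and scoring the overlap with a
hypergeometric enrichment p-value, a matching rate and the Jaccard index.
The trajectory view is a complete-linkage dendrogram over cluster mean
embeddings.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .io import ExpressionMatrix

__all__ = [
    "MarkerTable",
    "CellTypeAssignment",
    "TrajectoryResult",
    "rank_sum_markers",
    "enrichment_pvalue",
    "assign_cell_types",
    "cluster_trajectory",
    "read_reference_markers",
]

_EPS = 1e-9  # pseudocount guarding fold-change division
_EXACT_MAX_N = 20  # per-side size below which the exact rank-sum null is used


@dataclass
class MarkerTable:
    """Per-cluster up-regulated genes passing the p and fold-change cuts."""

    table: pd.DataFrame  # columns: cluster, gene, pvalue, fold_change
    p_max: float
    fc_min: float

    def markers_for(self, cluster) -> set[str]:
        sub = self.table[self.table["cluster"] == cluster]
        return set(sub["gene"])

    @property
    def clusters(self) -> list:
        return sorted(self.table["cluster"].unique().tolist())


@dataclass
class CellTypeAssignment:
    cluster: object
    cell_type: str
    overlap: int  # k
    n_cluster_markers: int  # a
    n_reference_markers: int  # b
    n_background: int  # N_bg
    matching_rate: float
    jaccard: float
    pvalue: float
    candidates: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class TrajectoryResult:
    cluster_ids: list
    mean_embedding: np.ndarray  # k x d
    distances: np.ndarray  # k x k
    linkage: np.ndarray  # scipy linkage matrix (complete)

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)
        names = [str(c) for c in self.cluster_ids]

        def walk(node) -> str:
            if node.is_leaf():
                return f"{names[node.id]}:{node.dist:.6g}"
            left, right = walk(node.get_left()), walk(node.get_right())
            return f"({left},{right}):{node.dist:.6g}"

        out = walk(tree)
        return out.rsplit(":", 1)[0] + ";"


def _rank_sum_greater(x: np.ndarray, y: np.ndarray) -> float:
    """One-sided (x stochastically greater) rank-sum p-value.

    Exact enumeration for small tie-free samples, otherwise the normal
    approximation with continuity and tie correction.
    """
    small = min(len(x), len(y)) < _EXACT_MAX_N
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if small and not has_ties else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="greater", method=method).pvalue
    )


def rank_sum_markers(
    m: ExpressionMatrix,
    labels,
    p_max: float = 1e-6,
    fc_min: float = 1.5,
) -> MarkerTable:
    """Per-cluster up-regulated marker genes.

    For every (cluster, gene) pair, a one-sided rank-sum test of in-cluster
    versus remaining cells and a fold change of group means (with a small
    pseudocount); rows are kept iff p <= p_max and fold change >= fc_min.
    """
    if m.layer != "lognorm":
        raise ValueError("rank_sum_markers expects the lognorm layer")
    labels = np.asarray(labels)
    if labels.shape[0] != m.n_cells:
        raise ValueError("labels length does not match cell count")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("marker detection needs at least 2 clusters")

    rows = []
    x = m.values
    for cluster in uniq:
        mask = labels == cluster
        inside, outside = x[mask], x[~mask]
        mean_in = inside.mean(axis=0)
        mean_out = outside.mean(axis=0)
        fc = (mean_in + _EPS) / (mean_out + _EPS)
        # fold-change prefilter: p-values only needed where fc can pass
        for j in np.flatnonzero(fc >= fc_min):
            p = _rank_sum_greater(inside[:, j], outside[:, j])
            if p <= p_max:
                rows.append((cluster, m.gene_ids[j], p, float(fc[j])))
    table = pd.DataFrame(rows, columns=["cluster", "gene", "pvalue", "fold_change"])
    return MarkerTable(table=table, p_max=p_max, fc_min=fc_min)


def enrichment_pvalue(n_bg: int, a: int, b: int, k: int) -> float:
    """Hypergeometric upper-tail probability of >= k overlapping genes.

    ``sum_{i=k}^{min(a,b)} C(a,i) C(n_bg-a, b-i) / C(n_bg, b)``, evaluated
    in log space by scipy's hypergeometric survival function.
    """
    if not (0 <= a <= n_bg and 0 <= b <= n_bg):
        raise ValueError("marker counts cannot exceed the background size")
    if not 0 <= k <= min(a, b):
        raise ValueError(f"overlap k={k} outside [0, min(a, b)={min(a, b)}]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, n_bg, a, b))


def read_reference_markers(path: str | os.PathLike) -> dict[str, set[str]]:
    """Read a two-column (cell_type, gene) delimited file into gene sets."""
    path = Path(path)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (cell_type, gene)")
    if str(df.iloc[0, 0]).lower() in ("cell_type", "celltype"):
        df = df.iloc[1:]
    out: dict[str, set[str]] = {}
    for cell_type, gene in zip(df.iloc[:, 0], df.iloc[:, 1]):
        out.setdefault(str(cell_type), set()).add(str(gene).casefold())
    return out


def assign_cell_types(
    markers: MarkerTable,
    reference: dict[str, set[str]],
    n_background: int,
) -> list[CellTypeAssignment]:
    """Score every (cluster, reference type) overlap and call the best type.

    The winning type has the smallest enrichment p-value, with ties broken
    by larger Jaccard. A cluster with no markers, or no overlap with any
    type, is labelled ``unknown`` with p = 1.
    """
    if not reference:
        raise ValueError("reference marker map is empty")
    reference = {t: {g.casefold() for g in genes} for t, genes in reference.items()}
    out = []
    for cluster in markers.clusters:
        cluster_genes = {g.casefold() for g in markers.markers_for(cluster)}
        a = len(cluster_genes)
        cand_rows = []
        for cell_type, ref_genes in sorted(reference.items()):
            b = len(ref_genes)
            k = len(cluster_genes & ref_genes)
            p = enrichment_pvalue(n_background, a, b, k) if a else 1.0
            jac = k / (a + b - k) if (a + b - k) > 0 else 0.0
            match = k / b if b else 0.0
            cand_rows.append((cell_type, k, b, match, jac, p))
        cand = pd.DataFrame(
            cand_rows,
            columns=["cell_type", "overlap", "n_reference", "matching_rate",
                     "jaccard", "pvalue"],
        )
        best = cand.sort_values(
            ["pvalue", "jaccard", "cell_type"], ascending=[True, False, True]
        ).iloc[0]
        if a == 0 or best["overlap"] == 0:
            out.append(
                CellTypeAssignment(
                    cluster=cluster, cell_type="unknown", overlap=0,
                    n_cluster_markers=a, n_reference_markers=0,
                    n_background=n_background, matching_rate=0.0, jaccard=0.0,
                    pvalue=1.0, candidates=cand,
                )
            )
            continue
        out.append(
            CellTypeAssignment(
                cluster=cluster,
                cell_type=str(best["cell_type"]),
                overlap=int(best["overlap"]),
                n_cluster_markers=a,
                n_reference_markers=int(best["n_reference"]),
                n_background=n_background,
                matching_rate=float(best["matching_rate"]),
                jaccard=float(best["jaccard"]),
                pvalue=float(best["pvalue"]),
                candidates=cand,
            )
        )
    return out


def cluster_trajectory(embedding: np.ndarray, labels) -> TrajectoryResult:
    """Complete-linkage dendrogram over per-cluster mean embeddings."""
    embedding = np.atleast_2d(np.asarray(embedding, dtype=float))
    labels = np.asarray(labels)
    if labels.shape[0] != embedding.shape[0]:
        raise ValueError("labels length does not match embedding rows")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("trajectory needs at least 2 clusters")
    means = np.stack([embedding[labels == c].mean(axis=0) for c in uniq])
    condensed = pdist(means, metric="euclidean")
    link = hierarchy.linkage(condensed, method="complete")
    return TrajectoryResult(
        cluster_ids=uniq.tolist(),
        mean_embedding=means,
        distances=squareform(condensed),
        linkage=link,
    )
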