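"""Co-alteration similarity clustering of tumors.

The co-mutation method: for non-hypermutated donors i, j, c_ij is the number
of genes (from a chosen gene set) altered in both tumors, giving a symmetric
N x N count matrix whose diagonal c_ii is the tumor's own altered-gene
count. Each element is replaced by 1/(c_ij + 1), mapping counts into (0, 1]
with 1 meaning "nothing in common". Rows of the normalized matrix are then
clustered agglomeratively with Euclidean distance and Ward linkage.

The normalized quantity *decreases* as shared alterations increase; it is
used verbatim as the feature matrix rather than converted into a
conventional similarity, so tumors with similar co-alteration profiles end
up with similar rows and cluster together.

Cluster-count selection uses three internal validation measures —
connectivity, average silhouette width, and the Dunn index — with average
silhouette as the primary criterion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import fisher_exact
from sklearn.metrics import silhouette_score

from .biomarkers import altered_genes
from .models import TumorProfile

#: number of nearest neighbors used by the connectivity measure
CONNECTIVITY_NEIGHBORS = 10


@dataclass
class SimilarityMatrix:
    """Pairwise co-alteration counts and their 1/(c+1) normalization."""

    tumor_ids: list[str]
    counts: np.ndarray
    normalized: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        n = len(self.tumor_ids)
        if c.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("co-alteration counts must be non-negative")
        if not np.array_equal(c, c.T):
            raise ValueError("co-alteration counts must be symmetric")
        self.counts = c
        self.normalized = normalize_matrix(c)


@dataclass
class ClusterResult:
    assignments: dict[str, int]
    k: int
    linkage_record: np.ndarray
    labels: dict[int, str] = field(default_factory=dict)
    stability: pd.DataFrame | None = None

    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for c in self.assignments.values():
            out[c] = out.get(c, 0) + 1
        return out


def comutation_counts(
    tumors: Sequence[TumorProfile],
    gene_set: Iterable[str],
    altered_predicate: Callable[[TumorProfile], set[str]] | None = None,
) -> SimilarityMatrix:
    """Pairwise shared-altered-gene counts c_ij over a gene set.

    ``altered_predicate`` maps a tumor to its set of altered genes; the
    default counts any small variant or SCNA gain/loss. Hypermutated tumors
    should be excluded by the caller before building the matrix.
    """
    genes = frozenset(gene_set)
    if not genes:
        raise ValueError("gene_set must be non-empty")
    if altered_predicate is None:
        profiles = [altered_genes(t, genes) for t in tumors]
    else:
        profiles = [set(altered_predicate(t)) & genes for t in tumors]
    n = len(tumors)
    counts = np.zeros((n, n), dtype=int)
    for i in range(n):
        counts[i, i] = len(profiles[i])
        for j in range(i + 1, n):
            c = len(profiles[i] & profiles[j])
            counts[i, j] = counts[j, i] = c
    return SimilarityMatrix([t.tumor_id for t in tumors], counts)


def normalize_matrix(counts: np.ndarray) -> np.ndarray:
    """Elementwise 1/(c + 1); strictly decreasing in c, range (0, 1]."""
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise ValueError("counts must be non-negative")
    return 1.0 / (c + 1.0)


def ward_linkage(normalized: np.ndarray) -> np.ndarray:
    """Ward merge history over rows of the normalized matrix (Euclidean)."""
    x = np.asarray(normalized, dtype=float)
    return linkage(x, method="ward")


def ward_cluster(
    normalized: np.ndarray,
    k: int,
    linkage_record: np.ndarray | None = None,
) -> np.ndarray:
    """Cut the Ward dendrogram into k clusters; labels are 1..k.

    Cluster indices are renumbered by first appearance in row order so the
    labeling is deterministic and invariant to how fcluster numbers leaves.
    """
    x = np.asarray(normalized, dtype=float)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in [1, {n}], got {k}")
    if k == 1:
        return np.ones(n, dtype=int)
    z = linkage_record if linkage_record is not None else ward_linkage(x)
    # cut by merge order (not height) so exactly k clusters come out even
    # when merge costs tie
    raw = cut_tree(z, n_clusters=k).ravel()
    remap: dict[int, int] = {}
    out = np.empty(n, dtype=int)
    for i, c in enumerate(raw):
        if c not in remap:
            remap[c] = len(remap) + 1
        out[i] = remap[c]
    return out


def connectivity_index(dist: np.ndarray, assignments: np.ndarray,
                       n_neighbors: int = CONNECTIVITY_NEIGHBORS) -> float:
    """Connectivity: penalty 1/j when an observation's j-th nearest neighbor
    sits in a different cluster. Lower is better."""
    n = dist.shape[0]
    m = min(n_neighbors, n - 1)
    total = 0.0
    for i in range(n):
        order = np.argsort(dist[i], kind="stable")
        order = order[order != i][:m]
        for j, nb in enumerate(order, start=1):
            if assignments[nb] != assignments[i]:
                total += 1.0 / j
    return total


def dunn_index(dist: np.ndarray, assignments: np.ndarray) -> float:
    """Minimum between-cluster distance over maximum cluster diameter."""
    labels = np.unique(assignments)
    if len(labels) < 2:
        raise ValueError("Dunn index needs at least two clusters")
    max_diam = 0.0
    for c in labels:
        idx = np.where(assignments == c)[0]
        if len(idx) > 1:
            max_diam = max(max_diam, dist[np.ix_(idx, idx)].max())
    min_sep = np.inf
    for a_i, a_c in enumerate(labels):
        for b_c in labels[a_i + 1:]:
            ia = np.where(assignments == a_c)[0]
            ib = np.where(assignments == b_c)[0]
            min_sep = min(min_sep, dist[np.ix_(ia, ib)].min())
    if max_diam == 0.0:
        # every cluster is a point mass: perfectly compact
        return float("inf") if min_sep > 0 else 0.0
    return float(min_sep / max_diam)


def select_k(
    normalized: np.ndarray,
    k_range: Iterable[int],
) -> tuple[int, pd.DataFrame]:
    """Stability table over k and the silhouette-optimal k (ties -> smaller).

    Returns ``(best_k, table)`` where the table has one row per k with
    connectivity, average silhouette width, and Dunn index.
    """
    x = np.asarray(normalized, dtype=float)
    n = x.shape[0]
    ks = sorted(set(k_range))
    if not ks:
        raise ValueError("k_range must be non-empty")
    if any(k < 2 or k > n - 1 for k in ks):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    dist = squareform(pdist(x))
    if dist.max() == 0.0:
        raise ValueError("all rows identical: silhouette is undefined")
    z = ward_linkage(x)
    rows = []
    for k in ks:
        a = ward_cluster(x, k, linkage_record=z)
        sil = float(silhouette_score(dist, a, metric="precomputed")) if len(np.unique(a)) > 1 else float("nan")
        rows.append(
            {
                "k": k,
                "connectivity": connectivity_index(dist, a),
                "silhouette": sil,
                "dunn": dunn_index(dist, a),
            }
        )
    table = pd.DataFrame(rows)
    best = table.loc[table["silhouette"].idxmax(), "k"]  # idxmax: first max -> smaller k
    return int(best), table


def label_clusters(
    assignments: Mapping[str, int],
    tumors: Sequence[TumorProfile],
    gene_set: Iterable[str],
    min_within_freq: float = 0.5,
) -> dict[int, str]:
    """Name each cluster by its most enriched gene.

    For every cluster the candidate label is the gene with the smallest
    two-tailed Fisher p-value (cluster vs rest) among genes altered in at
    least ``min_within_freq`` of the cluster's tumors; ties break
    lexicographically. Clusters with no qualifying gene are 'unassigned'
    (tumors with minor or no alterations).
    """
    genes = sorted(set(gene_set))
    if not genes:
        raise ValueError("gene_set must be non-empty")
    by_id = {t.tumor_id: altered_genes(t, genes) for t in tumors}
    clusters = sorted(set(assignments.values()))
    labels: dict[int, str] = {}
    for c in clusters:
        inside = [tid for tid, cc in assignments.items() if cc == c]
        outside = [tid for tid, cc in assignments.items() if cc != c]
        best_gene, best_p = None, np.inf
        for g in genes:
            a = sum(g in by_id[t] for t in inside)
            if a / len(inside) < min_within_freq:
                continue
            b = len(inside) - a
            cc = sum(g in by_id[t] for t in outside)
            dd = len(outside) - cc
            p = fisher_exact([[a, b], [cc, dd]])[1]
            if p < best_p:
                best_gene, best_p = g, p
        labels[c] = best_gene if best_gene is not None else "unassigned"
    return labels


def cluster_cohort(
    tumors: Sequence[TumorProfile],
    gene_set: Iterable[str],
    k: int | None = 6,
    k_range: Iterable[int] = range(2, 11),
    altered_predicate: Callable[[TumorProfile], set[str]] | None = None,
) -> ClusterResult:
    """Full clustering pass: counts -> normalize -> Ward -> (select k) -> label.

    ``k=None`` selects k by stability; the caller is responsible for having
    excluded hypermutated tumors.
    """
    sim = comutation_counts(tumors, gene_set, altered_predicate)
    z = ward_linkage(sim.normalized)
    stability = None
    if k is None:
        k, stability = select_k(sim.normalized, k_range)
    a = ward_cluster(sim.normalized, k, linkage_record=z)
    assignments = dict(zip(sim.tumor_ids, (int(v) for v in a)))
    labels = label_clusters(assignments, tumors, gene_set)
    return ClusterResult(
        assignments=assignments, k=k, linkage_record=z, labels=labels, stability=stability
    )
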