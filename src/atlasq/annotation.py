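"""Hierarchical marker-based cluster annotation.

Clusters are scored against a three-level label taxonomy using, per marker
gene, the ROC AUC of in-cluster vs out-of-cluster expression together with
the difference of mean log-normalized expression ("fold change" on the log
scale). For every candidate label the maximum AUC and maximum fold change
across its markers are averaged; the candidate with the highest average wins
the cluster. Levels are annotated top-down so a level-2 label is always a
child of the cluster's level-1 label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.cluster import hierarchy as sch
from scipy.stats import norm, rankdata

from .dataset import ExpressionDataset
from .exceptions import ConfigurationError, ParameterError, ValidationError

LEVELS = (1, 2, 3)


# ---------------------------------------------------------------------------
# Taxonomy
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TaxonomyNode:
    label: str
    level: int
    parent: str | None
    markers: tuple[str, ...]


class LabelTaxonomy:
    """Three-level label tree (class -> type -> subtype) with markers."""

    def __init__(self, nodes: dict[str, TaxonomyNode]):
        self.nodes = nodes
        self._validate()

    def _validate(self) -> None:
        for node in self.nodes.values():
            if node.level not in LEVELS:
                raise ValidationError(f"{node.label}: level must be 1, 2 or 3")
            if not node.markers:
                raise ValidationError(f"{node.label}: marker list is empty")
            if node.level == 1 and node.parent is not None:
                raise ValidationError(f"{node.label}: level-1 node has a parent")
            if node.level > 1:
                parent = self.nodes.get(node.parent)
                if parent is None:
                    raise ValidationError(f"{node.label}: parent {node.parent!r} missing")
                if parent.level != node.level - 1:
                    raise ValidationError(
                        f"{node.label}: parent must be level {node.level - 1}"
                    )

    @classmethod
    def from_dict(cls, tree: dict) -> "LabelTaxonomy":
        """Build from nested JSON: ``{label: {"markers": [...], "children": {...}}}``."""
        nodes: dict[str, TaxonomyNode] = {}

        def walk(subtree: dict, level: int, parent: str | None) -> None:
            for label, entry in subtree.items():
                nodes[label] = TaxonomyNode(
                    label=label,
                    level=entry.get("level", level),
                    parent=parent,
                    markers=tuple(entry.get("markers", ())),
                )
                walk(entry.get("children", {}), level + 1, label)

        walk(tree, 1, None)
        return cls(nodes)

    def labels_at_level(self, level: int) -> list[str]:
        return sorted(n.label for n in self.nodes.values() if n.level == level)

    def children_of(self, label: str) -> list[str]:
        return sorted(n.label for n in self.nodes.values() if n.parent == label)

    def markers_of(self, label: str) -> tuple[str, ...]:
        return self.nodes[label].markers


# ---------------------------------------------------------------------------
# Graph clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusterAssignment:
    """Per-cell cluster ids, contiguous from 0."""

    labels: np.ndarray
    resolution: float
    method: str = "leiden"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if len(uniq) and not np.array_equal(uniq, np.arange(len(uniq))):
            # remap to contiguous ids preserving first-appearance order
            _, self.labels = np.unique(self.labels, return_inverse=True)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    def mask(self, cluster: int) -> np.ndarray:
        return self.labels == cluster


def knn_edges(embedding: np.ndarray, k: int) -> np.ndarray:
    """Undirected edge list (union of directed kNN edges), Euclidean metric."""
    from sklearn.neighbors import NearestNeighbors

    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    src = np.repeat(np.arange(embedding.shape[0]), k)
    dst = idx[:, 1:].ravel()
    lo, hi = np.minimum(src, dst), np.maximum(src, dst)
    return np.unique(np.stack([lo, hi], axis=1), axis=0)


def cluster_graph(
    embedding: np.ndarray,
    k: int = 30,
    resolution: float = 2.0,
    seed: int = 0,
) -> ClusterAssignment:
    """Leiden community detection on the Euclidean kNN graph.

    Deterministic for a fixed ``seed``. All-identical coordinates collapse to
    a single cluster.
    """
    import igraph as ig
    import leidenalg

    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 cells to cluster")
    if k >= n:
        raise ParameterError(f"k={k} must be smaller than the number of cells ({n})")
    if np.all(embedding == embedding[0]):
        # degenerate geometry: neighbor selection would be arbitrary
        return ClusterAssignment(labels=np.zeros(n, dtype=int),
                                 resolution=resolution)
    edges = knn_edges(embedding, k)
    g = ig.Graph(n=n, edges=[tuple(e) for e in edges], directed=False)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
    )
    return ClusterAssignment(labels=np.asarray(part.membership), resolution=resolution)


# ---------------------------------------------------------------------------
# Marker statistics
# ---------------------------------------------------------------------------

def _as_dense(x) -> np.ndarray:
    if sparse.issparse(x):
        return np.asarray(x.todense(), dtype=float)
    return np.asarray(x, dtype=float)


def _auc_bulk(ranks: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """AUC per column from midranks: U1/(n1*n2), the 1/2-tie convention."""
    n1 = int(mask.sum())
    n2 = ranks.shape[0] - n1
    r1 = ranks[mask].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return u1 / (n1 * n2)


def marker_auc(expr: np.ndarray, in_cluster: np.ndarray) -> float:
    """P(random in-cluster value > random out value) + half the tie mass.

    Equals the Mann-Whitney U statistic divided by ``n_in * n_out``.
    """
    expr = np.asarray(expr, dtype=float).ravel()
    in_cluster = np.asarray(in_cluster, dtype=bool).ravel()
    if in_cluster.all() or not in_cluster.any():
        raise ParameterError("both in- and out-of-cluster groups must be non-empty")
    ranks = rankdata(expr)[:, None]
    return float(_auc_bulk(ranks, in_cluster)[0])


def marker_fc(expr: np.ndarray, in_cluster: np.ndarray) -> float:
    """Difference of group means on the (log) scale of ``expr``."""
    expr = np.asarray(expr, dtype=float).ravel()
    in_cluster = np.asarray(in_cluster, dtype=bool).ravel()
    if in_cluster.all() or not in_cluster.any():
        raise ParameterError("both groups must be non-empty")
    return float(expr[in_cluster].mean() - expr[~in_cluster].mean())


# ---------------------------------------------------------------------------
# Cluster scoring against the taxonomy
# ---------------------------------------------------------------------------

@dataclass
class TypeScoreTable:
    """Scores per (cluster, candidate label) and the winning assignment."""

    table: pd.DataFrame  # columns: cluster, label, auc_max, fc_max, score
    assigned: dict[int, str | None]
    ties: set[int] = field(default_factory=set)


def score_types(
    ds: ExpressionDataset,
    clusters: ClusterAssignment,
    taxonomy: LabelTaxonomy,
    level: int,
    parent_assignment: dict[int, str | None] | None = None,
    fc_rescale: str = "none",
) -> TypeScoreTable:
    """Score every cluster against the candidate labels of one level.

    Per candidate label: ``auc_max``/``fc_max`` are the maxima over that
    label's resolvable markers; ``score = (auc_max + fc_max) / 2``. At levels
    2-3, candidates are restricted to children of the cluster's assigned
    parent label. Ties at the argmax are broken lexicographically and flagged.

    ``fc_rescale='rank'`` rank-normalizes ``fc_max`` to [0, 1] within each
    cluster before averaging (robustness option; default is the literal mix).
    """
    lognorm = ds.require_lognorm()
    if parent_assignment is None and level > 1:
        raise ConfigurationError("levels 2-3 require a parent_assignment")
    candidates_all = taxonomy.labels_at_level(level)
    if not candidates_all:
        raise ConfigurationError(f"taxonomy has no level-{level} labels")

    # resolve markers once
    gene_index = {g: i for i, g in enumerate(ds.gene_ids.astype(str))}
    label_markers: dict[str, list[int]] = {}
    for label in candidates_all:
        cols = []
        for g in taxonomy.markers_of(label):
            if g in gene_index:
                cols.append(gene_index[g])
            else:
                warnings.warn(f"marker {g!r} for {label!r} not in dataset; dropped",
                              stacklevel=2)
        if cols:
            label_markers[label] = cols
        else:
            warnings.warn(f"all markers missing for {label!r}; label excluded",
                          stacklevel=2)
    if not label_markers:
        raise ConfigurationError(f"no scorable level-{level} labels")

    all_cols = sorted({c for cols in label_markers.values() for c in cols})
    col_pos = {c: j for j, c in enumerate(all_cols)}
    X = _as_dense(lognorm[:, all_cols])
    ranks = rankdata(X, axis=0)

    rows = []
    assigned: dict[int, str | None] = {}
    ties: set[int] = set()
    for c in range(clusters.n_clusters):
        mask = clusters.mask(c)
        if mask.all() or not mask.any():
            assigned[c] = None
            continue
        auc_all = _auc_bulk(ranks, mask)
        fc_all = X[mask].mean(axis=0) - X[~mask].mean(axis=0)
        if level == 1:
            candidates = [l for l in candidates_all if l in label_markers]
        else:
            parent = (parent_assignment or {}).get(c)
            candidates = [
                l for l in taxonomy.children_of(parent) if l in label_markers
            ] if parent is not None else []
        if not candidates:
            assigned[c] = None
            continue
        per_label = {}
        for label in candidates:
            j = [col_pos[k] for k in label_markers[label]]
            per_label[label] = (float(auc_all[j].max()), float(fc_all[j].max()))
        fc_maxes = {l: v[1] for l, v in per_label.items()}
        if fc_rescale == "rank" and len(fc_maxes) > 1:
            order = rankdata(list(fc_maxes.values()))
            scaled = (order - 1) / (len(order) - 1)
            fc_used = dict(zip(fc_maxes, scaled))
        else:
            fc_used = fc_maxes
        scores = {l: (per_label[l][0] + fc_used[l]) / 2.0 for l in candidates}
        best = max(scores.values())
        winners = sorted(l for l, s in scores.items() if s == best)
        if len(winners) > 1:
            ties.add(c)
        assigned[c] = winners[0]
        for label in candidates:
            rows.append(
                dict(cluster=c, label=label, auc_max=per_label[label][0],
                     fc_max=per_label[label][1], score=scores[label])
            )
    return TypeScoreTable(table=pd.DataFrame(rows), assigned=assigned, ties=ties)


def annotate_hierarchy(
    ds: ExpressionDataset,
    clusters: ClusterAssignment,
    taxonomy: LabelTaxonomy,
    max_level: int = 3,
    fc_rescale: str = "none",
) -> pd.DataFrame:
    """Annotate clusters top-down (level 1 -> 2 -> 3).

    Returns one row per cluster with ``level1``/``level2``/``level3`` columns
    (deeper levels are None when the taxonomy has no children there).
    """
    result: dict[int, dict[str, str | None]] = {
        c: {} for c in range(clusters.n_clusters)
    }
    parent: dict[int, str | None] | None = None
    for level in range(1, max_level + 1):
        if not taxonomy.labels_at_level(level):
            for c in result:
                result[c][f"level{level}"] = None
            continue
        tbl = score_types(ds, clusters, taxonomy, level,
                          parent_assignment=parent, fc_rescale=fc_rescale)
        for c in result:
            result[c][f"level{level}"] = tbl.assigned.get(c)
        parent = tbl.assigned
    df = pd.DataFrame.from_dict(result, orient="index")
    df.index.name = "cluster"
    return df


# ---------------------------------------------------------------------------
# Majority-vote reannotation
# ---------------------------------------------------------------------------

def majority_reannotate(
    clusters: ClusterAssignment, cell_labels: np.ndarray | pd.Series
) -> dict[int, str]:
    """Cluster label = modal per-cell label.

    Ties go to the label most abundant in the whole dataset, then
    lexicographic.
    """
    labels = pd.Series(np.asarray(cell_labels, dtype=object))
    if labels.isna().any():
        raise ValidationError("every cell needs a provisional label")
    global_counts = labels.value_counts()
    out: dict[int, str] = {}
    for c in range(clusters.n_clusters):
        counts = labels[clusters.mask(c)].value_counts()
        top = counts.max()
        cands = sorted(counts[counts == top].index)
        if len(cands) > 1:
            gmax = max(global_counts[l] for l in cands)
            cands = sorted(l for l in cands if global_counts[l] == gmax)
        out[c] = cands[0]
    return out


# ---------------------------------------------------------------------------
# Marker refinement (Wilcoxon one-vs-rest)
# ---------------------------------------------------------------------------

def rank_sum_zscores(X: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized two-sided Wilcoxon rank-sum per column.

    Returns (z, p). Normal approximation with tie correction, no continuity
    correction. ``z > 0`` means the masked group has larger values.
    """
    n = X.shape[0]
    n1 = int(mask.sum())
    n2 = n - n1
    ranks = rankdata(X, axis=0)
    r1 = ranks[mask].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie correction term per column
    tie_term = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        _, counts = np.unique(X[:, j], return_counts=True)
        t = counts[counts > 1]
        tie_term[j] = np.sum(t**3 - t)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma2 > 0, (u1 - mu) / np.sqrt(np.maximum(sigma2, 1e-300)), 0.0)
    p = 2.0 * norm.sf(np.abs(z))
    return z, np.minimum(p, 1.0)


def refine_markers(
    ds: ExpressionDataset,
    labels: np.ndarray | pd.Series,
    subsample: int = 100_000,
    top_n: int = 10,
    seed: int = 0,
) -> tuple[dict[str, list[str]], np.ndarray | None, list[str]]:
    """One-vs-rest Wilcoxon markers per label plus a gene dendrogram.

    A random subset of at most ``subsample`` cells is used (seeded); per
    label the ``top_n`` genes by z (ties: p ascending, then gene id) are
    kept. The union of selected genes is hierarchically clustered (average
    linkage, correlation distance on per-label mean profiles).

    Returns (label -> genes, linkage matrix or None, clustered gene order).
    """
    lognorm = ds.require_lognorm()
    labels = pd.Series(np.asarray(labels, dtype=object)).reset_index(drop=True)
    uniq = sorted(labels.unique())
    if len(uniq) < 2:
        raise ParameterError("need at least 2 labels")

    rng = np.random.default_rng(seed)
    n = ds.n_cells
    if subsample < n:
        idx = np.sort(rng.choice(n, size=subsample, replace=False))
    else:
        idx = np.arange(n)
    X = _as_dense(lognorm[idx])
    sub_labels = labels.iloc[idx].reset_index(drop=True)
    gene_ids = ds.gene_ids.astype(str).to_numpy()

    markers: dict[str, list[str]] = {}
    for label in uniq:
        mask = (sub_labels == label).to_numpy()
        if mask.sum() < 3:
            warnings.warn(f"label {label!r} has < 3 cells; skipped", stacklevel=2)
            continue
        z, p = rank_sum_zscores(X, mask)
        order = np.lexsort((gene_ids, p, -z))
        markers[label] = list(gene_ids[order[:top_n]])

    union = sorted({g for gs in markers.values() for g in gs})
    linkage = None
    leaf_order = union
    if len(union) >= 3 and len(markers) >= 2:
        cols = [int(np.flatnonzero(gene_ids == g)[0]) for g in union]
        profiles = np.stack(
            [X[(sub_labels == l).to_numpy()][:, cols].mean(axis=0) for l in markers],
            axis=1,
        )  # genes x labels
        # correlation distance is undefined for constant rows; nudge them
        const = profiles.std(axis=1) == 0
        if const.any():
            profiles = profiles + rng.normal(0, 1e-9, size=profiles.shape)
        linkage = sch.linkage(profiles, method="average", metric="correlation")
        leaf_order = [union[i] for i in sch.leaves_list(linkage)]
    return markers, linkage, leaf_order
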