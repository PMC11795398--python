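"""kNN graph construction, Leiden clustering, hierarchical subclustering.

The global neighborhood graph is built once: exact Euclidean k nearest
neighbors, edges weighted by the Jaccard overlap of the two endpoints'
neighbor sets (shared-nearest-neighbor weighting), symmetrized by union.
Leiden community detection (RB-configuration modularity) partitions it;
subclustering extracts a cluster's induced subgraph from the same global
graph — no fresh neighbor search — renormalizes its weights, and runs
Leiden again, so resolution values stay comparable across levels.
Labels are hierarchical paths ("3", "3.1", "3.1.2", ...), numbered by
decreasing cluster size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .exceptions import ConfigError, FlowPhenoError


@dataclass
class NeighborGraph:
    """Exact kNN graph with shared-nearest-neighbor edge weights."""

    neighbors: np.ndarray          # (n, k) neighbor indices, self excluded
    edges: np.ndarray              # (m, 2) undirected edge list, i < j
    weights: np.ndarray            # (m,) edge weights in [0, 1]
    k: int
    metric: str = "euclidean"
    weighting: str = "jaccard"

    @property
    def n_events(self) -> int:
        return self.neighbors.shape[0]


@dataclass
class ClusterAssignment:
    """Hierarchical per-event labels plus per-level provenance.

    ``labels`` holds the current leaf path for every event (e.g. "3.1").
    ``levels`` records each clustering/subclustering step: (target label or
    "" for the root step, resolution, seed).
    """

    labels: np.ndarray
    levels: list[dict] = field(default_factory=list)

    @property
    def leaf_labels(self) -> list[str]:
        return sorted(set(self.labels.tolist()))

    def members(self, label: str) -> np.ndarray:
        """Indices of events whose path is ``label`` or a descendant of it."""
        lab = np.asarray(self.labels, dtype=object)
        return np.flatnonzero((lab == label)
                              | np.char.startswith(lab.astype(str), label + "."))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"event": np.arange(len(self.labels)),
                             "label": self.labels})


def build_knn_graph(matrix: np.ndarray, k: int = 20,
                    metric: str = "euclidean",
                    weighting: str = "jaccard") -> NeighborGraph:
    """Exact k-nearest-neighbor graph with SNN Jaccard edge weights.

    Neighbor lists equal brute-force all-pairs search (the exactness is
    part of the contract). The undirected edge set is the union of the
    directed kNN relations; each edge's weight is the Jaccard overlap of
    the two endpoints' k-neighbor sets (``weighting="uniform"`` gives
    plain weight-1 edges).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if n < 2:
        raise ConfigError("need at least 2 events to build a graph")
    if k < 1:
        raise ConfigError("k must be >= 1")
    if k >= n:
        warnings.warn(f"k={k} >= n={n}; truncating to {n - 1}", stacklevel=2)
        k = n - 1
    if weighting not in ("jaccard", "uniform"):
        raise ConfigError(f"unknown weighting {weighting!r}")

    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute", metric=metric)
    nn.fit(matrix)
    _, idx = nn.kneighbors(matrix)
    # drop self wherever it appears (ties/duplicates may push it off col 0);
    # stable argsort on the self-mask moves non-self entries first while
    # preserving distance order
    is_self = idx == np.arange(n)[:, None]
    order = np.argsort(is_self, axis=1, kind="stable")
    neighbors = np.take_along_axis(idx, order, axis=1)[:, :k].astype(np.int64)

    src = np.repeat(np.arange(n, dtype=np.int64), k)
    dst = neighbors.reshape(-1)
    lo, hi = np.minimum(src, dst), np.maximum(src, dst)
    edges = np.unique(np.stack([lo, hi], axis=1), axis=0)

    if weighting == "uniform":
        weights = np.ones(len(edges))
    else:
        from scipy import sparse

        # neighbor sets include the event itself, so two mutual neighbors
        # sharing all their other neighbors score exactly 1
        adj = sparse.csr_matrix((np.ones(n * k), (src, dst)), shape=(n, n))
        adj = adj + sparse.eye(n, format="csr")
        overlap = adj @ adj.T              # (i, j) -> |N'(i) & N'(j)|
        inter = np.asarray(overlap[edges[:, 0], edges[:, 1]]).ravel()
        union = 2.0 * (k + 1) - inter      # every set has exactly k+1 members
        weights = np.where(union > 0, inter / union, 0.0)
    return NeighborGraph(neighbors=neighbors, edges=edges, weights=weights,
                         k=k, metric=metric, weighting=weighting)


def _leiden_partition(edges: np.ndarray, weights: np.ndarray, n: int,
                      resolution: float, seed: int) -> np.ndarray:
    g = ig.Graph(n=n, edges=[tuple(e) for e in edges])
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=list(weights), resolution_parameter=resolution, seed=seed,
        n_iterations=2)
    return np.asarray(part.membership, dtype=np.int64)


def _rank_labels(membership: np.ndarray) -> dict[int, int]:
    """Rank communities: 1 = largest; ties by smallest contained index."""
    comms = np.unique(membership)
    keyed = []
    for c in comms:
        members = np.flatnonzero(membership == c)
        keyed.append((-len(members), int(members[0]), int(c)))
    keyed.sort()
    return {c: rank + 1 for rank, (_, _, c) in enumerate(keyed)}


def leiden_cluster(graph: NeighborGraph, resolution: float = 1.0,
                   seed: int = 0) -> ClusterAssignment:
    """Leiden partition of the global graph; labels "1", "2", ... by size."""
    if graph.n_events == 0:
        raise ConfigError("empty graph")
    membership = _leiden_partition(graph.edges, graph.weights,
                                   graph.n_events, resolution, seed)
    rank = _rank_labels(membership)
    labels = np.array([str(rank[c]) for c in membership], dtype=object)
    return ClusterAssignment(labels=labels,
                             levels=[{"target": "", "resolution": resolution,
                                      "seed": seed}])


def induced_subgraph(graph: NeighborGraph, member_idx: np.ndarray,
                     renormalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Edges/weights of the global graph restricted to ``member_idx``.

    Returned edges are re-indexed to 0..len(member_idx)-1; weights are
    divided by their maximum within the subgraph when ``renormalize``.
    """
    member_idx = np.asarray(member_idx, dtype=np.int64)
    inv = np.full(graph.n_events, -1, dtype=np.int64)
    inv[member_idx] = np.arange(len(member_idx))
    e = graph.edges
    mask = (inv[e[:, 0]] >= 0) & (inv[e[:, 1]] >= 0)
    sub_edges = np.stack([inv[e[mask, 0]], inv[e[mask, 1]]], axis=1)
    sub_weights = graph.weights[mask].copy()
    if renormalize and len(sub_weights) and sub_weights.max() > 0:
        sub_weights = sub_weights / sub_weights.max()
    return sub_edges, sub_weights


def subcluster(graph: NeighborGraph, assignment: ClusterAssignment,
               target_label: str, resolution: float = 1.0,
               seed: int = 0) -> ClusterAssignment:
    """Split one cluster by re-running Leiden on its induced subgraph.

    The subgraph is extracted from the already-built global graph (no
    neighbor re-search) and its edge weights renormalized to max 1;
    children are labeled ``target.1``, ``target.2``, ... by decreasing
    size. Events outside the target cluster are untouched.
    """
    members = assignment.members(target_label)
    if len(members) == 0:
        raise FlowPhenoError(f"no cluster labeled {target_label!r}")
    sub_edges, sub_weights = induced_subgraph(graph, members)
    membership = _leiden_partition(sub_edges, sub_weights, len(members),
                                   resolution, seed)
    rank = _rank_labels(membership)
    new_labels = np.asarray(assignment.labels, dtype=object).copy()
    for local, global_idx in enumerate(members):
        new_labels[global_idx] = f"{target_label}.{rank[membership[local]]}"
    levels = assignment.levels + [{"target": target_label,
                                   "resolution": resolution, "seed": seed}]
    return ClusterAssignment(labels=new_labels, levels=levels)


def consolidate(assignment: ClusterAssignment,
                annotation: "dict[str, str] | object") -> ClusterAssignment:
    """Merge leaf clusters that share a cell-type annotation.

    ``annotation`` maps every leaf label to a cell-type name (an
    :class:`~flowpheno.annotate.AnnotationMap` works too). Leaves with the
    same annotation collapse into one cluster whose label is the smallest
    (hierarchy-compressed) member label; the result is flat.
    """
    mapping = getattr(annotation, "mapping", annotation)
    leaves = assignment.leaf_labels
    missing = [l for l in leaves if l not in mapping]
    if missing:
        raise FlowPhenoError(f"unannotated leaf clusters: {missing}")
    by_type: dict[str, list[str]] = {}
    for leaf in leaves:
        by_type.setdefault(mapping[leaf], []).append(leaf)
    canon = {}
    for _, group in sorted(by_type.items()):
        rep = sorted(group, key=lambda s: ([int(p) for p in s.split(".")]))[0]
        for leaf in group:
            canon[leaf] = rep
    labels = np.array([canon[l] for l in assignment.labels], dtype=object)
    levels = assignment.levels + [{"target": "<consolidate>",
                                   "resolution": None, "seed": None}]
    return ClusterAssignment(labels=labels, levels=levels)


def umap_embed(matrix: np.ndarray, seed: int = 0,
               n_neighbors: int = 15, min_dist: float = 0.1) -> np.ndarray:
    """2-D UMAP embedding, deterministic given the seed."""
    import umap  # deferred: slow import

    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape[0] < 10:
        raise ConfigError("umap_embed needs at least 10 events")
    reducer = umap.UMAP(n_components=2, random_state=seed,
                        n_neighbors=n_neighbors, min_dist=min_dist)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", category=UserWarning)
        return np.asarray(reducer.fit_transform(matrix), dtype=np.float64)
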