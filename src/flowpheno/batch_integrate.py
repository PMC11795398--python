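"""Balanced down-sampling and batch-effect correction.

Before clustering, cohorts are down-sampled to a fixed cap (default
200,000 events) with per-batch quotas so no acquisition batch dominates
the graph, then residual batch structure is removed with the Harmony
procedure: iterated soft k-means with a batch-diversity penalty followed
by per-cluster ridge regression of batch effects out of the embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .exceptions import ConfigError
from .io_model import EventTable

DEFAULT_DOWNSAMPLE_CAP = 200_000


@dataclass
class DownsampleResult:
    """Outcome of a balanced down-sampling draw."""

    selected: np.ndarray                 # sorted event indices
    per_batch_counts: dict[str, int]
    seed: int
    cap: int


@dataclass
class CorrectedEmbedding:
    """Batch-corrected event embedding plus the parameters that made it."""

    matrix: np.ndarray
    batch_labels: np.ndarray
    nclust: int
    max_iter: int
    seed: int
    converged: bool = True


def _largest_remainder(total: int, weights: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` proportional to ``weights``."""
    weights = np.asarray(weights, dtype=np.float64)
    if weights.sum() <= 0:
        return np.zeros(len(weights), dtype=np.int64)
    exact = total * weights / weights.sum()
    base = np.floor(exact).astype(np.int64)
    short = total - int(base.sum())
    if short > 0:
        # ties broken by position for determinism
        order = np.lexsort((np.arange(len(weights)), -(exact - base)))
        base[order[:short]] += 1
    return base


def balanced_downsample(events: EventTable, cap: int = DEFAULT_DOWNSAMPLE_CAP,
                        seed: int = 0) -> DownsampleResult:
    """Select at most ``cap`` events while balancing batches.

    When the cohort exceeds the cap, each batch receives an equal quota
    (cap / n_batches, rounded by largest remainder). A batch smaller than
    its quota contributes all its events and its surplus is redistributed
    proportionally to the remaining batches' sizes, iterating until every
    allocation is feasible. Within-batch selection is uniform at random
    under ``seed``; the selection depends only on the seed and the batch
    composition, not on event order.
    """
    if cap <= 0:
        raise ConfigError("downsample cap must be positive")
    batch_col = events.event_meta["batch_id"].astype(str).to_numpy()
    batches = sorted(pd.unique(batch_col))
    sizes = {b: int((batch_col == b).sum()) for b in batches}
    total = events.n_events

    if total <= cap:
        counts = dict(sizes)
    else:
        counts = {}
        active = list(batches)
        remaining = cap
        # equal quotas first; underfull batches take all, surplus goes to
        # the others proportionally to their sizes
        quota = dict(zip(active, _largest_remainder(remaining, np.ones(len(active)))))
        while True:
            small = [b for b in active if sizes[b] <= quota[b]]
            if not small:
                counts.update(quota)
                break
            for b in small:
                counts[b] = sizes[b]
                remaining -= sizes[b]
                active.remove(b)
            if not active:
                break
            alloc = _largest_remainder(remaining,
                                       np.array([sizes[b] for b in active], float))
            quota = dict(zip(active, alloc))

    rng = np.random.default_rng(seed)
    chosen: list[np.ndarray] = []
    for b in batches:  # fixed batch order -> order-invariant given seed
        idx = np.flatnonzero(batch_col == b)
        take = counts.get(b, 0)
        if take >= len(idx):
            chosen.append(idx)
        else:
            chosen.append(np.sort(rng.choice(idx, size=take, replace=False)))
    selected = np.sort(np.concatenate(chosen)) if chosen else np.array([], dtype=int)
    return DownsampleResult(selected=selected,
                            per_batch_counts={b: int(counts.get(b, 0)) for b in batches},
                            seed=seed, cap=cap)


def harmony_correct(matrix: np.ndarray, batch_labels: np.ndarray,
                    nclust: int | None = None, max_iter: int = 10,
                    sigma: float = 0.1, theta: float = 2.0,
                    ridge_lambda: float = 1.0, kmeans_rounds: int = 10,
                    block_fraction: float = 0.05,
                    seed: int = 0) -> CorrectedEmbedding:
    """Remove batch structure from an embedding (Harmony procedure).

    Soft k-means assignments on the L2-normalized rows carry a diversity
    penalty ``((E + 1)/(O + 1))^theta`` pushing each cluster's batch
    composition toward the global one; assignments are refreshed in small
    random blocks so the observed/expected counts equilibrate instead of
    oscillating. Each cluster's batch effect is then regressed out of the
    original-space embedding with a weighted ridge fit (intercept — the
    cluster centroid — unpenalized and retained). Iterating the two steps
    attenuates batch separation while leaving population structure in
    place. Deterministic given ``seed``. With a single batch the input is
    returned unchanged (with a warning).
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2:
        raise ConfigError("harmony_correct expects a 2-D matrix")
    if not np.all(np.isfinite(matrix)):
        raise ConfigError("harmony_correct requires finite values")
    batch_labels = np.asarray(batch_labels).astype(str)
    if len(batch_labels) != matrix.shape[0]:
        raise ConfigError("batch_labels length must match matrix rows")

    batches = np.unique(batch_labels)
    n, _ = matrix.shape
    if len(batches) < 2:
        warnings.warn("single batch: harmony_correct is an identity pass-through",
                      stacklevel=2)
        return CorrectedEmbedding(matrix=matrix.copy(), batch_labels=batch_labels,
                                  nclust=0, max_iter=0, seed=seed)

    if nclust is None:
        nclust = int(np.clip(round(n / 30), 2, 100))
    nclust = min(nclust, n)
    rng = np.random.default_rng(seed)

    phi = (batch_labels[:, None] == batches[None, :]).astype(np.float64)  # n x B
    batch_freq = phi.mean(axis=0)                                         # B

    def _normalize_rows(z: np.ndarray) -> np.ndarray:
        return z / np.maximum(np.linalg.norm(z, axis=1, keepdims=True), 1e-12)

    z_corr = matrix.copy()
    z_cos = _normalize_rows(z_corr)
    from sklearn.cluster import KMeans
    km = KMeans(n_clusters=nclust, n_init=10, max_iter=25,
                random_state=int(seed) % (2 ** 31))
    centers = _normalize_rows(km.fit(z_cos).cluster_centers_)

    design = np.hstack([np.ones((n, 1)), phi])            # n x (1+B)
    lam = ridge_lambda * np.eye(design.shape[1])
    lam[0, 0] = 0.0                                       # intercept unpenalized

    converged = False
    for _ in range(max_iter):
        z_cos = _normalize_rows(z_corr)

        # --- diversity-penalized soft k-means with block updates
        dist2 = 2.0 * (1.0 - z_cos @ centers.T)           # n x K
        r = np.exp(-dist2 / sigma)
        r /= r.sum(axis=1, keepdims=True)
        o = r.T @ phi                                     # K x B observed
        e = np.outer(r.sum(axis=0), batch_freq)           # K x B expected
        block = max(1, int(np.ceil(block_fraction * n)))
        for _ in range(kmeans_rounds):
            centers = _normalize_rows(r.T @ z_cos)
            dist2 = 2.0 * (1.0 - z_cos @ centers.T)
            order = rng.permutation(n)
            for start in range(0, n, block):
                idx = order[start:start + block]
                o -= r[idx].T @ phi[idx]
                e -= np.outer(r[idx].sum(axis=0), batch_freq)
                penalty = np.power((e + 1.0) / (o + 1.0), theta)   # K x B
                r_idx = np.exp(-dist2[idx] / sigma) * (phi[idx] @ penalty.T)
                r_idx /= np.maximum(r_idx.sum(axis=1, keepdims=True), 1e-300)
                r[idx] = r_idx
                o += r[idx].T @ phi[idx]
                e += np.outer(r[idx].sum(axis=0), batch_freq)

        # --- per-cluster ridge correction in the original space
        correction = np.zeros_like(z_corr)
        for k in range(nclust):
            w = r[:, k]
            xtwx = design.T @ (design * w[:, None])
            beta = np.linalg.solve(xtwx + lam, design.T @ (matrix * w[:, None]))
            beta[0, :] = 0.0                              # keep the cluster mean
            correction += (w[:, None] * (design @ beta))
        z_new = matrix - correction
        shift = float(np.max(np.abs(z_new - z_corr)))
        z_corr = z_new
        if shift < 1e-4:
            converged = True
            break

    return CorrectedEmbedding(matrix=z_corr, batch_labels=batch_labels,
                              nclust=nclust, max_iter=max_iter, seed=seed,
                              converged=converged)


def batch_mixing_score(matrix: np.ndarray, batch_labels: np.ndarray,
                       k: int = 30) -> float:
    """Mean normalized entropy of batch labels among k nearest neighbors.

    1 means batches are perfectly interleaved locally, 0 means fully
    separated. A single batch scores 1 by convention.
    """
    if k <= 0:
        raise ConfigError("neighbor count k must be positive")
    matrix = np.asarray(matrix, dtype=np.float64)
    batch_labels = np.asarray(batch_labels).astype(str)
    n = matrix.shape[0]
    if k >= n:
        raise ConfigError("k must be smaller than the number of events")
    batches, codes = np.unique(batch_labels, return_inverse=True)
    n_batches = len(batches)
    if n_batches < 2:
        return 1.0

    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute", metric="euclidean")
    nn.fit(matrix)
    _, idx = nn.kneighbors(matrix)
    neigh_codes = codes[idx[:, 1:]]                       # drop self
    counts = np.zeros((n, n_batches))
    for b in range(n_batches):
        counts[:, b] = (neigh_codes == b).sum(axis=1)
    p = counts / k
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.where(p > 0, p * np.log(p), 0.0).sum(axis=1)
    return float(np.mean(ent) / np.log(n_batches))
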