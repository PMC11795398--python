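"""Out-of-sample annotation by kNN majority vote.

Only the down-sampled events are clustered and annotated; the remaining
events are labeled afterwards by exact k-nearest-neighbor majority vote
(k = 20 by default) over the full cohort, with a confidence threshold
(default X = 80%): an event whose majority label carries less than X% of
its annotated neighbors is discarded from downstream analysis rather than
mislabeled. The per-cell-type percent mapped flags blended or transient
populations that fail to transfer cleanly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .exceptions import ConfigError


@dataclass(frozen=True)
class IntegrationParams:
    """Label-transfer knobs: neighbor count and confidence threshold.

    ``denominator`` selects the confidence basis: ``"annotated"`` divides
    the majority count by the number of annotated neighbors (default);
    ``"k"`` divides by k regardless of how many neighbors were annotated.
    """

    k: int = 20
    confidence_threshold: float = 80.0    # percent
    denominator: str = "annotated"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ConfigError("k must be >= 1")
        if not (0 < self.confidence_threshold <= 100):
            raise ConfigError("confidence threshold must be in (0, 100]")
        if self.denominator not in ("annotated", "k"):
            raise ConfigError("denominator must be 'annotated' or 'k'")


@dataclass
class TransferResult:
    """Per out-of-sample event transfer outcome."""

    candidate_index: np.ndarray     # global indices of out-of-sample events
    assigned: np.ndarray            # label or "" when discarded
    discarded: np.ndarray           # bool
    confidence: np.ndarray          # majority fraction in [0, 1]
    annotated_neighbor_count: np.ndarray
    plurality: np.ndarray           # majority label even when discarded ("" if none)
    params: IntegrationParams

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "event": self.candidate_index,
            "assigned": self.assigned,
            "discarded": self.discarded,
            "confidence": self.confidence,
            "annotated_neighbors": self.annotated_neighbor_count,
            "plurality": self.plurality,
        })


def build_full_knn(matrix: np.ndarray, k: int = 20) -> np.ndarray:
    """Exact Euclidean k-nearest-neighbor lists over all events, self excluded.

    Brute-force-equal exactness is part of the contract; any accelerated
    backend must produce identical lists.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    n = matrix.shape[0]
    if n < 2:
        raise ConfigError("need at least 2 events")
    if k >= n:
        warnings.warn(f"k={k} >= n={n}; truncating to {n - 1}", stacklevel=2)
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="brute", metric="euclidean")
    nn.fit(matrix)
    _, idx = nn.kneighbors(matrix)
    is_self = idx == np.arange(n)[:, None]
    order = np.argsort(is_self, axis=1, kind="stable")
    return np.take_along_axis(idx, order, axis=1)[:, :k].astype(np.int64)


def annotate_out_of_sample(neighbors: np.ndarray,
                           annotated_labels: dict[int, str] | pd.Series,
                           params: IntegrationParams = IntegrationParams(),
                           candidates: np.ndarray | None = None
                           ) -> TransferResult:
    """Majority-vote labels for events absent from ``annotated_labels``.

    The vote is restricted to annotated neighbors. An event is discarded
    when it has no annotated neighbor, when the vote ties, or when the
    majority fraction falls below the confidence threshold; the plurality
    label is still recorded for percent-mapped accounting.
    """
    if isinstance(annotated_labels, pd.Series):
        annotated_labels = {int(i): str(v) for i, v in annotated_labels.items()}
    n = neighbors.shape[0]
    label_arr = np.array([annotated_labels.get(i, "") for i in range(n)],
                         dtype=object)
    if candidates is None:
        candidates = np.array([i for i in range(n) if i not in annotated_labels],
                              dtype=np.int64)
    else:
        candidates = np.asarray(candidates, dtype=np.int64)

    threshold = params.confidence_threshold / 100.0
    assigned = np.empty(len(candidates), dtype=object)
    plurality = np.empty(len(candidates), dtype=object)
    discarded = np.zeros(len(candidates), dtype=bool)
    confidence = np.zeros(len(candidates))
    ann_count = np.zeros(len(candidates), dtype=np.int64)

    for row, event in enumerate(candidates):
        neigh_labels = label_arr[neighbors[event]]
        neigh_labels = neigh_labels[neigh_labels != ""]
        ann_count[row] = len(neigh_labels)
        if len(neigh_labels) == 0:
            assigned[row], plurality[row] = "", ""
            discarded[row] = True
            continue
        values, counts = np.unique(neigh_labels.astype(str), return_counts=True)
        top = counts.max()
        winners = values[counts == top]
        denom = params.k if params.denominator == "k" else len(neigh_labels)
        conf = top / denom
        confidence[row] = conf
        if len(winners) > 1:            # tie -> discard, no plurality label
            assigned[row], plurality[row] = "", ""
            discarded[row] = True
            continue
        plurality[row] = str(winners[0])
        if conf >= threshold:
            assigned[row] = str(winners[0])
        else:
            assigned[row] = ""
            discarded[row] = True
    return TransferResult(candidate_index=candidates, assigned=assigned,
                          discarded=discarded, confidence=confidence,
                          annotated_neighbor_count=ann_count,
                          plurality=plurality, params=params)


def percent_mapped(result: TransferResult,
                   annotated_labels: dict[int, str] | pd.Series) -> pd.DataFrame:
    """Percent of each cell type's transfer candidates that were retained.

    For a type t: 100 * retained(t) / (retained(t) + discarded whose
    plurality label was t). Types with no candidates are reported with a
    missing value (not 0). All annotated types get a row.
    """
    if isinstance(annotated_labels, pd.Series):
        annotated_labels = {int(i): str(v) for i, v in annotated_labels.items()}
    types = sorted(set(map(str, annotated_labels.values())))
    rows = []
    for t in types:
        retained = int(((~result.discarded) & (result.assigned == t)).sum())
        dropped = int((result.discarded & (result.plurality == t)).sum())
        total = retained + dropped
        rows.append({"cell_type": t,
                     "candidates": total,
                     "retained": retained,
                     "percent_mapped": 100.0 * retained / total if total else np.nan})
    return pd.DataFrame(rows, columns=["cell_type", "candidates", "retained",
                                       "percent_mapped"])
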