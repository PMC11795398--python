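"""Cluster-level marker summaries and rule-based cell-type assignment.

For every (cluster, marker) pair the module computes the summary
statistics behind cluster-marker dot plots: mean display-scale intensity,
grand-mean-centered intensity ("mean corrected"), log-fold change (the
difference of display-scale means between the cluster and all other
events — display units are decade-linear at high intensity, so a
difference of means reads as a log-fold change), and the fraction of
cluster events above the marker's negative-peak landmark. Cell types are
then assigned by an ordered rule list over these statistics, replacing
the manual annotation step with a reproducible, testable one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cluster import ClusterAssignment
from .exceptions import ConfigError, FlowPhenoError
from .io_model import EventTable

VALUE_FIELDS = ("mean", "mean_corrected", "lfc", "fraction_positive")


@dataclass
class AnnotationStats:
    """Per-(cluster, marker) summary table plus cluster sizes."""

    table: pd.DataFrame            # index (cluster, marker); columns VALUE_FIELDS
    cluster_sizes: dict[str, int]
    landmarks: dict[str, float]

    def value(self, cluster: str, marker: str, field: str) -> float:
        if field not in VALUE_FIELDS:
            raise ConfigError(f"unknown stats field {field!r}")
        return float(self.table.loc[(cluster, marker), field])

    @property
    def clusters(self) -> list[str]:
        return sorted(self.cluster_sizes)


@dataclass
class AnnotationMap:
    """Leaf cluster label -> cell-type name with provenance."""

    mapping: dict[str, str]
    provenance: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"cluster": c, "cell_type": t,
              "provenance": self.provenance.get(c, "manual")}
             for c, t in sorted(self.mapping.items())])


@dataclass
class Rule:
    """One annotation rule: a conjunction of marker predicates."""

    cell_type: str
    predicates: list[dict]   # each: {marker, field, op (">="|"<="), threshold}

    def matches(self, stats: AnnotationStats, cluster: str) -> bool:
        for pred in self.predicates:
            value = stats.value(cluster, pred["marker"], pred["field"])
            thr = float(pred["threshold"])
            op = pred.get("op", ">=")
            if op == ">=":
                ok = value >= thr
            elif op == "<=":
                ok = value <= thr
            elif op == ">":
                ok = value > thr
            elif op == "<":
                ok = value < thr
            else:
                raise ConfigError(f"unknown predicate op {op!r}")
            if not ok:
                return False
        return True


@dataclass
class RuleSet:
    """Ordered annotation rules with a fallback label."""

    rules: list[Rule]
    fallback: str = "Unassigned"

    def __post_init__(self) -> None:
        if not self.rules:
            raise ConfigError("RuleSet needs at least one rule")
        for rule in self.rules:
            for pred in rule.predicates:
                if not np.isfinite(float(pred["threshold"])):
                    raise ConfigError("rule thresholds must be finite")
                if pred.get("field", "mean") not in VALUE_FIELDS:
                    raise ConfigError(f"unknown rule field {pred.get('field')!r}")

    @classmethod
    def from_config(cls, entries: list[dict], fallback: str = "Unassigned") -> "RuleSet":
        rules = []
        for entry in entries:
            preds = [dict(marker=p["marker"], field=p.get("field", "mean"),
                          op=p.get("op", ">="), threshold=p["threshold"])
                     for p in entry["predicates"]]
            rules.append(Rule(cell_type=entry["cell_type"], predicates=preds))
        return cls(rules=rules, fallback=fallback)


def cluster_marker_stats(events: EventTable, assignment: ClusterAssignment,
                         landmarks: dict[str, float] | None = None
                         ) -> AnnotationStats:
    """Compute the dot-plot summary statistics for every leaf cluster.

    ``landmarks`` gives the per-marker display-scale position separating
    negative from positive events (defaults to 0 fraction-positive basis
    of 0.0 when missing, i.e. everything counts as positive unless a
    landmark is supplied). Grand means are unweighted over all events.
    Empty clusters are excluded with a warning.
    """
    if events.scale != "transformed":
        raise ConfigError("cluster_marker_stats requires transformed events")
    labels = np.asarray(assignment.labels, dtype=object)
    if len(labels) != events.n_events:
        raise FlowPhenoError("assignment does not cover the event table")
    landmarks = landmarks or {}

    grand_mean = events.intensities.mean(axis=0)
    rows = []
    sizes: dict[str, int] = {}
    n_total = events.n_events
    for cluster in sorted(set(labels.tolist())):
        members = labels == cluster
        size = int(members.sum())
        if size == 0:
            warnings.warn(f"cluster {cluster!r} is empty; excluded", stacklevel=2)
            continue
        sizes[cluster] = size
        sub = events.intensities[members]
        rest = events.intensities[~members]
        for j, marker in enumerate(events.marker_names):
            mean = float(sub[:, j].mean())
            rest_mean = float(rest[:, j].mean()) if len(rest) else mean
            landmark = float(landmarks.get(marker, 0.0))
            rows.append({
                "cluster": cluster, "marker": marker,
                "mean": mean,
                "mean_corrected": mean - float(grand_mean[j]),
                "lfc": mean - rest_mean if n_total > size else 0.0,
                "fraction_positive": float((sub[:, j] > landmark).mean()),
            })
    table = pd.DataFrame(rows).set_index(["cluster", "marker"])
    return AnnotationStats(table=table, cluster_sizes=sizes,
                           landmarks={m: float(v) for m, v in landmarks.items()})


def default_landmarks(shift_table, panel_markers: list[str],
                      bandwidths: dict[str, float] | None = None,
                      negative_peaks: dict[str, float] | None = None
                      ) -> dict[str, float]:
    """Fraction-positive landmarks: aligned negative peak + 2x KDE bandwidth."""
    negative_peaks = negative_peaks or {}
    bandwidths = bandwidths or {}
    return {m: negative_peaks.get(m, 0.0) + 2.0 * bandwidths.get(m, 0.0)
            for m in panel_markers}


def assign_cell_types(stats: AnnotationStats, rules: RuleSet) -> AnnotationMap:
    """Label every leaf cluster with the first matching rule (order wins)."""
    mapping: dict[str, str] = {}
    provenance: dict[str, str] = {}
    for cluster in stats.clusters:
        for i, rule in enumerate(rules.rules):
            if rule.matches(stats, cluster):
                mapping[cluster] = rule.cell_type
                provenance[cluster] = f"rule:{i}"
                break
        else:
            mapping[cluster] = rules.fallback
            provenance[cluster] = "fallback"
    return AnnotationMap(mapping=mapping, provenance=provenance)


def dot_plot_table(stats: AnnotationStats, value_field: str = "mean_corrected"
                   ) -> pd.DataFrame:
    """Long-format (cluster, marker, value, cluster_size) table for plotting.

    Rows are ordered by cluster label then by the marker order of the
    underlying panel (the order statistics were computed in).
    """
    if value_field not in VALUE_FIELDS:
        raise ConfigError(f"unknown value field {value_field!r}; "
                          f"choose from {VALUE_FIELDS}")
    if stats.table.empty:
        return pd.DataFrame(columns=["cluster", "marker", "value", "cluster_size"])
    out = stats.table[[value_field]].rename(columns={value_field: "value"})
    out = out.reset_index()
    out["cluster_size"] = out["cluster"].map(stats.cluster_sizes)
    # preserve panel marker order within each cluster
    marker_order = {m: i for i, m in
                    enumerate(dict.fromkeys(stats.table.index.get_level_values(1)))}
    out["_m"] = out["marker"].map(marker_order)
    out = out.sort_values(["cluster", "_m"], kind="stable").drop(columns="_m")
    return out.reset_index(drop=True)


def plot_dot_plot(stats: AnnotationStats, value_field: str = "mean_corrected",
                  ax=None):
    """Static cluster x marker dot plot (color = value, size = fraction+)."""
    import matplotlib.pyplot as plt

    table = dot_plot_table(stats, value_field)
    frac = dot_plot_table(stats, "fraction_positive").rename(
        columns={"value": "frac"})
    table = table.merge(frac[["cluster", "marker", "frac"]],
                        on=["cluster", "marker"])
    clusters = sorted(table["cluster"].unique())
    markers = list(dict.fromkeys(table["marker"]))
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.5 * len(markers),
                                      1 + 0.4 * len(clusters)))
    x = table["marker"].map({m: i for i, m in enumerate(markers)})
    y = table["cluster"].map({c: i for i, c in enumerate(clusters)})
    sc = ax.scatter(x, y, c=table["value"], s=20 + 180 * table["frac"],
                    cmap="coolwarm")
    ax.set_xticks(range(len(markers)), markers, rotation=90)
    ax.set_yticks(range(len(clusters)), clusters)
    ax.figure.colorbar(sc, ax=ax, label=value_field)
    return ax
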