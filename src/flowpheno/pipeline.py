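"""End-to-end orchestration of the six pipeline stages.

Stage order: preprocessing (read + pregate + logicle), aligning and
thresholding (negative-peak batch alignment; the gate thresholds belong
to preprocessing but are configured alongside), batch correction
(balanced down-sampling + Harmony), clustering (kNN graph + Leiden +
subclustering), integration (kNN majority-vote label transfer), and
analysis (per-sample proportions + group statistics). Every artifact is
a delimited text file or JSON in the run directory, and the manifest
records versions, seeds, parameters, and per-stage event counts so a run
can be replayed from it alone.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .annotate import (AnnotationMap, RuleSet, assign_cell_types,
                       cluster_marker_stats)
from .batch_integrate import balanced_downsample, harmony_correct
from .cluster import (build_knn_graph, consolidate, leiden_cluster,
                      subcluster, umap_embed)
from .config import RunConfig, validate_config
from .exceptions import FlowPhenoError
from .integrate import (IntegrationParams, annotate_out_of_sample,
                        build_full_knn, percent_mapped)
from .io_model import (EventTable, GateSpec, RatioGate, ThresholdGate,
                       load_sample_sheet_events, read_sample_sheet)
from .stats import cell_proportions, compare_groups
from .synthetic import _three_population_config, generate_cohort
from .transform import (TransformParams, apply_panel_transform, apply_shifts,
                        detect_negative_peak, estimate_batch_shifts,
                        silverman_bandwidth, default_panel)

log = logging.getLogger("flowpheno")

_FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _gates_from_config(entries: list[dict]) -> GateSpec:
    gates = []
    for g in entries:
        kind = g.get("kind", "threshold")
        if kind == "threshold":
            gates.append(ThresholdGate(marker=g["marker"],
                                       direction=g.get("direction", "below"),
                                       cutoff=float(g["cutoff"]),
                                       scale=g.get("scale", "raw"),
                                       name=g.get("name", "")))
        elif kind == "ratio":
            gates.append(RatioGate(numerator=g["numerator"],
                                   denominator=g["denominator"],
                                   min=float(g["min"]), max=float(g["max"]),
                                   scale=g.get("scale", "raw"),
                                   name=g.get("name", "")))
        else:
            raise FlowPhenoError(f"unknown gate kind {kind!r}")
    return GateSpec(gates=gates)


def _load_events(config: RunConfig) -> EventTable:
    if config["simulate.enabled"]:
        sim_seed = config.seed_for("simulate")
        cohort = _three_population_config(
            sim_seed,
            samples_per_group=dict(config["simulate.samples_per_group"]),
            group_effects={g: dict(v) for g, v in
                           config["simulate.group_effects"].items()},
            batch_shifts={b: dict(v) for b, v in
                          config["simulate.batch_shifts"].items()},
            events_per_sample=float(config["simulate.events_per_sample"]))
        events, _ = generate_cohort(cohort)
        return events
    sheet = read_sample_sheet(config["input.sample_sheet"])
    return load_sample_sheet_events(sheet, config["input.base_dir"])


def run_pipeline(config: RunConfig | str | Path,
                 output_dir: str | Path | None = None) -> Path:
    """Execute the configured stages; returns the run directory.

    A stage failure aborts the run with the stage name; artifacts written
    so far are kept next to a ``FAILED`` marker file.
    """
    if not isinstance(config, RunConfig):
        config = validate_config(config)
    out = Path(output_dir or config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": config.data,
        "stage_counts": {},
        "seeds": {},
        "stages_run": [],
    }
    stage = "preprocessing"
    try:
        # ---------------- preprocessing
        events = _load_events(config)
        manifest["stage_counts"]["input_events"] = events.n_events
        gates = _gates_from_config(config["gates"])
        if gates.gates:
            events, retention = pregate_stage(events, gates, out)
            manifest["stage_counts"]["after_pregate"] = events.n_events
        params = TransformParams(T=float(config["transform.T"]),
                                 W=float(config["transform.W"]),
                                 M=float(config["transform.M"]),
                                 A=float(config["transform.A"]))
        panel = default_panel(events.marker_names, params)
        events = apply_panel_transform(events, panel)
        manifest["stages_run"].append(stage)

        # ---------------- aligning and thresholding
        stage = "alignment"
        batches = events.event_meta["batch_id"].astype(str).unique()
        if config["align.enabled"] and len(batches) > 1:
            shifts = estimate_batch_shifts(
                events,
                reference=config["align.reference_batch"],
                fmo_landmarks={k: float(v) for k, v in
                               config["align.fmo_landmarks"].items()})
            for batch, per_marker in config["align.manual_shifts"].items():
                for marker, value in per_marker.items():
                    shifts.shifts[(str(batch), marker)] = float(value)
            events = apply_shifts(events, shifts)
            _write(shifts.to_frame(), out / "batch_shifts.csv")
        manifest["stages_run"].append(stage)

        # write the transformed/aligned events
        from .io_model import write_events_delimited
        write_events_delimited(events, out / "events_transformed.csv")

        # ---------------- batch correction
        stage = "batch_correction"
        ds_seed = config.seed_for("downsample")
        manifest["seeds"]["downsample"] = ds_seed
        ds = balanced_downsample(events, cap=int(config["downsample.cap"]),
                                 seed=ds_seed)
        _write(pd.DataFrame({"event": ds.selected}), out / "downsample_manifest.csv")
        manifest["stage_counts"]["downsampled"] = int(len(ds.selected))
        manifest["downsample_per_batch"] = ds.per_batch_counts
        sub_events = events.subset(ds.selected)

        matrix = sub_events.intensities
        if config["pca.enabled"]:
            from sklearn.decomposition import PCA
            pca = PCA(n_components=min(int(config["pca.dims"]),
                                       matrix.shape[1]),
                      random_state=config.seed_for("harmony"))
            matrix = pca.fit_transform(matrix)
        h_seed = config.seed_for("harmony")
        manifest["seeds"]["harmony"] = h_seed
        if config["harmony.enabled"] and len(batches) > 1:
            corrected = harmony_correct(
                matrix, sub_events.event_meta["batch_id"].to_numpy(),
                nclust=config.get("harmony.nclust"),
                max_iter=int(config["harmony.max_iter"]), seed=h_seed)
            embedding = corrected.matrix
        else:
            embedding = np.asarray(matrix, dtype=np.float64)
        _write(pd.DataFrame(embedding,
                            columns=[f"dim{i+1}" for i in range(embedding.shape[1])]),
               out / "corrected_embedding.csv")
        manifest["stages_run"].append(stage)

        # ---------------- clustering
        stage = "clustering"
        c_seed = config.seed_for("cluster")
        manifest["seeds"]["cluster"] = c_seed
        graph = build_knn_graph(embedding, k=int(config["cluster.k"]),
                                metric=config["cluster.metric"],
                                weighting=config["cluster.weighting"])
        assignment = leiden_cluster(graph,
                                    resolution=float(config["cluster.resolution"]),
                                    seed=c_seed)
        for step in config["subcluster"]:
            assignment = subcluster(graph, assignment, str(step["target"]),
                                    resolution=float(step.get("resolution", 1.0)),
                                    seed=c_seed)
        manifest["stage_counts"]["clusters"] = len(assignment.leaf_labels)

        landmarks = {}
        for marker in events.marker_names:
            col = sub_events.column(marker)
            try:
                landmarks[marker] = (detect_negative_peak(col)
                                     + 2.0 * silverman_bandwidth(col))
            except FlowPhenoError:
                landmarks[marker] = 0.0
        stats = cluster_marker_stats(sub_events, assignment, landmarks)
        _write(stats.table.reset_index(), out / "annotation_stats.csv")

        rules = config["annotate.rules"]
        if rules:
            ruleset = RuleSet.from_config(rules,
                                          fallback=config["annotate.fallback"])
            annotation = assign_cell_types(stats, ruleset)
            if config["annotate.consolidate"]:
                assignment = consolidate(assignment, annotation)
                stats = cluster_marker_stats(sub_events, assignment, landmarks)
                annotation = AnnotationMap(
                    mapping={leaf: annotation.mapping[leaf]
                             for leaf in assignment.leaf_labels},
                    provenance={leaf: annotation.provenance[leaf]
                                for leaf in assignment.leaf_labels})
        else:
            annotation = AnnotationMap(
                mapping={leaf: f"cluster_{leaf}"
                         for leaf in assignment.leaf_labels},
                provenance={leaf: "identity"
                            for leaf in assignment.leaf_labels})
        _write(assignment.to_frame(), out / "cluster_assignment.csv")
        _write(annotation.to_frame(), out / "annotation_map.csv")
        manifest["stages_run"].append(stage)

        if config["umap.enabled"]:
            u_seed = config.seed_for("umap")
            manifest["seeds"]["umap"] = u_seed
            coords = umap_embed(embedding, seed=u_seed,
                                n_neighbors=int(config["umap.n_neighbors"]))
            _write(pd.DataFrame(coords, columns=["umap1", "umap2"]),
                   out / "umap_coordinates.csv")

        # ---------------- integration
        stage = "integration"
        cell_type_of = {i: annotation.mapping[assignment.labels[row]]
                        for row, i in enumerate(ds.selected)}
        all_labels = np.full(events.n_events, "", dtype=object)
        for i, t in cell_type_of.items():
            all_labels[i] = t
        retained_mask = np.zeros(events.n_events, dtype=bool)
        retained_mask[ds.selected] = True
        if config["integrate.enabled"] and len(ds.selected) < events.n_events:
            iparams = IntegrationParams(
                k=int(config["integrate.k"]),
                confidence_threshold=float(config["integrate.confidence_threshold"]),
                denominator=config["integrate.denominator"])
            neighbors = build_full_knn(events.intensities, k=iparams.k)
            transfer = annotate_out_of_sample(neighbors, cell_type_of, iparams)
            _write(transfer.to_frame(), out / "transfer_result.csv")
            _write(percent_mapped(transfer, cell_type_of),
                   out / "percent_mapped.csv")
            kept = transfer.candidate_index[~transfer.discarded]
            all_labels[kept] = transfer.assigned[~transfer.discarded]
            retained_mask[kept] = True
            manifest["stage_counts"]["transferred"] = int(len(kept))
            manifest["stage_counts"]["discarded"] = int(transfer.discarded.sum())
        manifest["stages_run"].append(stage)

        # ---------------- analysis
        stage = "analysis"
        final = pd.DataFrame({
            "event": np.flatnonzero(retained_mask),
            "cell_type": all_labels[retained_mask],
        })
        _write(final, out / "final_labels.csv")
        proportions = cell_proportions(
            all_labels[retained_mask],
            events.event_meta.iloc[retained_mask].reset_index(drop=True),
            parent_spec=dict(config["analysis.parent_spec"]))
        _write(proportions, out / "proportions.csv")

        group_pair = config["analysis.group_pair"]
        if group_pair is None:
            groups = sorted(events.event_meta["group"].astype(str).unique())
            group_pair = groups[:2] if len(groups) >= 2 else None
        if group_pair is not None:
            comparisons = compare_groups(
                proportions, (str(group_pair[0]), str(group_pair[1])),
                tests=tuple(config["analysis.tests"]),
                min_samples=int(config["analysis.min_samples"]))
            _write(comparisons, out / "comparisons.csv")
        manifest["stages_run"].append(stage)

    except Exception as exc:
        (out / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise FlowPhenoError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    (out / "config_echo.yaml").write_text(config.to_yaml())
    return out


def pregate_stage(events: EventTable, gates: GateSpec,
                  out: Path) -> tuple[EventTable, pd.DataFrame]:
    from .io_model import pregate
    gated, retention = pregate(events, gates)
    _write(retention, out / "pregate_retention.csv")
    return gated, retention


def rerun_analysis(run_dir: str | Path) -> Path:
    """Analysis-only rerun from a run directory's cached artifacts.

    Reads the cached final labels and the echoed config, recomputes the
    proportion and comparison tables, and rewrites them in place — the
    statistical outputs are a pure function of those cached inputs.
    """
    run_dir = Path(run_dir)
    config = validate_config(run_dir / "config_echo.yaml")
    final = pd.read_csv(run_dir / "final_labels.csv")
    events_df = pd.read_csv(run_dir / "events_transformed.csv")
    meta = events_df.iloc[final["event"].to_numpy()][
        ["sample_id", "batch_id", "group"]].reset_index(drop=True)
    proportions = cell_proportions(final["cell_type"].to_numpy(), meta,
                                   parent_spec=dict(config["analysis.parent_spec"]))
    _write(proportions, run_dir / "proportions.csv")
    group_pair = config["analysis.group_pair"]
    if group_pair is None:
        groups = sorted(meta["group"].astype(str).unique())
        group_pair = groups[:2] if len(groups) >= 2 else None
    if group_pair is not None:
        comparisons = compare_groups(proportions,
                                     (str(group_pair[0]), str(group_pair[1])),
                                     tests=tuple(config["analysis.tests"]),
                                     min_samples=int(config["analysis.min_samples"]))
        _write(comparisons, run_dir / "comparisons.csv")
    return run_dir
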