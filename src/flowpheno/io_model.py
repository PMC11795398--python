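"""Core data model and event-level I/O.

The pipeline's shared container is the :class:`EventTable` — an events x
markers intensity matrix plus per-event sample/batch/group metadata and a
scale flag declaring whether the values are raw fluorescence units or
logicle display units. Panels, pregating, and sample sheets are all
declarative configuration applied here, so the rest of the pipeline never
touches files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from . import fcs
from .exceptions import ConfigError, FlowPhenoError

META_COLUMNS = ["sample_id", "batch_id", "group"]

Scale = Literal["raw", "transformed"]


@dataclass
class EventTable:
    """Events x markers intensity matrix with per-event metadata.

    Parameters
    ----------
    intensities
        ``(n_events, n_markers)`` float array. Raw fluorescence units when
        ``scale == "raw"``, logicle display units in [0, 1] when
        ``scale == "transformed"``.
    marker_names
        Unique, ordered marker names matching the columns.
    event_meta
        One row per event with at least ``sample_id``, ``batch_id`` and
        ``group`` columns; a ``population`` column carries ground-truth
        labels for synthetic data.
    scale
        ``"raw"`` or ``"transformed"``; operations declare which they need.
    """

    intensities: np.ndarray
    marker_names: list[str]
    event_meta: pd.DataFrame
    scale: Scale = "raw"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 2:
            raise FlowPhenoError("intensities must be 2-D (events x markers)")
        self.marker_names = list(self.marker_names)
        if len(set(self.marker_names)) != len(self.marker_names):
            raise FlowPhenoError("marker names must be unique")
        if self.intensities.shape[1] != len(self.marker_names):
            raise FlowPhenoError("marker_names length does not match columns")
        if not isinstance(self.event_meta, pd.DataFrame):
            self.event_meta = pd.DataFrame(self.event_meta)
        if len(self.event_meta) != self.intensities.shape[0]:
            raise FlowPhenoError("event_meta rows do not match event count")
        for col in META_COLUMNS:
            if col not in self.event_meta.columns:
                raise FlowPhenoError(f"event_meta missing required column {col!r}")
        if self.scale not in ("raw", "transformed"):
            raise FlowPhenoError(f"unknown scale {self.scale!r}")
        if len(self.event_meta):
            for col in ("sample_id", "batch_id"):
                vals = self.event_meta[col].astype(str)
                if (vals == "").any():
                    raise FlowPhenoError(f"every event needs a nonempty {col}")
        self.event_meta = self.event_meta.reset_index(drop=True)

    @property
    def n_events(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise FlowPhenoError(
                f"marker {name!r} not in table (have {self.marker_names})"
            ) from None

    def column(self, name: str) -> np.ndarray:
        return self.intensities[:, self.marker_index(name)]

    def subset(self, index: np.ndarray) -> "EventTable":
        """Row subset (boolean mask or integer index), order preserved."""
        index = np.asarray(index)
        return EventTable(
            intensities=self.intensities[index],
            marker_names=list(self.marker_names),
            event_meta=self.event_meta.iloc[index].reset_index(drop=True),
            scale=self.scale,
        )

    def with_intensities(self, intensities: np.ndarray,
                         scale: Scale | None = None) -> "EventTable":
        return EventTable(
            intensities=intensities,
            marker_names=list(self.marker_names),
            event_meta=self.event_meta.copy(),
            scale=self.scale if scale is None else scale,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.marker_names)
        return pd.concat([df, self.event_meta.reset_index(drop=True)], axis=1)


@dataclass
class MarkerSpec:
    """One panel entry: a marker, its fluorophore, role and transform."""

    name: str
    fluorophore: str = ""
    role: str = "lineage"  # lineage | activation | viability | scatter
    transform: "TransformParams | None" = None
    fmo_landmark: float | None = None


@dataclass
class PanelSpec:
    """Marker roster with per-marker transform parameters and roles."""

    markers: list[MarkerSpec]

    def __post_init__(self) -> None:
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ConfigError("panel marker names must be unique")
        viability = [m for m in self.markers if m.role == "viability"]
        if len(viability) > 1:
            raise ConfigError("at most one viability-role marker allowed")

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    def get(self, name: str) -> MarkerSpec:
        for m in self.markers:
            if m.name == name:
                return m
        raise ConfigError(f"marker {name!r} not in panel")


@dataclass
class ThresholdGate:
    marker: str
    direction: str            # "below" keeps values < cutoff; "above" keeps >
    cutoff: float
    scale: Scale = "raw"
    name: str = ""

    def __post_init__(self) -> None:
        if self.direction not in ("below", "above"):
            raise ConfigError(f"gate direction must be below/above, got {self.direction!r}")
        if not np.isfinite(self.cutoff):
            raise ConfigError("gate cutoff must be finite")
        if not self.name:
            self.name = f"{self.marker}_{self.direction}_{self.cutoff:g}"


@dataclass
class RatioGate:
    """Keep events whose numerator/denominator channel ratio lies in [min, max]."""

    numerator: str
    denominator: str
    min: float
    max: float
    scale: Scale = "raw"
    name: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.min) and np.isfinite(self.max)):
            raise ConfigError("ratio gate bounds must be finite")
        if self.min >= self.max:
            raise ConfigError("ratio gate requires min < max")
        if not self.name:
            self.name = f"{self.numerator}/{self.denominator}"


@dataclass
class GateSpec:
    """Ordered pregating sequence (debris / dead-cell / aggregate removal)."""

    gates: list[ThresholdGate | RatioGate] = field(default_factory=list)


def read_fcs(path: str | Path, sample_record: dict | None = None) -> EventTable:
    """Read an FCS 3.0/3.1 file into a raw-scale :class:`EventTable`.

    ``sample_record`` supplies the sample-sheet metadata (``sample_id``,
    ``batch_id``, ``group``) attached to every event; when omitted the file
    stem is used as both sample and batch id.
    """
    parsed = fcs.read_fcs_file(str(path))
    n = parsed.events.shape[0]
    if sample_record is None:
        stem = Path(path).stem
        sample_record = {"sample_id": stem, "batch_id": stem, "group": ""}
    meta = pd.DataFrame({
        "sample_id": [str(sample_record.get("sample_id", ""))] * n,
        "batch_id": [str(sample_record.get("batch_id", ""))] * n,
        "group": [str(sample_record.get("group", ""))] * n,
    })
    return EventTable(intensities=parsed.events,
                      marker_names=parsed.channel_names,
                      event_meta=meta, scale="raw")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Read a delimited sample sheet with columns file, sample_id, batch_id, group."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    sheet = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    missing = {"file", "sample_id", "batch_id", "group"} - set(sheet.columns)
    if missing:
        raise ConfigError(f"sample sheet missing columns: {sorted(missing)}")
    return sheet


def read_events_delimited(path: str | Path, sample_sheet: pd.DataFrame) -> EventTable:
    """Read delimited event tables listed in a sample sheet.

    Each file holds a header row of marker names and one numeric row per
    event; the sheet maps files to sample/batch/group. Multiple files for
    the same sample are concatenated in sheet order.
    """
    path = Path(path)
    rows = sample_sheet[sample_sheet["file"].map(lambda f: Path(f).name) == path.name]
    if rows.empty:
        rows = sample_sheet[sample_sheet["file"] == str(path)]
    if rows.empty:
        raise ConfigError(f"file {path.name!r} not listed in the sample sheet")
    record = rows.iloc[0]

    if not path.exists():
        raise FlowPhenoError(f"event file missing on disk: {path}")
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    markers = [str(c) for c in df.columns]
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(np.float64)
        except (ValueError, TypeError):
            bad = df[~df[col].map(_is_number)]
            row = int(bad.index[0]) if len(bad) else -1
            raise FlowPhenoError(
                f"non-numeric value in {path.name} at row {row}, column {col!r}"
            ) from None
    scale: Scale = "transformed" if str(record.get("scale", "")) == "transformed" else "raw"
    n = values.shape[0]
    meta = pd.DataFrame({
        "sample_id": [record["sample_id"]] * n,
        "batch_id": [record["batch_id"]] * n,
        "group": [record["group"]] * n,
    })
    return EventTable(values, markers, meta, scale=scale)


def _is_number(x) -> bool:
    try:
        float(x)
        return True
    except (TypeError, ValueError):
        return False


def load_sample_sheet_events(sheet: pd.DataFrame, base_dir: str | Path = ".") -> EventTable:
    """Read and merge every file listed in a sample sheet (FCS or delimited)."""
    base = Path(base_dir)
    tables = []
    for _, rec in sheet.iterrows():
        fpath = base / rec["file"]
        if fpath.suffix.lower() == ".fcs":
            tables.append(read_fcs(fpath, rec.to_dict()))
        else:
            tables.append(read_events_delimited(fpath, sheet))
    return merge_samples(tables)


def merge_samples(tables: Sequence[EventTable]) -> EventTable:
    """Row-wise concatenation of tables sharing marker order and scale."""
    if not tables:
        raise FlowPhenoError("merge_samples needs at least one table")
    first = tables[0]
    for t in tables[1:]:
        if t.marker_names != first.marker_names:
            extra = set(t.marker_names) ^ set(first.marker_names)
            raise FlowPhenoError(
                "marker mismatch between tables"
                + (f"; differing markers: {sorted(extra)}" if extra
                   else "; same markers in different order (no silent reordering)")
            )
        if t.scale != first.scale:
            raise FlowPhenoError("cannot merge tables on different scales")
    if len(tables) == 1:
        return first.subset(np.arange(first.n_events))
    return EventTable(
        intensities=np.vstack([t.intensities for t in tables]),
        marker_names=list(first.marker_names),
        event_meta=pd.concat([t.event_meta for t in tables], ignore_index=True),
        scale=first.scale,
    )


def pregate(events: EventTable, gates: GateSpec) -> tuple[EventTable, pd.DataFrame]:
    """Apply threshold/ratio gates sequentially; report per-gate retention.

    Returns the gated table and a frame with one row per gate:
    ``gate``, ``retained``, ``fraction_of_input`` (relative to the original
    event count). Gates are applied in order; an event must pass all gates.
    """
    keep = np.ones(events.n_events, dtype=bool)
    records = []
    n0 = events.n_events
    for gate in gates.gates:
        if gate.scale != events.scale:
            warnings.warn(
                f"gate {gate.name!r} declares scale {gate.scale!r} but events are "
                f"{events.scale!r}; applying anyway", stacklevel=2)
        if isinstance(gate, ThresholdGate):
            col = events.column(gate.marker)
            passed = col < gate.cutoff if gate.direction == "below" else col > gate.cutoff
        else:
            num = events.column(gate.numerator)
            den = events.column(gate.denominator)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(den != 0, num / den, np.inf)
            passed = (ratio >= gate.min) & (ratio <= gate.max)
        keep &= passed
        records.append({
            "gate": gate.name,
            "retained": int(keep.sum()),
            "fraction_of_input": float(keep.sum() / n0) if n0 else 1.0,
        })
    return events.subset(keep), pd.DataFrame(records, columns=["gate", "retained",
                                                               "fraction_of_input"])


def write_events_delimited(events: EventTable, path: str | Path) -> None:
    """Serialize an EventTable (intensities + metadata) as CSV."""
    events.to_dataframe().to_csv(path, index=False, float_format="%.10g")
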