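"""Logicle display transform and negative-peak batch alignment.

The logicle is the standard biexponential display scale for cytometry: it
is linear around zero (so negative unmixing residuals remain visible) and
logarithmic at high intensity. Here the display codomain is [0, 1], i.e. a
fraction of the ``M + A`` display decades. The inverse (display -> raw) is
the closed-form biexponential

    B(y) = a * exp(b*y) - c * exp(-d*y) - f,

whose constants are fixed by the parameters (T, W, M, A); the forward
direction solves ``B(y) = x`` numerically.

Batch alignment mimics the first-pass manual correction used on spectral
panels: the negative (left-most) peak of each marker's per-batch intensity
distribution is located by kernel density estimation, and each batch is
shifted additively on the display scale so its negative peaks land on the
reference batch (or on an FMO-derived landmark).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import ConfigError, InsufficientDataError
from .io_model import EventTable, PanelSpec

#: Events below this count cannot support a KDE landmark.
MIN_EVENTS_FOR_LANDMARK = 200

#: KDE evaluation grid size for peak detection.
KDE_GRID_SIZE = 512

#: A local maximum must reach this fraction of the global density maximum
#: to count as a mode.
MODE_SIGNIFICANCE = 0.05


@dataclass(frozen=True)
class TransformParams:
    """Logicle parameters.

    T : top-of-scale intensity (raw units); maps to display position 1.
    W : linearization width in decades around zero.
    M : total display decades.
    A : additional negative display decades.
    """

    T: float = float(2 ** 22)
    W: float = 0.5
    M: float = 4.5
    A: float = 0.0

    def __post_init__(self) -> None:
        if not (self.T > 0):
            raise ConfigError("logicle requires T > 0")
        if not (self.M > 0):
            raise ConfigError("logicle requires M > 0")
        if not (0 <= self.W <= self.M / 2):
            raise ConfigError("logicle requires 0 <= W <= M/2")
        if self.A < -self.W:
            raise ConfigError("logicle requires A >= -W")


class _LogicleScale:
    """Biexponential constants and solvers for one parameter set."""

    def __init__(self, p: TransformParams) -> None:
        self.params = p
        span = p.M + p.A
        w = p.W / span
        x2 = p.A / span
        x1 = x2 + w
        x0 = x2 + 2.0 * w
        b = span * math.log(10.0)

        if w > 0:
            # d solves 2*(ln d - ln b) + w*(b + d) = 0 on (0, b)
            def g(d: float) -> float:
                return 2.0 * (math.log(d) - math.log(b)) + w * (b + d)
            d = optimize.brentq(g, 1e-12 * b, b, xtol=1e-14, rtol=8.9e-16)
        else:
            d = b
        c_a = math.exp(x0 * (b + d))
        mf_a = math.exp(b * x1) - c_a / math.exp(d * x1)
        a = p.T / ((math.exp(b) - mf_a) - c_a / math.exp(d))
        self.a, self.b, self.c, self.d = a, b, c_a * a, d
        self.f = mf_a * a
        self.x1 = x1  # display position of raw 0

        # the biexponential is defined for all real y; extend the working
        # range below 0 far enough to represent x = -0.2*T so strongly
        # negative unmixing residuals still round-trip exactly
        ymin = 0.0
        while self._eval(ymin) > -0.2 * p.T and ymin > -8.0:
            ymin -= 0.25
        self.ymin = ymin
        self._grid_y = np.linspace(ymin, 1.0, 2048)
        self._grid_x = self._eval(self._grid_y)

    def _eval(self, y):
        y = np.asarray(y, dtype=np.float64)
        out = (self.a * np.exp(self.b * y)
               - self.c * np.exp(-self.d * y) - self.f)
        return out if out.ndim else float(out)

    def inverse(self, y: np.ndarray | float) -> np.ndarray | float:
        return self._eval(y)

    def _deriv(self, y: np.ndarray) -> np.ndarray:
        return (self.a * self.b * np.exp(self.b * y)
                + self.c * self.d * np.exp(-self.d * y))

    def forward(self, x: np.ndarray | float, tol: float = 1e-8
                ) -> tuple[np.ndarray | float, int]:
        """Solve B(y) = x; values above B(1) are clamped to y = 1."""
        scalar = np.isscalar(x) or np.ndim(x) == 0
        x = np.atleast_1d(np.asarray(x, dtype=np.float64))
        lo, hi = self._grid_x[0], self._grid_x[-1]
        clipped = np.clip(x, lo, hi)
        eps_hi = 1e-9 * abs(hi) + 1e-12
        eps_lo = 1e-9 * abs(lo) + 1e-12
        n_clamped = int((x > hi + eps_hi).sum() + (x < lo - eps_lo).sum())

        y = np.interp(clipped, self._grid_x, self._grid_y)
        # Newton with bracketing clamp; B is smooth and strictly increasing
        # so this converges quadratically from the interpolated start
        for _ in range(60):
            fy = np.asarray(self._eval(y)) - clipped
            dy = fy / self._deriv(y)
            y = np.clip(y - dy, self.ymin, 1.0)
            if np.max(np.abs(dy)) < tol * 0.5:
                break
        if scalar:
            return float(y[0]), n_clamped
        return y, n_clamped


_SCALE_CACHE: dict[TransformParams, _LogicleScale] = {}


def _scale_for(p: TransformParams) -> _LogicleScale:
    if p not in _SCALE_CACHE:
        _SCALE_CACHE[p] = _LogicleScale(p)
    return _SCALE_CACHE[p]


def logicle_forward(x, params: TransformParams, *, tol: float = 1e-8):
    """Map raw intensity to display position in [0, 1].

    Values beyond the representable range are clamped (a warning is issued
    with the clamp count; no exception).
    """
    y, n_clamped = _scale_for(params).forward(x, tol=tol)
    if n_clamped:
        warnings.warn(f"logicle_forward clamped {n_clamped} value(s) outside "
                      "the display range", stacklevel=2)
    return y


def logicle_inverse(y, params: TransformParams):
    """Map a display position back to raw intensity (closed form).

    The nominal display range is [0, 1]; slightly negative positions (down
    to the extension used by the forward solver for strongly negative raw
    values) are accepted so that forward/inverse round-trip exactly.
    Positions above 1 are a domain error.
    """
    scale = _scale_for(params)
    arr = np.asarray(y, dtype=np.float64)
    if np.any(arr < scale.ymin) or np.any(arr > 1):
        raise ConfigError("logicle_inverse requires y in the display range [0, 1] "
                          "(or its small negative extension)")
    return scale.inverse(y)


def raw_zero_position(params: TransformParams) -> float:
    """Display position of raw intensity 0 (= (A + W) / (M + A))."""
    return _scale_for(params).x1


def apply_panel_transform(events: EventTable, panel: PanelSpec) -> EventTable:
    """Transform every marker of a raw-scale table to display units.

    Fluorescence markers go through their logicle parameters; scatter-role
    channels are linearly rescaled to [0, 1] by their top-of-scale T.
    """
    if events.scale != "raw":
        raise ConfigError("apply_panel_transform requires raw-scale events")
    out = events.intensities.copy()
    for j, name in enumerate(events.marker_names):
        spec = panel.get(name)
        params = spec.transform
        if params is None:
            raise ConfigError(f"marker {name!r} has no transform parameters")
        if spec.role == "scatter":
            out[:, j] = np.clip(out[:, j] / params.T, 0.0, 1.0)
        else:
            out[:, j] = _scale_for(params).forward(out[:, j])[0]
    return events.with_intensities(out, scale="transformed")


def detect_negative_peak(values: np.ndarray) -> float:
    """Locate the negative (lowest-position) density mode of one batch x marker.

    A Gaussian KDE (Silverman bandwidth) is evaluated on a 512-point grid
    over the observed range; the landmark is the smallest-x local maximum
    whose density reaches at least 5% of the global maximum.
    """
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if values.size < MIN_EVENTS_FOR_LANDMARK:
        raise InsufficientDataError(
            f"negative-peak detection needs >= {MIN_EVENTS_FOR_LANDMARK} events, "
            f"got {values.size}")
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    kde = stats.gaussian_kde(values, bw_method="silverman")
    grid = np.linspace(lo, hi, KDE_GRID_SIZE)
    dens = kde(grid)
    peak_floor = MODE_SIGNIFICANCE * dens.max()
    interior = (dens[1:-1] >= dens[:-2]) & (dens[1:-1] > dens[2:])
    candidates = np.flatnonzero(interior) + 1
    # grid endpoints can carry a mode when the distribution is truncated
    if dens[0] > dens[1]:
        candidates = np.concatenate([[0], candidates])
    if dens[-1] > dens[-2]:
        candidates = np.concatenate([candidates, [KDE_GRID_SIZE - 1]])
    candidates = candidates[dens[candidates] >= peak_floor]
    if candidates.size == 0:
        candidates = np.array([int(np.argmax(dens))])
    return float(grid[candidates[0]])


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb KDE bandwidth for one marker's values."""
    values = np.asarray(values, dtype=np.float64)
    values = values[np.isfinite(values)]
    if values.size < 2 or values.std(ddof=1) == 0:
        return 0.0
    kde = stats.gaussian_kde(values, bw_method="silverman")
    return float(kde.factor * values.std(ddof=1))


@dataclass
class BatchShiftTable:
    """Additive per-(batch, marker) shifts on the display scale."""

    shifts: dict[tuple[str, str], float] = field(default_factory=dict)
    reference: str = ""

    def get(self, batch_id: str, marker: str) -> float:
        return self.shifts.get((str(batch_id), marker), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"batch_id": b, "marker": m, "shift": s}
                for (b, m), s in sorted(self.shifts.items())]
        return pd.DataFrame(rows, columns=["batch_id", "marker", "shift"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, reference: str = "") -> "BatchShiftTable":
        shifts = {(str(r.batch_id), str(r.marker)): float(r.shift)
                  for r in frame.itertuples()}
        return cls(shifts=shifts, reference=reference)


def estimate_batch_shifts(events: EventTable, markers: list[str] | None = None,
                          reference: str | None = None,
                          fmo_landmarks: dict[str, float] | None = None,
                          ) -> BatchShiftTable:
    """Estimate additive per-batch shifts aligning negative peaks.

    ``shift(batch, marker) = landmark(reference, marker) − landmark(batch,
    marker)``; the reference batch gets shift 0 for every marker. A marker
    listed in ``fmo_landmarks`` is anchored to that display-scale landmark
    instead of the reference batch. Batches with too few events for a KDE
    fall back to shift 0 with a warning.
    """
    if events.scale != "transformed":
        raise ConfigError("estimate_batch_shifts requires transformed events")
    markers = markers if markers is not None else list(events.marker_names)
    fmo_landmarks = fmo_landmarks or {}
    batches = list(pd.unique(events.event_meta["batch_id"].astype(str)))
    if reference is None:
        reference = batches[0]
    reference = str(reference)
    if reference not in batches:
        raise ConfigError(f"reference batch {reference!r} not present "
                          f"(batches: {batches})")

    batch_col = events.event_meta["batch_id"].astype(str).to_numpy()
    table = BatchShiftTable(reference=reference)
    for marker in markers:
        col = events.column(marker)
        landmarks: dict[str, float | None] = {}
        for b in batches:
            vals = col[batch_col == b]
            try:
                landmarks[b] = detect_negative_peak(vals)
            except InsufficientDataError:
                warnings.warn(f"batch {b!r}, marker {marker!r}: too few events "
                              "for a landmark; shift set to 0", stacklevel=2)
                landmarks[b] = None
        if marker in fmo_landmarks:
            anchor = float(fmo_landmarks[marker])
            for b in batches:
                lm = landmarks[b]
                table.shifts[(b, marker)] = 0.0 if lm is None else anchor - lm
        else:
            ref_lm = landmarks[reference]
            for b in batches:
                lm = landmarks[b]
                if b == reference or lm is None or ref_lm is None:
                    table.shifts[(b, marker)] = 0.0
                else:
                    table.shifts[(b, marker)] = ref_lm - lm
    return table


def apply_shifts(events: EventTable, shifts: BatchShiftTable) -> EventTable:
    """Add each event's batch/marker shift to its display-scale value."""
    if events.scale != "transformed":
        raise ConfigError("apply_shifts requires transformed events")
    out = events.intensities.copy()
    batch_col = events.event_meta["batch_id"].astype(str).to_numpy()
    for j, marker in enumerate(events.marker_names):
        per_batch = {b: shifts.get(b, marker) for b in np.unique(batch_col)}
        if any(per_batch.values()):
            delta = np.array([per_batch[b] for b in batch_col])
            out[:, j] = out[:, j] + delta
    return events.with_intensities(out)


def default_panel(marker_names: list[str], params: TransformParams | None = None,
                  roles: dict[str, str] | None = None) -> PanelSpec:
    """Build a panel applying one TransformParams to every marker."""
    from .io_model import MarkerSpec
    params = params or TransformParams()
    roles = roles or {}
    return PanelSpec(markers=[
        MarkerSpec(name=m, role=roles.get(m, "lineage"), transform=params)
        for m in marker_names
    ])
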