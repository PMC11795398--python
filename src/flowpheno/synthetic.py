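"""Seeded synthetic multi-batch, multi-sample cohort generator.

Emulates the statistical structure of a stained whole-blood cohort as the
pipeline sees it: marker-defined cell populations that are Gaussian on
the logicle display scale, per-batch additive display-scale shifts (what
negative-peak alignment corrects), per-sample population proportions
drawn from a Dirichlet around group-adjusted means (so group effects are
multiplicative proportion shifts), and optional debris/blended events.
Events are mapped through the inverse logicle to raw intensities, so the
generated files exercise the full preprocessing path. Everything is
reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io_model import EventTable
from .transform import TransformParams, _scale_for


@dataclass
class PopulationSpec:
    """One cell population: per-marker display-scale mean and sd."""

    name: str
    means: dict[str, float]
    sds: dict[str, float]


@dataclass
class OverlapSpec:
    """A blended population placed between two parents.

    Each event draws its own mixing coefficient ``u`` uniformly from
    ``[mix - spread/2, mix + spread/2]`` and sits at
    ``u * mean(pop_a) + (1 - u) * mean(pop_b)`` (sds interpolated the same
    way), so a positive ``spread`` produces a diffuse bridge between the
    parents — a transitional population without a crisp identity of its
    own. ``spread = 0`` gives a tight cluster at the midpoint.
    """

    name: str
    pop_a: str
    pop_b: str
    mix: float = 0.5
    spread: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.mix - self.spread / 2, self.mix + self.spread / 2
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigError("overlap mix +/- spread/2 must stay in [0, 1]")


@dataclass
class CohortConfig:
    """Full description of a synthetic cohort.

    ``group_effects[group][population]`` multiplies that population's
    baseline proportion for samples of that group; the shifted vector is
    renormalized. ``batch_shifts[batch][marker]`` is an additive
    display-scale shift. Samples are assigned to batches round-robin in
    sample order.
    """

    populations: list[PopulationSpec]
    baseline_proportions: dict[str, float]
    samples_per_group: dict[str, int]
    seed: int
    events_per_sample: float = 2000.0       # lognormal location (events)
    events_sigma: float = 0.25              # lognormal sigma (log-units)
    dirichlet_concentration: float = 200.0
    group_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    batch_shifts: dict[str, dict[str, float]] = field(default_factory=dict)
    overlaps: list[OverlapSpec] = field(default_factory=list)
    transform: TransformParams = field(default_factory=TransformParams)
    markers: list[str] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory")
        pop_names = [p.name for p in self.populations]
        if len(set(pop_names)) != len(pop_names):
            raise ConfigError("population names must be unique")
        if set(self.baseline_proportions) != set(pop_names) | {
                o.name for o in self.overlaps}:
            missing = (set(pop_names) | {o.name for o in self.overlaps}) \
                - set(self.baseline_proportions)
            extra = set(self.baseline_proportions) - set(pop_names) \
                - {o.name for o in self.overlaps}
            raise ConfigError(f"baseline_proportions mismatch "
                              f"(missing {sorted(missing)}, extra {sorted(extra)})")
        total = sum(self.baseline_proportions.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ConfigError(f"baseline proportions must sum to 1 (got {total})")
        if self.markers is None:
            self.markers = list(self.populations[0].means)
        for pop in self.populations:
            if set(pop.means) != set(self.markers) or set(pop.sds) != set(self.markers):
                raise ConfigError(f"population {pop.name!r} does not cover "
                                  "every marker")
            if any(s <= 0 for s in pop.sds.values()):
                raise ConfigError(f"population {pop.name!r} has non-positive sd")
        if self.events_per_sample <= 0 or self.events_sigma < 0:
            raise ConfigError("invalid events-per-sample parameters")
        if self.dirichlet_concentration <= 0:
            raise ConfigError("dirichlet concentration must be positive")

    @property
    def batches(self) -> list[str]:
        return sorted(self.batch_shifts) if self.batch_shifts else ["batch1"]

    def all_populations(self) -> list[PopulationSpec]:
        """Declared populations plus expanded overlap blends."""
        by_name = {p.name: p for p in self.populations}
        out = list(self.populations)
        for ov in self.overlaps:
            a, b = by_name[ov.pop_a], by_name[ov.pop_b]
            out.append(PopulationSpec(
                name=ov.name,
                means={m: ov.mix * a.means[m] + (1 - ov.mix) * b.means[m]
                       for m in self.markers},
                sds={m: ov.mix * a.sds[m] + (1 - ov.mix) * b.sds[m]
                     for m in self.markers},
            ))
        return out


@dataclass
class GroundTruth:
    """Row-for-row truth for a generated cohort."""

    population: np.ndarray               # per-event population label
    sample_proportions: pd.DataFrame     # sample_id x population true draws
    batch_shifts: dict[str, dict[str, float]]
    sample_groups: dict[str, str]
    sample_batches: dict[str, str]
    display_intensities: np.ndarray      # pre-inverse display-scale matrix
    config: CohortConfig


def _group_adjusted_means(config: CohortConfig) -> dict[str, np.ndarray]:
    pops = [p.name for p in config.all_populations()]
    base = np.array([config.baseline_proportions[p] for p in pops])
    out = {}
    for group in config.samples_per_group:
        mult = np.array([config.group_effects.get(group, {}).get(p, 1.0)
                         for p in pops])
        vec = base * mult
        out[group] = vec / vec.sum()
    return out


def draw_sample_proportions(config: CohortConfig, group: str,
                            rng: np.random.Generator) -> np.ndarray:
    """One Dirichlet draw around the group-adjusted proportion mean."""
    mean = _group_adjusted_means(config)[group]
    alpha = np.maximum(mean * config.dirichlet_concentration, 1e-6)
    return rng.dirichlet(alpha)


def generate_cohort(config: CohortConfig) -> tuple[EventTable, GroundTruth]:
    """Generate a raw-scale cohort plus its row-for-row ground truth."""
    rng = np.random.default_rng(config.seed)
    pops = config.all_populations()
    pop_names = [p.name for p in pops]
    markers = list(config.markers)
    batches = config.batches
    scale = _scale_for(config.transform)
    ymin, ymax = scale.ymin, 1.0

    blocks, meta_rows, labels = [], [], []
    prop_rows = []
    sample_groups: dict[str, str] = {}
    sample_batches: dict[str, str] = {}
    sample_counter = 0
    for group in sorted(config.samples_per_group):
        for i in range(config.samples_per_group[group]):
            sample_id = f"{group}_s{i + 1:02d}"
            batch = batches[sample_counter % len(batches)]
            sample_counter += 1
            sample_groups[sample_id] = group
            sample_batches[sample_id] = batch

            props = draw_sample_proportions(config, group, rng)
            prop_rows.append({"sample_id": sample_id, "group": group,
                              **dict(zip(pop_names, props))})
            n_events = max(1, int(round(rng.lognormal(
                mean=np.log(config.events_per_sample),
                sigma=config.events_sigma))))
            counts = rng.multinomial(n_events, props)
            shift = config.batch_shifts.get(batch, {})
            overlap_by_name = {o.name: o for o in config.overlaps}
            pop_by_name = {p.name: p for p in config.populations}
            for pop, count in zip(pops, counts):
                if count == 0:
                    continue
                block = np.empty((count, len(markers)))
                if pop.name in overlap_by_name:
                    ov = overlap_by_name[pop.name]
                    pa, pb = pop_by_name[ov.pop_a], pop_by_name[ov.pop_b]
                    u = rng.uniform(ov.mix - ov.spread / 2,
                                    ov.mix + ov.spread / 2, count)
                    for j, m in enumerate(markers):
                        mean = u * pa.means[m] + (1 - u) * pb.means[m]
                        sd = u * pa.sds[m] + (1 - u) * pb.sds[m]
                        block[:, j] = rng.normal(mean, sd) + shift.get(m, 0.0)
                else:
                    for j, m in enumerate(markers):
                        block[:, j] = rng.normal(pop.means[m], pop.sds[m],
                                                 count) + shift.get(m, 0.0)
                blocks.append(block)
                labels.extend([pop.name] * count)
                meta_rows.extend([(sample_id, batch, group, pop.name)] * count)

    display = np.clip(np.vstack(blocks), ymin, ymax)
    raw = np.asarray(scale.inverse(display))
    meta = pd.DataFrame(meta_rows,
                        columns=["sample_id", "batch_id", "group", "population"])
    events = EventTable(intensities=raw, marker_names=markers,
                        event_meta=meta, scale="raw")
    truth = GroundTruth(
        population=np.array(labels, dtype=object),
        sample_proportions=pd.DataFrame(prop_rows).set_index("sample_id"),
        batch_shifts={b: dict(config.batch_shifts.get(b, {})) for b in batches},
        sample_groups=sample_groups,
        sample_batches=sample_batches,
        display_intensities=display,
        config=config,
    )
    return events, truth


def simulate_proportion_table(config: CohortConfig, seed: int | None = None
                              ) -> pd.DataFrame:
    """Per-sample observed proportions without generating marker data.

    Draws each sample's true proportions from the group-adjusted Dirichlet
    and observed cell counts from a multinomial, exactly as
    :func:`generate_cohort` does, but skips the per-event Gaussians — the
    proportion table is all the group-comparison statistics consume. Used
    for calibration and power simulations.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pop_names = [p.name for p in config.all_populations()]
    rows = []
    for group in sorted(config.samples_per_group):
        for i in range(config.samples_per_group[group]):
            sample_id = f"{group}_s{i + 1:02d}"
            props = draw_sample_proportions(config, group, rng)
            n_events = max(1, int(round(rng.lognormal(
                mean=np.log(config.events_per_sample),
                sigma=config.events_sigma))))
            counts = rng.multinomial(n_events, props)
            for pop, count in zip(pop_names, counts):
                rows.append({"sample_id": sample_id, "group": group,
                             "parent": "all", "cell_type": pop,
                             "count": int(count), "parent_count": int(n_events),
                             "proportion": count / n_events})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# canonical fixtures

#: Evocative 8-marker panel used by the fixtures (names only; no biology).
FIXTURE_MARKERS = ["CD5", "CD4", "CD8", "CD21", "CD14", "MHCII", "CD62L",
                   "Viability"]


def _pop(name: str, highs: dict[str, float], sd: float = 0.02) -> PopulationSpec:
    means = {m: highs.get(m, 0.20) for m in FIXTURE_MARKERS}
    return PopulationSpec(name=name, means=means,
                          sds={m: sd for m in FIXTURE_MARKERS})


@dataclass
class Fixture:
    name: str
    config: CohortConfig
    events: EventTable
    truth: GroundTruth


def _three_population_config(seed: int, batch_shifts=None,
                             samples_per_group=None, group_effects=None,
                             events_per_sample=1000.0,
                             proportions=(0.5, 0.3, 0.2)) -> CohortConfig:
    pops = [
        _pop("CD4_T", {"CD5": 0.75, "CD4": 0.75}),
        _pop("CD8_T", {"CD5": 0.75, "CD8": 0.75}),
        _pop("B", {"CD21": 0.75, "MHCII": 0.75}),
    ]
    return CohortConfig(
        populations=pops,
        baseline_proportions=dict(zip([p.name for p in pops], proportions)),
        samples_per_group=samples_per_group or {"A": 3},
        group_effects=group_effects or {},
        batch_shifts=batch_shifts or {},
        events_per_sample=events_per_sample,
        seed=seed,
    )


def generate_fixture_library(seed: int = 20_240_101) -> dict[str, Fixture]:
    """The canonical named fixtures used across the test suite.

    Every fixture embeds a deterministic seed derived from ``seed``, so
    repeated calls regenerate identical data.
    """
    lib: dict[str, Fixture] = {}

    def add(name: str, config: CohortConfig) -> None:
        events, truth = generate_cohort(config)
        lib[name] = Fixture(name=name, config=config, events=events, truth=truth)

    # 1. three well-separated populations (>= 8 sd apart on defining markers)
    add("three_gaussians", _three_population_config(seed + 1))

    # 2. two batches, every marker shifted +0.10 display units in batch2
    add("two_batch_shift", _three_population_config(
        seed + 2,
        batch_shifts={"batch1": {},
                      "batch2": {m: 0.10 for m in FIXTURE_MARKERS}},
        samples_per_group={"A": 4}, events_per_sample=1500.0))

    # 3. a transient population blended into two adjacent T-cell clusters:
    # the parents nearly touch along the CD4/CD8 axis and the blend is a
    # broad cloud spanning both, so it has no exclusive territory of its
    # own — the geometry behind poorly-mapping populations. B cells stay
    # well separated as the clean reference.
    mid, sep = 0.475, 0.05
    pops = [
        _pop("CD4_T", {"CD5": 0.75, "CD4": mid + sep, "CD8": mid - sep}),
        _pop("CD8_T", {"CD5": 0.75, "CD4": mid - sep, "CD8": mid + sep}),
        _pop("B", {"CD21": 0.75, "MHCII": 0.75}),
        PopulationSpec(
            "blend",
            means={m: (0.75 if m == "CD5" else mid
                       if m in ("CD4", "CD8") else 0.20)
                   for m in FIXTURE_MARKERS},
            sds={m: (0.06 if m in ("CD4", "CD8") else 0.02)
                 for m in FIXTURE_MARKERS}),
    ]
    total = 0.45 + 0.25 + 0.2 + 0.12
    cfg = CohortConfig(
        populations=pops,
        baseline_proportions={"CD4_T": 0.45 / total, "CD8_T": 0.25 / total,
                              "B": 0.2 / total, "blend": 0.12 / total},
        samples_per_group={"A": 3},
        events_per_sample=1200.0,
        seed=seed + 3,
    )
    add("overlap_blend", cfg)

    # 4. nested subsets: CD62L-high/low split inside the CD4 T population
    pops = [
        _pop("CD4_T_CD62Lhi", {"CD5": 0.75, "CD4": 0.75, "CD62L": 0.78}),
        _pop("CD4_T_CD62Llo", {"CD5": 0.75, "CD4": 0.75, "CD62L": 0.30}),
        _pop("CD8_T", {"CD5": 0.75, "CD8": 0.75}),
        _pop("B", {"CD21": 0.75, "MHCII": 0.75}),
    ]
    cfg = CohortConfig(
        populations=pops,
        baseline_proportions={"CD4_T_CD62Lhi": 0.25, "CD4_T_CD62Llo": 0.25,
                              "CD8_T": 0.3, "B": 0.2},
        samples_per_group={"A": 3},
        events_per_sample=1200.0,
        seed=seed + 4,
    )
    add("nested_subsets", cfg)

    # 5. group-B proportion shift (1.5x on the CD8 T population), n=20/20
    add("proportion_shift", _three_population_config(
        seed + 5,
        samples_per_group={"A": 20, "B": 20},
        group_effects={"B": {"CD8_T": 1.5}},
        events_per_sample=600.0))

    return lib
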