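"""Run configuration: schema, defaults, and whole-file validation.

The pipeline is driven by a single declarative YAML document. Validation
reports every problem at once rather than stopping at the first, and the
validated config echoes all defaults so a run manifest is self-contained.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ConfigError

#: Full schema with defaults. ``None`` means "no default, optional";
#: the REQUIRED sentinel marks keys the user must supply.
REQUIRED = object()

DEFAULTS: dict[str, Any] = {
    "seed": REQUIRED,
    "output_dir": "flowpheno_run",
    "log_level": "INFO",
    "input": {
        "sample_sheet": None,
        "base_dir": ".",
    },
    "simulate": {
        "enabled": False,
        "samples_per_group": {"A": 3},
        "events_per_sample": 1000.0,
        "group_effects": {},
        "batch_shifts": {},
        "seed": None,           # falls back to the global seed
    },
    "transform": {"T": 4194304.0, "W": 0.5, "M": 4.5, "A": 0.0},
    "gates": [],
    "align": {
        "enabled": True,
        "reference_batch": None,
        "fmo_landmarks": {},
        "manual_shifts": {},    # {batch: {marker: shift}} overrides
    },
    "downsample": {"cap": 200000, "seed": None},
    "harmony": {"enabled": True, "nclust": None, "max_iter": 10, "seed": None},
    "pca": {"enabled": False, "dims": 10},
    "cluster": {"k": 20, "metric": "euclidean", "weighting": "jaccard",
                "resolution": 1.0, "seed": None},
    "subcluster": [],           # list of {target, resolution}
    "annotate": {"rules": [], "fallback": "Unassigned", "consolidate": True},
    "integrate": {"enabled": True, "k": 20, "confidence_threshold": 80.0,
                  "denominator": "annotated"},
    "analysis": {"group_pair": None, "tests": ["wrs", "ks"],
                 "min_samples": 2, "parent_spec": {}},
    "umap": {"enabled": False, "seed": None, "n_neighbors": 15},
}

_TYPES: dict[str, type | tuple[type, ...]] = {
    "seed": int,
    "output_dir": str,
    "log_level": str,
    "transform.T": (int, float),
    "transform.W": (int, float),
    "transform.M": (int, float),
    "transform.A": (int, float),
    "align.enabled": bool,
    "downsample.cap": int,
    "harmony.enabled": bool,
    "harmony.max_iter": int,
    "pca.enabled": bool,
    "pca.dims": int,
    "cluster.k": int,
    "cluster.resolution": (int, float),
    "integrate.enabled": bool,
    "integrate.k": int,
    "integrate.confidence_threshold": (int, float),
    "analysis.min_samples": int,
    "umap.enabled": bool,
    "simulate.enabled": bool,
    "simulate.events_per_sample": (int, float),
}


@dataclass
class RunConfig:
    """Validated configuration with every default filled in."""

    data: dict[str, Any]
    path: str | None = None

    def __getitem__(self, key: str) -> Any:
        node: Any = self.data
        for part in key.split("."):
            node = node[part]
        return node

    def get(self, key: str, default: Any = None) -> Any:
        try:
            return self[key]
        except (KeyError, TypeError):
            return default

    def seed_for(self, section: str) -> int:
        """Per-stage seed: the section's own seed or the global one."""
        own = self.get(f"{section}.seed")
        return int(self.data["seed"] if own is None else own)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.data, sort_keys=True)


def _merge(defaults: Any, user: Any, prefix: str, errors: list[str],
           strict: bool) -> Any:
    if isinstance(defaults, dict) and not prefix.startswith(
            ("simulate.samples_per_group", "simulate.group_effects",
             "simulate.batch_shifts", "align.fmo_landmarks",
             "align.manual_shifts", "analysis.parent_spec")):
        if user is None:
            user = {}
        if not isinstance(user, dict):
            errors.append(f"{prefix or '<root>'}: expected a mapping, "
                          f"got {type(user).__name__}")
            return copy.deepcopy(defaults)
        out = {}
        for key, dval in defaults.items():
            path = f"{prefix}.{key}" if prefix else key
            if key in user:
                out[key] = _merge(dval, user[key], path, errors, strict)
            elif dval is REQUIRED:
                errors.append(f"{path}: required key missing")
            else:
                out[key] = copy.deepcopy(dval)
        for key in user:
            if key not in defaults:
                msg = f"{prefix + '.' if prefix else ''}{key}: unknown key"
                if strict:
                    errors.append(msg)
        return out
    # leaf (or free-form mapping)
    if defaults is REQUIRED:
        value = user
    else:
        value = copy.deepcopy(defaults) if user is None else user
    expected = _TYPES.get(prefix)
    if expected is not None and value is not None:
        if isinstance(value, bool) and expected is not bool and not (
                isinstance(expected, tuple) and bool in expected):
            errors.append(f"{prefix}: expected {expected}, got bool")
        elif not isinstance(value, expected):
            errors.append(
                f"{prefix}: expected "
                f"{getattr(expected, '__name__', expected)}, "
                f"got {type(value).__name__} ({value!r})")
    return value


def validate_config_dict(user: dict[str, Any], strict: bool = True,
                         path: str | None = None) -> RunConfig:
    """Validate a config mapping; every error is reported at once."""
    errors: list[str] = []
    merged = _merge(DEFAULTS, user or {}, "", errors, strict)

    if not errors:
        if merged["downsample"]["cap"] <= 0:
            errors.append("downsample.cap: must be positive")
        if merged["cluster"]["k"] < 1:
            errors.append("cluster.k: must be >= 1")
        if not (0 < merged["integrate"]["confidence_threshold"] <= 100):
            errors.append("integrate.confidence_threshold: must be in (0, 100]")
        for i, step in enumerate(merged["subcluster"]):
            if not isinstance(step, dict) or "target" not in step:
                errors.append(f"subcluster[{i}]: needs a 'target' key")
            elif not isinstance(step.get("resolution", 1.0), (int, float)):
                errors.append(f"subcluster[{i}].resolution: must be numeric")
        if not merged["simulate"]["enabled"] and \
                not merged["input"]["sample_sheet"]:
            errors.append("input.sample_sheet: required unless simulate.enabled")
        gp = merged["analysis"]["group_pair"]
        if gp is not None and (not isinstance(gp, (list, tuple)) or len(gp) != 2):
            errors.append("analysis.group_pair: must be a pair of group labels")
    if errors:
        raise ConfigError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return RunConfig(data=merged, path=path)


def validate_config(path: str | Path, strict: bool = True) -> RunConfig:
    """Load and validate a YAML config file."""
    path = Path(path)
    try:
        with open(path) as fh:
            user = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file not parseable: {exc}") from exc
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ConfigError("config file must hold a mapping at top level")
    return validate_config_dict(user, strict=strict, path=str(path))


def apply_overrides(config: RunConfig, overrides: list[str]) -> RunConfig:
    """Apply dot-path ``key=value`` overrides (CLI flags) to a config."""
    data = copy.deepcopy(config.data)
    for item in overrides:
        if "=" not in item:
            raise ConfigError(f"override {item!r} must look like key=value")
        key, raw = item.split("=", 1)
        value = yaml.safe_load(raw)
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = value
    return validate_config_dict(data, strict=True, path=config.path)
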