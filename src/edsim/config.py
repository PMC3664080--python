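"""Scenario configuration: YAML/JSON loading, validation, named overrides.

An empty (or missing-key) config file materializes the full default ED base
case — the inputs tables' capacities, mean service times and probabilities.
Overrides are given as nested mappings or dotted paths and may only touch
keys that exist in the base configuration; probabilities are bounds-checked.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__ as _version
from .distributions import DistributionSpec
from .ed import EDConfig
from .validation import ValidationConfig

__all__ = [
    "RunManifest",
    "ScenarioConfig",
    "builtin_scenarios",
    "load_config",
    "load_scenario_file",
]

_SCENARIO_DIR = Path(__file__).parent / "scenarios"


@dataclass
class ScenarioConfig:
    """A labeled ED experiment: the base case plus named parameter patches."""

    label: str
    overrides: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def build(self, **extra: Any) -> EDConfig:
        base = _ed_defaults_dict()
        merged = _apply_overrides(base, self.overrides)
        merged.update(extra)
        return _ed_from_dict(merged, seed=self.seed)


@dataclass(frozen=True)
class RunManifest:
    """Traceability record written next to every result set."""

    label: str
    config_hash: str
    seed: int
    version: str
    started: str
    finished: str

    @staticmethod
    def create(label: str, cfg: EDConfig | ValidationConfig, started: float, finished: float) -> "RunManifest":
        return RunManifest(
            label=label,
            config_hash=config_hash(cfg),
            seed=cfg.seed,
            version=_version,
            started=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime(started)),
            finished=time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime(finished)),
        )

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def config_hash(cfg: EDConfig | ValidationConfig) -> str:
    """Stable content hash of a configuration (seed excluded)."""
    d = _to_jsonable(dataclasses.asdict(cfg))
    d.pop("seed", None)
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, DistributionSpec):
        return obj.to_config()
    if isinstance(obj, float) and obj == float("inf"):
        return "inf"
    return obj


# ---------------------------------------------------------------------------
# defaults <-> dict round trip
# ---------------------------------------------------------------------------

def _ed_defaults_dict() -> dict[str, Any]:
    cfg = EDConfig()
    d = {f.name: getattr(cfg, f.name) for f in dataclasses.fields(EDConfig)}
    d["services"] = {k: v for k, v in d["services"].items()}
    return d

_PROB_KEYS = {"admit_prob", "walk_in_fraction"}


def _apply_overrides(base: dict[str, Any], overrides: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    flat: dict[str, Any] = {}

    def flatten(prefix: str, m: Mapping[str, Any]) -> None:
        for k, v in m.items():
            key = f"{prefix}.{k}" if prefix else str(k)
            if isinstance(v, Mapping) and not _is_dist_mapping(v):
                flatten(key, v)
            else:
                flat[key] = v

    flatten("", overrides)
    for key, value in flat.items():
        parts = key.split(".")
        if parts[0] not in out:
            raise KeyError(f"unknown configuration key {parts[0]!r}")
        if len(parts) == 1:
            if parts[0] in _PROB_KEYS and not 0.0 <= float(value) <= 1.0:
                raise ValueError(f"{parts[0]} must be a probability in [0, 1], got {value}")
            out[parts[0]] = value
        elif parts[0] == "services":
            services = dict(out["services"])
            if parts[1] not in services:
                raise KeyError(f"unknown service {parts[1]!r}")
            services[parts[1]] = DistributionSpec.from_config(value)
            out["services"] = services
        elif parts[0] in ("radiology_probs", "blood_probs"):
            probs = dict(out[parts[0]])
            level = int(parts[1])
            if level not in probs:
                raise KeyError(f"unknown CTAS level {level} in {parts[0]}")
            if not 0.0 <= float(value) <= 1.0:
                raise ValueError(f"{key} must be a probability in [0, 1], got {value}")
            probs[level] = float(value)
            out[parts[0]] = probs
        else:
            raise KeyError(f"unknown configuration key {key!r}")
    return out


def _is_dist_mapping(v: Mapping[str, Any]) -> bool:
    return "family" in v


def _ed_from_dict(d: Mapping[str, Any], seed: int | None = None) -> EDConfig:
    d = dict(d)
    d["services"] = {k: DistributionSpec.from_config(v) for k, v in d["services"].items()}
    for key in ("hourly_weights", "day_weights", "ctas_probs"):
        d[key] = tuple(d[key])
    for key in ("triage_nurses", "registrars"):
        if not isinstance(d[key], int):
            d[key] = tuple(d[key])
    d["radiology_probs"] = {int(k): float(v) for k, v in d["radiology_probs"].items()}
    d["blood_probs"] = {int(k): float(v) for k, v in d["blood_probs"].items()}
    d["lwbs_bands"] = tuple(
        (float("inf") if b in ("inf", ".inf") else float(b), float(p)) for b, p in d["lwbs_bands"]
    )
    if seed is not None:
        d["seed"] = seed
    return EDConfig(**d)


def load_config(path: str | Path, seed: int | None = None) -> ScenarioConfig:
    """Load a scenario file; an empty file yields the full default base case."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    label = raw.pop("label", path.stem)
    file_seed = raw.pop("seed", 0)
    overrides = raw.pop("overrides", raw)  # flat files are treated as overrides
    sc = ScenarioConfig(label=str(label), overrides=overrides, seed=file_seed if seed is None else seed)
    sc.build()  # validate eagerly so errors point at the file
    return sc


def load_scenario_file(name: str, seed: int | None = None) -> ScenarioConfig:
    """Load one of the shipped sensitivity scenarios by name."""
    path = _SCENARIO_DIR / f"{name}.yaml"
    if not path.exists():
        raise FileNotFoundError(
            f"no shipped scenario {name!r}; available: {sorted(builtin_scenarios())}"
        )
    return load_config(path, seed=seed)


def builtin_scenarios() -> list[str]:
    return sorted(p.stem for p in _SCENARIO_DIR.glob("*.yaml"))
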