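"""Pipeline configuration: one flat YAML file governs every stage.

Unknown keys are rejected at load time, and the effective configuration
is serialized into each output directory for provenance. The same config
drives simulation (system, construct, copying model, seed), read
processing (filters) and the statistic windows, so a reaction condition
is exactly one config file.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .chemistry import ChemistrySystem, get_system
from .construct import ConstructSpec, CopyingModel

__all__ = ["PipelineConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content; names the offending key."""


_TOP_KEYS = {"system", "construct", "model", "filters", "stats", "n_reads", "seed"}
_CONSTRUCT_KEYS = {"handle5", "template_len", "loop"}
_MODEL_KEYS = {
    "template_dist", "propensity", "p_ext_initial", "p_ext_after_match",
    "p_ext_after_mismatch", "post_mismatch_error_boost", "seq_error_rate",
    "rt_error_rate",
}
_FILTER_KEYS = {"max_anchor_mismatches", "min_quality"}
_STATS_KEYS = {"m_positions", "stalling_position"}


@dataclass
class PipelineConfig:
    system: ChemistrySystem
    construct: ConstructSpec
    model: CopyingModel
    max_anchor_mismatches: int = 1
    min_quality: int = 20
    m_positions: Tuple[int, ...] = (1, 2, 3, 4)
    stalling_position: int = 1
    n_reads: int = 10000
    seed: int = 0

    def to_dict(self) -> Dict[str, object]:
        return {
            "system": self.system.name,
            "construct": {
                "handle5": self.construct.handle5,
                "template_len": self.construct.template_len,
                "loop": self.construct.loop,
            },
            "model": {
                "template_dist": self.model.template_dist.tolist(),
                "propensity": self.model.propensity.tolist(),
                "p_ext_initial": self.model.p_ext_initial,
                "p_ext_after_match": self.model.p_ext_after_match,
                "p_ext_after_mismatch": self.model.p_ext_after_mismatch,
                "post_mismatch_error_boost": self.model.post_mismatch_error_boost,
                "seq_error_rate": self.model.seq_error_rate,
                "rt_error_rate": self.model.rt_error_rate,
            },
            "filters": {
                "max_anchor_mismatches": self.max_anchor_mismatches,
                "min_quality": self.min_quality,
            },
            "stats": {
                "m_positions": list(self.m_positions),
                "stalling_position": self.stalling_position,
            },
            "n_reads": self.n_reads,
            "seed": self.seed,
        }

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _check_keys(d: Dict, allowed: set, context: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {context}: {', '.join(sorted(unknown))}")


def config_from_dict(raw: Dict[str, object]) -> PipelineConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, _TOP_KEYS, "config")
    try:
        system = get_system(str(raw.get("system", "DUCG")))
    except ValueError as exc:
        raise ConfigError(f"system: {exc}") from exc

    c = dict(raw.get("construct") or {})
    _check_keys(c, _CONSTRUCT_KEYS, "construct")
    try:
        construct = ConstructSpec(**c)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"construct: {exc}") from exc

    m = dict(raw.get("model") or {})
    _check_keys(m, _MODEL_KEYS, "model")
    if "template_dist" in m:
        m["template_dist"] = np.asarray(m["template_dist"], dtype=float)
    if "propensity" in m:
        m["propensity"] = np.asarray(m["propensity"], dtype=float)
    try:
        model = CopyingModel(system=system, seed=int(raw.get("seed", 0)), **m)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"model: {exc}") from exc

    f = dict(raw.get("filters") or {})
    _check_keys(f, _FILTER_KEYS, "filters")
    s = dict(raw.get("stats") or {})
    _check_keys(s, _STATS_KEYS, "stats")

    try:
        return PipelineConfig(
            system=system,
            construct=construct,
            model=model,
            max_anchor_mismatches=int(f.get("max_anchor_mismatches", 1)),
            min_quality=int(f.get("min_quality", 20)),
            m_positions=tuple(int(p) for p in s.get("m_positions", (1, 2, 3, 4))),
            stalling_position=int(s.get("stalling_position", 1)),
            n_reads=int(raw.get("n_reads", 10000)),
            seed=int(raw.get("seed", 0)),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path, overrides: Optional[Dict[str, object]] = None) -> PipelineConfig:
    """Load and validate a YAML pipeline config; CLI overrides win."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if overrides:
        for k, v in overrides.items():
            if v is not None:
                raw[k] = v
    return config_from_dict(raw)
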