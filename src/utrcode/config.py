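"""YAML configuration: motif sets plus rule-engine parameters.

Schema (version 1)::

    version: 1
    patterns:
      PAS: [AATAAA]
      CPE: [TTTTAT, TTTTAAT, TTTTTAT, TTTTTAAT]
      PBE: [TGTANATA]
    engine:
      w_one: 40
      w_flank: 100
      w_occlude: 12
      one_sided_penalty: 0.5
      dose_step: 0.25
      stim_per_cpe: 0.5
      active_threshold: 0.25
      partial_hi: 0.75

Both sections are optional; omitted values fall back to the defaults.
"""

from __future__ import annotations

import dataclasses
import os

import yaml

from .engine import CodeConfig
from .motifs import MotifPattern, default_patterns

__all__ = ["load_config", "dump_config", "CONFIG_VERSION"]

CONFIG_VERSION = 1


def load_config(
    path: str | os.PathLike | None,
) -> tuple[list[MotifPattern], CodeConfig]:
    """Load (patterns, engine config) from YAML; None -> defaults."""
    if path is None:
        return default_patterns(), CodeConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    version = data.get("version", CONFIG_VERSION)
    if version != CONFIG_VERSION:
        raise ValueError(f"unsupported config version {version}")
    if "patterns" in data:
        patterns = [
            MotifPattern(f"{cls}-{pat}", cls, str(pat))
            for cls, pats in data["patterns"].items()
            for pat in pats
        ]
        if not patterns:
            raise ValueError("patterns section is empty")
    else:
        patterns = default_patterns()
    engine_kwargs = data.get("engine", {})
    allowed = {f.name for f in dataclasses.fields(CodeConfig)}
    bad = set(engine_kwargs) - allowed
    if bad:
        raise ValueError(f"unknown engine parameters: {sorted(bad)}")
    return patterns, CodeConfig(**engine_kwargs)


def dump_config(
    patterns: list[MotifPattern],
    cfg: CodeConfig,
    path: str | os.PathLike,
) -> None:
    """Write the active configuration back out as versioned YAML."""
    by_class: dict[str, list[str]] = {}
    for pat in patterns:
        by_class.setdefault(pat.element_class, []).append(pat.pattern)
    data = {
        "version": CONFIG_VERSION,
        "patterns": by_class,
        "engine": dataclasses.asdict(cfg),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
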