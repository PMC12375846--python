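"""Run orchestration and I/O: configuration loading/validation, the
simulate-screen-economics-summarize-frontier pipeline, result
serialization and the run manifest (seed, config hash, version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .outcomes import frontier_from_outcomes, outcome_table
from .sensitivity import apply_overrides, base_config, run_config

log = logging.getLogger("prostasim")


class ValidationError(ValueError):
    pass


@dataclass
class RunConfig:
    """Declarative run configuration for the comparison pipeline."""

    strategies: list = field(default_factory=list)  # preset names; empty = all
    n_persons: int = 50_000
    master_seed: int = 1
    discount_rate: float = 0.03
    out_dir: str = "results"
    scenario: Optional[str] = None
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_persons < 1:
            raise ValidationError("n_persons must be >= 1")
        if self.discount_rate < 0:
            raise ValidationError("discount_rate must be >= 0")

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise ValidationError(f"invalid run config: {exc}") from exc

    def to_nested(self) -> dict:
        cfg = base_config(
            strategies=self.strategies or None,
            n_persons=self.n_persons,
            seed=self.master_seed,
        )
        cfg["econ"]["discount_rate"] = self.discount_rate
        if self.scenario:
            from .sensitivity import preset_scenarios

            match = [s for s in preset_scenarios(cfg) if s.name == self.scenario]
            if not match:
                raise ValidationError(f"unknown scenario '{self.scenario}'")
            cfg = apply_overrides(cfg, match[0].overrides)
        if self.overrides:
            cfg = apply_overrides(cfg, self.overrides)
        return cfg


def config_hash(cfg: dict) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_compare(config: RunConfig) -> dict:
    """Execute the full comparison and write the result bundle.

    Writes ``outcomes.csv`` (per-100,000 outcome table), ``frontier.json``
    (efficient set with ICERs and dominance labels) and ``manifest.json``
    (master seed, config hash, package version) under ``config.out_dir``.
    """
    cfg = config.to_nested()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log.info("simulating %d persons, %d strategies (seed %d)",
             cfg["n_persons"], len(cfg["strategies"]), cfg["seed"])
    outcomes, _ = run_config(cfg)
    table = outcome_table(outcomes)
    log.info("summarized outcomes; computing efficiency frontier")
    frontier = frontier_from_outcomes(outcomes)

    manifest = {
        "master_seed": config.master_seed,
        "config_hash": config_hash(cfg),
        "version": __version__,
        "n_persons": cfg["n_persons"],
        "strategies": sorted(cfg["strategies"]),
        "scenario": config.scenario,
    }
    table.assign(master_seed=config.master_seed).to_csv(out_dir / "outcomes.csv")
    with open(out_dir / "frontier.json", "w") as fh:
        json.dump({**frontier.to_dict(), "master_seed": config.master_seed}, fh, indent=2)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    log.info("wrote %s", out_dir)
    return {"outcomes": table, "frontier": frontier, "manifest": manifest}
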