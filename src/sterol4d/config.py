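"""Run configuration: matching parameters, file paths, seeds, and the
machine-readable run manifest.

Defaults reproduce the published identification settings: MS1 gate 25 ppm;
RT trapezoid 0/12 s (standard) and 0/30 s (extended); CCS trapezoid
1/1.5 % and 1/3 %; MS/MS cutoffs 0.6 and 0.5; weights 0.2/0.4/0.4; keep
threshold 0.6 (strict).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .matching import (DEFAULT_WEIGHTS, EXTENDED_TOLERANCES, STANDARD_TOLERANCES,
                       MatchTolerances, MatchWeights)

__all__ = ["RunConfig", "load_config", "write_manifest"]


@dataclass
class RunConfig:
    tolerances_standard: MatchTolerances = field(default_factory=lambda: STANDARD_TOLERANCES)
    tolerances_extended: MatchTolerances = field(default_factory=lambda: EXTENDED_TOLERANCES)
    weights: MatchWeights = field(default_factory=lambda: DEFAULT_WEIGHTS)
    seed: int = 0
    output_dir: str = "."
    verbosity: int = 1

    def to_dict(self) -> dict:
        return {
            "tolerances_standard": dataclasses.asdict(self.tolerances_standard),
            "tolerances_extended": dataclasses.asdict(self.tolerances_extended),
            "weights": dataclasses.asdict(self.weights),
            "seed": self.seed,
            "output_dir": self.output_dir,
            "verbosity": self.verbosity,
        }


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML config; missing keys keep the published defaults."""
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "tolerances_standard" in raw:
        cfg.tolerances_standard = MatchTolerances(**{
            **dataclasses.asdict(STANDARD_TOLERANCES), **raw["tolerances_standard"]})
    if "tolerances_extended" in raw:
        cfg.tolerances_extended = MatchTolerances(**{
            **dataclasses.asdict(EXTENDED_TOLERANCES), **raw["tolerances_extended"]})
    if "weights" in raw:
        cfg.weights = MatchWeights(**{**dataclasses.asdict(DEFAULT_WEIGHTS), **raw["weights"]})
    for key in ("seed", "output_dir", "verbosity"):
        if key in raw:
            setattr(cfg, key, raw[key])
    return cfg


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir: str | Path, command: str, config: RunConfig,
                   inputs: dict[str, str | Path | None]) -> Path:
    """Write a JSON run manifest (parameters, seed, input digests) enabling
    exact re-runs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config.to_dict(),
        "inputs": {k: {"path": str(v), "sha256": _digest(Path(v))}
                   for k, v in inputs.items() if v is not None},
    }
    path = out_dir / "run_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
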