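"""Run configuration: defaults, YAML/JSON loading, flag precedence.

Defaults mirror the study conditions: a DPPC/DPPG/cholesterol 75:10:15
membrane at 293 K, 50 layers, 5 snapshots.  Command-line flags override
file values, which override the built-in defaults; the resolved config
is hashed so every output file can carry its provenance.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import yaml

from .profiles import ProfileShapeParams

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    temperature: float = 293.0
    membrane: str = "DPPC/DPPG/Chol 75:10:15"
    n_snapshots: int = 5
    layers: int = 50
    seed: int = 0
    boundaries: str | None = None      # path to a boundaries YAML/JSON
    shape: ProfileShapeParams = field(default_factory=ProfileShapeParams)

    def __post_init__(self) -> None:
        if self.n_snapshots < 1 or self.layers < 3:
            raise ValueError("n_snapshots must be >= 1 and layers >= 3")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        # keep the profile block consistent with the top-level settings
        object.__setattr__(self, "shape", replace(
            self.shape,
            layers=self.layers,
            seed=self.seed,
            temperature=self.temperature,
            composition=self.membrane,
        ))

    @property
    def config_hash(self) -> str:
        payload = asdict(self)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    def provenance(self) -> dict:
        return {"config_hash": self.config_hash, "seed": self.seed,
                "temperature_K": self.temperature, "membrane": self.membrane}


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus overrides.

    Precedence: explicit keyword overrides (CLI flags) > file values >
    defaults.  ``None`` overrides are ignored so optional flags pass
    through cleanly.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    shape_block = data.pop("shape", {})
    if isinstance(shape_block, dict):
        known = {f.name for f in fields(ProfileShapeParams)}
        unknown = set(shape_block) - known
        if unknown:
            raise ValueError(f"unknown profile-shape keys: {sorted(unknown)}")
        shape = ProfileShapeParams(**shape_block)
    else:
        shape = shape_block
    known = {f.name for f in fields(RunConfig)} - {"shape"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(shape=shape, **data)
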