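"""Pipeline configuration: a single dataclass that round-trips through YAML/JSON.

One master seed governs every random stage; per-stage seeds are spawned
from it deterministically, so a config + seed pair pins the whole artifact
set byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .sessions import Behavior


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full generate → fit → analyze → features run needs."""

    # network: either a Pajek file or a seeded constrained generator
    network_file: str | None = None
    apply_modification: bool = False
    n_nodes: int = 31
    network_seed: int = 1

    # session generation
    n_sessions: int = 21
    n_minority: int = 4
    max_rounds: int = 15
    behavior: Behavior = field(default_factory=Behavior)
    stubborn_prob: float = 0.25   # chance a session carries one stubborn agent

    # fitting / analysis
    fit_grid: dict | None = None  # FitGrid overrides: c_values/T_values/delta_values
    normalized_threshold: bool = True
    pad_curves: bool = True
    z_cut: float = 2.0
    tukey_k: float = 1.5
    mr_k: float = 3.0

    # feature importance
    importance_trees: int = 200
    run_nested_cv: bool = True

    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be ≥ 1")
        if not 0 <= self.stubborn_prob <= 1:
            raise ValueError("stubborn_prob must be a probability")
        if isinstance(self.behavior, dict):
            object.__setattr__(self, "behavior", Behavior(**self.behavior))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict(), sort_keys=False)
        )
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = (
            json.loads(path.read_text())
            if path.suffix == ".json"
            else yaml.safe_load(path.read_text())
        )
        return cls(**raw)
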