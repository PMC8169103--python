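"""Run configuration: one flat record of every tunable the pipeline uses.

Serialized verbatim into each output directory so a run can be reproduced
bit-for-bit from its artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    tr: float = 1.5
    n_events: int = 7
    n_features: int = 10
    radius: int = 5
    stride: int = 5
    min_voxels: int = 20
    min_subjects: int = 15
    n_null: int = 99
    q_threshold: float = 0.05
    k_min: int = 2
    k_max: int = 10
    max_lag_trs: int = 10
    n_boot: int = 100
    mode: str = "first_vs_rest"
    srm_iter: int = 30
    hmm_max_iter: int = 100
    hmm_tol: float = 1e-4
    seed: int = 0
    data_dir: str | None = None
    mask_path: str | None = None
    annotations_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        for name in ("tr", "n_events", "n_features", "stride", "min_voxels",
                     "min_subjects", "n_null", "max_lag_trs", "n_boot"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.q_threshold < 1):
            raise ValueError("q_threshold must lie in (0, 1)")

    @property
    def k_range(self) -> range:
        return range(self.k_min, self.k_max + 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
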