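"""Run configuration: one serializable object drives every CLI stage.

A persisted config re-runs bit-identically in single-threaded mode; every
stage writes the resolved config next to its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    # cohort
    n_patients: int = 24
    hours_per_patient: float = 0.5
    sampling_rate: float = 256.0
    seizure_rate: float = 10.0
    artifact_rate: float = 0.0
    zone_distribution: dict | None = None
    hemisphere_distribution: dict | None = None
    # preprocessing
    band: tuple[float, float] = (1.0, 40.0)
    notch: float = 50.0
    amplitude_max_uv: float = 500.0
    flatline_std_uv: float = 0.1
    dominance_fraction: float = 0.5
    # features
    feature_mode: str = "reduced"
    # splits
    n_splits: int = 3
    train_fraction: float = 0.75
    # classifier
    hyper_params: dict | None = None
    search_budget: int = 30
    # search stages
    channels: list[str] = field(default_factory=list)  # empty = full montage
    sweep_sizes: list[int] = field(default_factory=list)  # empty = 1..n-1
    k: int = 4
    max_samples: int = 1000
    top_n: int = 10
    # bookkeeping
    seed: int = 0
    out_dir: str = "runs/default"

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        if isinstance(cfg.band, list):
            cfg.band = tuple(cfg.band)
        return cfg
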