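"""Flat, schema-validated run configuration.

A :class:`RunConfig` collects every knob of the end-to-end pipeline in
one flat document (YAML on disk). Unknown keys are rejected so typos
fail loudly; every run writes its resolved configuration beside its
outputs. Defaults mirror the study settings: 7×7 hexagonal grid,
rlen 100, 20,000 training epochs, 1,000 bootstrap replicates, RF with
100 trees and 4 candidate variables per split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, fields

import yaml


@dataclass
class RunConfig:
    profile: str = "galea26"
    grid_nx: int = 7
    grid_ny: int = 7
    topology: str = "hexagonal"
    rlen: int = 100
    alpha_start: float = 0.05
    alpha_end: float = 0.01
    neighbourhood: str = "bubble"
    train_n: int = 20000
    n_boot: int = 1000
    n_trees: int = 100
    mtry: int = 4
    sweep_sizes: list[int] = field(default_factory=lambda: [100, 200, 500, 1000, 2000, 5000])
    sweep_reps: int = 10
    grid_range_low: int = 4
    grid_range_high: int = 9
    simulate_train_s: float = 6000.0
    simulate_test_s: float = 3000.0
    rate_hz: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_nx < 1 or self.grid_ny < 1:
            raise ValueError("grid dims must be positive")
        if self.topology not in ("hexagonal", "rectangular"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.neighbourhood not in ("bubble", "gaussian"):
            raise ValueError(f"unknown neighbourhood {self.neighbourhood!r}")
        if self.rlen < 1 or self.train_n < 1 or self.n_boot < 1:
            raise ValueError("rlen, train_n and n_boot must be positive")
        if self.grid_range_high < self.grid_range_low:
            raise ValueError("empty grid range")

    @classmethod
    def from_dict(cls, doc: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ValueError("config must be a mapping")
        return cls.from_dict(doc)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
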