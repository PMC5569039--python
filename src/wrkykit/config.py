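"""Run configuration: every tunable with its default, JSON round-trippable."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    # promoter / motif scanning
    window: int = 1000
    min_sites: int = 3
    # differential expression
    up_threshold: float = 1.5
    down_threshold: float = 0.66
    alpha: float = 0.05
    fpkm_validity: float = 10.0
    deviation_prob: float = 0.8
    n_boot: int = 1000
    dunnett_draws: int = 200_000
    # phylogenetics / alignment
    bootstrap_replicates: int = 1000
    gap_open: float = 10.0
    gap_extend: float = 1.0
    identity_floor: float = 0.35
    # domain detection
    max_mismatches: int = 3
    spacer1_min: int = 3
    spacer1_max: int = 7
    spacer2_min: int = 5
    spacer2_max: int = 27
    linker_max: int = 120
    # randomness
    seed: int = 0

    @property
    def spacer1_range(self) -> tuple[int, int]:
        return (self.spacer1_min, self.spacer1_max)

    @property
    def spacer2_range(self) -> tuple[int, int]:
        return (self.spacer2_min, self.spacer2_max)

    def to_json(self, path: str | Path) -> None:
        from .io import atomic_open

        with atomic_open(path) as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)
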