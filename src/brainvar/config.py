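"""Pipeline-wide configuration."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs shared across the pipeline stages.

    ``alpha`` is the two-sided significance level; ``n_permutations`` the
    permutation-test replicate count; ``log2_offset`` is added to RPKM
    before the log2 transform (0 drops zero values instead);
    ``min_region_points`` is the per-region coverage floor of the
    trajectory stage.  All randomness flows from ``seed``: each stage
    draws a deterministic sub-seed via :meth:`subseed`.
    """

    alpha: float = 0.05
    n_permutations: int = 999
    seed: int = 0
    log2_offset: float = 0.0
    min_region_points: int = 5
    output_dir: Path = field(default_factory=lambda: Path("."))

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.log2_offset < 0:
            raise ValueError("log2_offset must be nonnegative")
        if self.min_region_points < 1:
            raise ValueError("min_region_points must be >= 1")
        object.__setattr__(self, "output_dir", Path(self.output_dir))

    def subseed(self, stage: str) -> int:
        """Deterministic per-stage sub-seed derived from the master seed."""
        ss = np.random.SeedSequence(
            self.seed, spawn_key=tuple(stage.encode("utf-8"))
        )
        return int(ss.generate_state(1, dtype=np.uint32)[0])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})
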