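"""Run configuration for the herd analysis pipeline.

All analysis constants live here: the 21-day cycle length, the
3-mature-cow season-start rule, the empirical BPI quartile descriptors
(0.4 / 1.4), the 60% first-cycle benchmark, the suggested 75% vigor-score
cutoff, and the published per-10%-vigor-score benchmark slopes that
estimated effects are compared against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

#: Published per-10%-vigor-score benchmark effects the test is marketed on:
#: +1.33 kg weaning weight, -2 d age at first calving, +2 percentage points
#: conception rate, +35.7 kg cow lifetime productivity.
DEFAULT_BENCHMARK_SLOPES: dict[str, float] = {
    "avg_ww_kg": 1.33,
    "afc_days": -2.0,
    "conception_rate": 0.02,
    "lifetime_kg": 35.7,
}


@dataclass
class RunConfig:
    """Pipeline constants. Fractions are on the 0-1 scale throughout."""

    cycle_length_days: int = 21
    mature_age_years: int = 3
    first_cycle_start_rank: int = 3
    bpi_bottom_cutoff: float = 0.4
    bpi_top_cutoff: float = 1.4
    first_cycle_benchmark: float = 0.60
    vs_cutoff: float = 0.75
    include_indeterminate: bool = True
    use_rounded_grandcalf_average: bool = True
    herd_wide_season_start: bool = False
    max_mismatches: int = 1
    base_panel_size: int = 100
    extension_size: int = 20
    benchmark_slopes: dict = field(
        default_factory=lambda: dict(DEFAULT_BENCHMARK_SLOPES)
    )
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.cycle_length_days <= 0:
            raise ValueError("cycle_length_days must be positive")
        for name in ("bpi_bottom_cutoff", "bpi_top_cutoff", "first_cycle_benchmark",
                     "vs_cutoff"):
            v = getattr(self, name)
            if name in ("first_cycle_benchmark", "vs_cutoff") and not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.bpi_top_cutoff < self.bpi_bottom_cutoff:
            raise ValueError(
                "bpi_top_cutoff must be >= bpi_bottom_cutoff "
                f"({self.bpi_top_cutoff} < {self.bpi_bottom_cutoff})"
            )
        if self.first_cycle_start_rank < 1:
            raise ValueError("first_cycle_start_rank must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
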