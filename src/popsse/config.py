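"""Run configuration: scenario filters, replication, seeds, output layout.

A run is fully described by a flat YAML document; every command writes its
resolved configuration next to its outputs so any artifact can be
regenerated from ``(config, seed)`` alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .cohort import (CANONICAL_CL, CANONICAL_DURATIONS, CANONICAL_N,
                     DATASET_TYPES, ScenarioSpec, VarianceSpec, scenario_grid)

__all__ = ["RunConfig"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Scenario filters plus estimation and replication settings.

    Defaults reproduce the full study grid at 200 replicates per scenario;
    desk-scale runs narrow the filters and replicate count.
    """

    dataset_types: list[str] = field(default_factory=lambda: list(DATASET_TYPES))
    clearances: list[float] = field(default_factory=lambda: list(CANONICAL_CL))
    infusion_durations: list[float] = field(default_factory=lambda: list(CANONICAL_DURATIONS))
    n_subjects: list[int] = field(default_factory=lambda: list(CANONICAL_N))
    replicates: int = 200
    base_seed: int = 0
    method: str = "foce-i"
    omega_sd: list[float] = field(default_factory=lambda: [0.30] * 4)
    sigma_prop: float = 0.10
    # policy for the first-dose 0 h sample (structurally zero prediction):
    # True excludes it from fitting via MDV=1
    baseline_mdv: bool = True
    output_dir: str = "popsse_output"

    def __post_init__(self) -> None:
        if not (self.dataset_types and self.clearances
                and self.infusion_durations and self.n_subjects):
            raise ValueError("every scenario filter must select at least one value")
        unknown = set(self.dataset_types) - set(DATASET_TYPES)
        if unknown:
            raise ValueError(f"unknown dataset types {sorted(unknown)}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    def scenarios(self) -> list[ScenarioSpec]:
        grid = scenario_grid(self.dataset_types, self.clearances,
                             self.infusion_durations, self.n_subjects)
        for s in grid:
            if not s.is_canonical:
                logger.warning("scenario %s lies outside the canonical study grid",
                               s.label())
        return grid

    @property
    def variance(self) -> VarianceSpec:
        return VarianceSpec(omega_sd=tuple(self.omega_sd),
                            sigma_prop=self.sigma_prop)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys {sorted(unknown)}")
        return cls(**data)
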