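"""Shared fixtures, including the two session-scoped SSE runs that the
performance-bound tests share (a favorable large-sample scenario and the
reduced 12-cell study sub-grid)."""

from __future__ import annotations

import numpy as np
import pytest

from popsse import (EstimationSettings, PKParameters, ScenarioSpec,
                    VarianceSpec, run_sse, scenario_grid)

#: fixed base seed for every stochastic fixture in the suite
SUITE_SEED = 1234

FAVORABLE = ScenarioSpec("PK3", 4.5, 1.0, 100)
FAVORABLE_REPLICATES = 25
SUBGRID_REPLICATES = 10


@pytest.fixture(scope="session")
def pop_params_low_cl() -> PKParameters:
    """Population typical values with the low clearance (1.5 L/h)."""
    return PKParameters(CL=1.5, V1=24.2, V2=32.3, Q=11.2)


@pytest.fixture(scope="session")
def favorable_run():
    """SSE of the favorable scenario: PK3 sampling, 1 h infusion,
    CL = 4.5 L/h, 100 subjects, 25 simulate-then-fit replicates."""
    return run_sse(FAVORABLE, FAVORABLE_REPLICATES,
                   VarianceSpec(), EstimationSettings(),
                   base_seed=SUITE_SEED)


@pytest.fixture(scope="session")
def subgrid_runs():
    """SSE over the reduced sub-grid: three dataset types, both clearances,
    1 h infusion, n in {25, 200}; 10 replicates per cell."""
    scenarios = scenario_grid(("PK1", "PK2", "PK3"), (1.5, 4.5), (1.0,), (25, 200))
    return {s: run_sse(s, SUBGRID_REPLICATES, VarianceSpec(),
                       EstimationSettings(), base_seed=SUITE_SEED)
            for s in scenarios}
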