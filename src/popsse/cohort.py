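"""Virtual-cohort simulation for the sampling-period study.

Generates population datasets for a vancomycin-like two-compartment model
under the study's scenario grid: three dataset types (PK1 = samples after
the first dose, PK2 = after the fourth dose, PK3 = both), two typical
clearances (1.5 and 4.5 L/h), three infusion durations (1, 2, 4 h) and four
cohort sizes (25, 50, 100, 200), i.e. 72 scenarios.

Between-subject variability is exponential (log-normal) with a 30% CV on
each of the four structural parameters; residual variability is
proportional with a 10% CV.  Datasets are exchanged as NONMEM-dialect CSV
(columns ID, TIME, AMT, RATE, EVID, MDV, DV; "." for empty cells).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .pk_model import PKParameters, Regimen, conc_profile

__all__ = [
    "SAMPLING_OFFSETS",
    "DATASET_TYPES",
    "CANONICAL_CL", "CANONICAL_DURATIONS", "CANONICAL_N",
    "POP_V1", "POP_V2", "POP_Q",
    "DOSE_AMOUNT", "DOSE_INTERVAL", "N_DOSES",
    "VarianceSpec", "ScenarioSpec", "PopDataset", "DatasetParseError",
    "sampling_offsets", "draw_individual", "simulate_dataset",
    "scenario_grid", "write_dataset", "read_dataset",
]

#: Fixed blood-sampling offsets (h from dose start) per infusion duration.
SAMPLING_OFFSETS: dict[float, tuple[float, ...]] = {
    1.0: (0.0, 1.0, 2.0, 4.0, 12.0),
    2.0: (0.0, 2.0, 3.0, 5.0, 12.0),
    4.0: (0.0, 4.0, 5.0, 9.0, 12.0),
}

DATASET_TYPES = ("PK1", "PK2", "PK3")
CANONICAL_CL = (1.5, 4.5)
CANONICAL_DURATIONS = (1.0, 2.0, 4.0)
CANONICAL_N = (25, 50, 100, 200)

# population typical values (vancomycin, adult ECMO model)
POP_V1 = 24.2   # L
POP_V2 = 32.3   # L
POP_Q = 11.2    # L/h

DOSE_AMOUNT = 1000.0   # mg
DOSE_INTERVAL = 12.0   # h
N_DOSES = 4

NONMEM_COLUMNS = ("ID", "TIME", "AMT", "RATE", "EVID", "MDV", "DV")


@dataclass(frozen=True)
class VarianceSpec:
    """Random-effect magnitudes for simulation and estimation.

    ``omega_sd`` holds the log-scale BSV standard deviations for
    (CL, V1, V2, Q); a 30% CV is implemented as omega = 0.30 exactly
    (the usual pharmacometric convention for exponential BSV).
    ``sigma_prop`` is the proportional residual-error coefficient.
    """

    omega_sd: tuple[float, float, float, float] = (0.30, 0.30, 0.30, 0.30)
    sigma_prop: float = 0.10

    def __post_init__(self) -> None:
        if len(self.omega_sd) != 4 or any(w < 0 for w in self.omega_sd):
            raise ValueError(f"omega_sd must be four non-negative values, got {self.omega_sd}")
        if self.sigma_prop < 0:
            raise ValueError(f"sigma_prop must be >= 0, got {self.sigma_prop}")

    @property
    def omega2(self) -> np.ndarray:
        """BSV variances (omega squared), the scale on which BSV is reported."""
        return np.asarray(self.omega_sd, dtype=float) ** 2


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the study grid."""

    dataset_type: str
    CL_true: float
    infusion_duration: float
    n_subjects: int

    def __post_init__(self) -> None:
        if self.dataset_type not in DATASET_TYPES:
            raise ValueError(f"dataset_type must be one of {DATASET_TYPES}, got {self.dataset_type!r}")
        if self.CL_true <= 0 or self.infusion_duration <= 0 or self.n_subjects < 1:
            raise ValueError(f"invalid scenario {self}")

    @property
    def is_canonical(self) -> bool:
        return (self.CL_true in CANONICAL_CL
                and self.infusion_duration in CANONICAL_DURATIONS
                and self.n_subjects in CANONICAL_N)

    @property
    def population_parameters(self) -> PKParameters:
        return PKParameters(CL=self.CL_true, V1=POP_V1, V2=POP_V2, Q=POP_Q)

    @property
    def regimen(self) -> Regimen:
        return Regimen.q_interval(DOSE_AMOUNT, self.infusion_duration,
                                  DOSE_INTERVAL, N_DOSES)

    def observation_times(self, baseline_mdv: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """Absolute observation times (h) and their MDV flags.

        The first-dose 0 h sample has a structurally zero prediction, which
        would make the proportional-error variance degenerate, so by
        default it is emitted with ``mdv=1`` (kept in the file, excluded
        from fitting); ``baseline_mdv=False`` keeps it fittable, which the
        estimator will reject.  The fourth-dose "0 h" sample is the 36 h
        trough and is always fitted.
        """
        offsets = np.asarray(sampling_offsets(self.infusion_duration))
        first = offsets
        fourth = offsets + 3 * DOSE_INTERVAL
        zero = (first == 0.0) if baseline_mdv else np.zeros(first.shape, dtype=bool)
        if self.dataset_type == "PK1":
            times, mdv = first, zero
        elif self.dataset_type == "PK2":
            times = fourth
            mdv = np.zeros(fourth.shape, dtype=bool)
        else:
            times = np.concatenate([first, fourth])
            mdv = np.concatenate([zero, np.zeros(fourth.shape, dtype=bool)])
        return times.astype(float), mdv

    def label(self, replicate: int | None = None) -> str:
        base = (f"{self.dataset_type}_{self.CL_true:g}_"
                f"{self.infusion_duration:g}h_n{self.n_subjects}")
        return base if replicate is None else f"{base}_rep{replicate}"

    def _seed_key(self) -> tuple[int, ...]:
        return (DATASET_TYPES.index(self.dataset_type),
                int(round(self.CL_true * 1000)),
                int(round(self.infusion_duration * 1000)),
                self.n_subjects)


@dataclass
class PopDataset:
    """Subject-structured observation records plus simulation provenance.

    ``records`` holds the NONMEM-dialect rows; ``individual_parameters``
    (one row per subject, with the drawn etas) is retained so tests can
    compare estimates against the simulation truth.
    """

    records: pd.DataFrame
    scenario: ScenarioSpec | None = None
    seed: object = None
    individual_parameters: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = [c for c in NONMEM_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"dataset is missing columns {missing}")

    @property
    def n_subjects(self) -> int:
        return self.records["ID"].nunique()


class DatasetParseError(ValueError):
    """Raised when a NONMEM-dialect CSV cannot be parsed."""


def sampling_offsets(infusion_duration: float) -> tuple[float, ...]:
    """The fixed sampling schedule (h after dose start) for one infusion length."""
    try:
        return SAMPLING_OFFSETS[float(infusion_duration)]
    except KeyError:
        raise ValueError(
            f"no sampling schedule is defined for a {infusion_duration} h infusion; "
            f"supported durations: {sorted(SAMPLING_OFFSETS)}"
        ) from None


def draw_individual(pop: PKParameters, var: VarianceSpec,
                    rng: np.random.Generator) -> PKParameters:
    """Draw one subject's parameters: theta_i = theta * exp(eta_i), eta ~ N(0, omega^2)."""
    eta = rng.normal(0.0, var.omega_sd, size=4)
    vals = pop.as_array() * np.exp(eta)
    return PKParameters(*vals)


def scenario_grid(dataset_types: Sequence[str] = DATASET_TYPES,
                  CLs: Sequence[float] = CANONICAL_CL,
                  durations: Sequence[float] = CANONICAL_DURATIONS,
                  ns: Sequence[int] = CANONICAL_N) -> list[ScenarioSpec]:
    """Cross product of the study factors; the full default grid has 72 cells."""
    return [ScenarioSpec(d, cl, dur, n)
            for d, cl, dur, n in itertools.product(dataset_types, CLs, durations, ns)]


def _subject_rows(subject_id: int, scenario: ScenarioSpec,
                  times: np.ndarray, mdv: np.ndarray,
                  dv: np.ndarray) -> pd.DataFrame:
    obs = pd.DataFrame({
        "ID": subject_id,
        "TIME": times,
        "AMT": np.nan,
        "RATE": np.nan,
        "EVID": 0,
        "MDV": mdv.astype(int),
        "DV": dv,
    })
    doses = pd.DataFrame({
        "ID": subject_id,
        "TIME": [d.start_time for d in scenario.regimen.doses],
        "AMT": [d.amount for d in scenario.regimen.doses],
        "RATE": [d.rate for d in scenario.regimen.doses],
        "EVID": 1,
        "MDV": 1,
        "DV": np.nan,
    })
    rows = pd.concat([obs, doses], ignore_index=True)
    # stable sort on (TIME, EVID): trough observations precede coincident doses
    return rows.sort_values(["TIME", "EVID"], kind="stable", ignore_index=True)


def simulate_dataset(scenario: ScenarioSpec, var: VarianceSpec | None = None,
                     seed: int | Sequence[int] = 0,
                     baseline_mdv: bool = True) -> PopDataset:
    """Simulate one replicate dataset for ``scenario``.

    Every subject receives four 1000 mg infusions 12 h apart and is sampled
    on the scenario's fixed schedule.  Observations carry proportional
    error, ``dv = pred * (1 + sigma * eps)``, truncated at zero (negative
    draws are astronomically rare at a 10% CV but must not produce invalid
    records).  Randomness is fully determined by ``(seed, scenario)`` with
    an independent substream per subject.
    """
    var = var or VarianceSpec()
    entropy = [seed] if np.isscalar(seed) else list(seed)
    root = np.random.SeedSequence(entropy + list(scenario._seed_key()))
    child_seqs = root.spawn(scenario.n_subjects)

    times, mdv = scenario.observation_times(baseline_mdv=baseline_mdv)
    pop = scenario.population_parameters
    frames, indiv_rows = [], []
    for i, seq in enumerate(child_seqs, start=1):
        rng = np.random.default_rng(seq)
        eta = rng.normal(0.0, var.omega_sd, size=4)
        params = PKParameters(*(pop.as_array() * np.exp(eta)))
        pred = conc_profile(params, scenario.regimen, times)
        eps = rng.normal(0.0, 1.0, size=times.shape)
        dv = pred * (1.0 + var.sigma_prop * eps)
        dv = np.maximum(dv, 0.0)
        frames.append(_subject_rows(i, scenario, times, mdv, dv))
        indiv_rows.append({"ID": i, "CL": params.CL, "V1": params.V1,
                           "V2": params.V2, "Q": params.Q,
                           "eta_CL": eta[0], "eta_V1": eta[1],
                           "eta_V2": eta[2], "eta_Q": eta[3]})
    records = pd.concat(frames, ignore_index=True)
    return PopDataset(records=records, scenario=scenario, seed=seed,
                      individual_parameters=pd.DataFrame(indiv_rows))


def write_dataset(dataset: PopDataset, path: str | Path) -> None:
    """Write the NONMEM-dialect CSV (missing numeric cells as ".")."""
    df = dataset.records.loc[:, list(NONMEM_COLUMNS)]
    df.to_csv(path, index=False, na_rep=".")


def read_dataset(path: str | Path) -> PopDataset:
    """Read a NONMEM-dialect CSV, validating every cell.

    Raises :class:`DatasetParseError` naming the 1-based file line of the
    first malformed cell.
    """
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in NONMEM_COLUMNS if c not in raw.columns]
    if missing:
        raise DatasetParseError(f"{path}: missing columns {missing}")
    out = pd.DataFrame()
    for col in NONMEM_COLUMNS:
        cells = raw[col].str.strip()
        empty = cells == "."
        vals = pd.to_numeric(cells.where(~empty), errors="coerce")
        bad = vals.isna() & ~empty
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise DatasetParseError(
                f"{path}, line {line}: non-numeric {col} value {cells[bad.idxmax()]!r}")
        out[col] = vals
    for col in ("ID", "EVID", "MDV"):
        if out[col].isna().any():
            line = int(out[col].isna().idxmax()) + 2
            raise DatasetParseError(f"{path}, line {line}: {col} must not be empty")
        out[col] = out[col].astype(int)
    return PopDataset(records=out)
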