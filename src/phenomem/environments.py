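"""Fluctuating environments: antibiotic-treatment schedules and lineage fitness.

The persistence protocol alternates two seasons.  In the permissive season
'off' cells grow at ``b_off - d_off = 0.02`` and the switch is inactive
(``mu = 0``).  Under treatment the switch is triggered (``mu = 0.2``), 'off'
cells die faster than they divide (``b_off - d_off = -0.02``) and 'on'
cells are persisters: tolerant but non-growing (``b_on = d_on = 0``).  The
leaching rate ``eps = 0.25`` applies throughout.

A lineage with memory ``n_on`` is scored against a memory-less comparator
(``n_on = 1``) whose leaching rate ``eps/n_on`` gives the same equilibrium
'on' fraction under sustained treatment.  Fitness over one environmental
sequence of total length ``t_max`` is the difference of log-growths per
unit time, ``r = (g_m - g_mless) / t_max`` with
``g = log(N(t_max)/N(0))``, computed from separate monoculture runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import (
    CompartmentState,
    InvalidParameterError,
    ModelParams,
    memoryless_equivalent_epsilon,
)
from .ode_dynamics import Trajectory, integrate_schedule

PERMISSIVE = "permissive"
TREATMENT = "treatment"

#: defaults of the antibiotic protocol
DEFAULT_EPSILON = 0.25
DEFAULT_T_MAX = 165.0
DEFAULT_ONSET = 40.0
DEFAULT_N_SEQUENCES = 84
DEFAULT_N0 = 1000.0


@dataclass(frozen=True)
class Season:
    duration: float
    label: str
    params: ModelParams

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise InvalidParameterError("season duration must be >= 0")
        if self.label not in (PERMISSIVE, TREATMENT):
            raise InvalidParameterError(f"unknown season label {self.label!r}")


@dataclass(frozen=True)
class EnvironmentSchedule:
    """Piecewise-constant sequence of seasons covering [0, total_duration]."""

    seasons: tuple
    schedule_id: str = ""

    def __post_init__(self) -> None:
        if not self.seasons:
            raise InvalidParameterError("schedule needs at least one season")
        object.__setattr__(self, "seasons", tuple(self.seasons))

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.seasons))

    @property
    def treatment_length(self) -> float:
        return float(sum(s.duration for s in self.seasons if s.label == TREATMENT))

    @property
    def n_on(self) -> int:
        return self.seasons[0].params.n_on

    def with_lineage(self, n_on: int, epsilon: float | None = None) -> "EnvironmentSchedule":
        """Re-instantiate every season's params for another lineage
        (memory length and optionally leaching rate)."""
        seasons = []
        for s in self.seasons:
            p = s.params.with_n_on(n_on)
            if epsilon is not None:
                p = p.replace(epsilon=epsilon)
            seasons.append(Season(s.duration, s.label, p))
        return EnvironmentSchedule(tuple(seasons), schedule_id=self.schedule_id)

    # -- serialisation: one season per line ------------------------------
    def to_tsv(self, path) -> None:
        header = "start\tend\tlabel\tmu\tb_off\td_off\tb_on\td_on\tepsilon"
        t = 0.0
        with open(path, "w") as fh:
            fh.write(f"# schedule_id\t{self.schedule_id}\n# n_on\t{self.n_on}\n")
            fh.write(header + "\n")
            for s in self.seasons:
                p = s.params
                b_on = p.birth[1] if p.n_on >= 1 else 0.0
                d_on = p.death[1] if p.n_on >= 1 else 0.0
                fh.write("\t".join([repr(t), repr(t + s.duration), s.label,
                                    repr(float(p.mu)), repr(float(p.birth[0])),
                                    repr(float(p.death[0])), repr(float(b_on)),
                                    repr(float(d_on)), repr(float(p.epsilon))]) + "\n")
                t += s.duration

    @classmethod
    def from_tsv(cls, path) -> "EnvironmentSchedule":
        schedule_id, n_on = "", None
        seasons = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# schedule_id"):
                    parts = line.split("\t")
                    schedule_id = parts[1] if len(parts) > 1 else ""
                    continue
                if line.startswith("# n_on"):
                    n_on = int(line.split("\t")[1])
                    continue
                if line.startswith("#") or line.startswith("start") or not line:
                    continue
                f = line.split("\t")
                start, end = float(f[0]), float(f[1])
                label = f[2]
                mu, b_off, d_off, b_on, d_on, eps = map(float, f[3:9])
                p = season_params(n_on, mu=mu, epsilon=eps, b_off=b_off,
                                  d_off=d_off, b_on=b_on, d_on=d_on)
                seasons.append(Season(end - start, label, p))
        return cls(tuple(seasons), schedule_id=schedule_id)


@dataclass(frozen=True)
class FitnessRecord:
    """Absolute and relative growth over one environmental sequence."""

    n_on: int
    schedule_id: str
    treatment_length: float
    g_m: float
    g_mless: float
    r: float
    extinct: bool = False


def season_params(n_on: int, *, mu: float, epsilon: float, b_off: float,
                  d_off: float, b_on: float = 0.0, d_on: float = 0.0) -> ModelParams:
    """ModelParams for one season: 'off' rates at index 0, uniform 'on' rates."""
    birth = np.concatenate([[b_off], np.full(n_on, b_on)])
    death = np.concatenate([[d_off], np.full(n_on, d_on)])
    return ModelParams(n_on=n_on, mu=mu, epsilon=epsilon, birth=birth, death=death)


def default_permissive_params(n_on: int, epsilon: float = DEFAULT_EPSILON) -> ModelParams:
    """No-treatment season: 'off' cells grow (b=1, d=0.98), switch inactive,
    'on' cells (persisters) neither divide nor die."""
    return season_params(n_on, mu=0.0, epsilon=epsilon, b_off=1.0, d_off=0.98)


def default_treatment_params(n_on: int, epsilon: float = DEFAULT_EPSILON) -> ModelParams:
    """Treatment season: switch triggered (mu=0.2), 'off' cells decline
    (b=1, d=1.02), persisters tolerant and non-growing."""
    return season_params(n_on, mu=0.2, epsilon=epsilon, b_off=1.0, d_off=1.02)


def make_treatment_schedule(treatment_length: float, onset: float, total: float,
                            permissive_params: ModelParams,
                            treatment_params: ModelParams,
                            schedule_id: str = "") -> EnvironmentSchedule:
    """[permissive(onset), treatment(length), permissive(rest)]; zero-length
    seasons are dropped."""
    if treatment_length < 0 or onset < 0 or total <= 0:
        raise InvalidParameterError("durations must be non-negative, total > 0")
    if onset + treatment_length > total + 1e-12:
        raise InvalidParameterError(
            f"onset + treatment_length = {onset + treatment_length} exceeds total {total}")
    pieces = [(onset, PERMISSIVE, permissive_params),
              (treatment_length, TREATMENT, treatment_params),
              (total - onset - treatment_length, PERMISSIVE, permissive_params)]
    seasons = tuple(Season(d, lab, p) for d, lab, p in pieces if d > 1e-12)
    if not seasons:
        raise InvalidParameterError("schedule would be empty")
    return EnvironmentSchedule(seasons, schedule_id=schedule_id)


def make_grid(n_sequences: int = DEFAULT_N_SEQUENCES, total: float = DEFAULT_T_MAX,
              onset: float = DEFAULT_ONSET, n_on: int = 1,
              epsilon: float = DEFAULT_EPSILON,
              permissive_params: ModelParams | None = None,
              treatment_params: ModelParams | None = None) -> list:
    """The treatment grid: schedules with treatment lengths 1..n_sequences
    time units, common onset and total duration."""
    if n_sequences < 1:
        raise InvalidParameterError("n_sequences must be >= 1")
    if onset + n_sequences > total:
        raise InvalidParameterError(
            f"longest treatment ({n_sequences}) exceeds total - onset ({total - onset})")
    pp = permissive_params or default_permissive_params(n_on, epsilon)
    tp = treatment_params or default_treatment_params(n_on, epsilon)
    return [
        make_treatment_schedule(float(k), onset, total, pp, tp, schedule_id=f"seq{k:03d}")
        for k in range(1, n_sequences + 1)
    ]


def _log_growth(schedule: EnvironmentSchedule, n0: float, dt_out: float) -> tuple[float, Trajectory]:
    init = CompartmentState.all_off(schedule.n_on, n0)
    traj = integrate_schedule(schedule, init, dt_out=dt_out)
    n_final = traj.total_population[-1]
    if n_final <= 0:
        return float("-inf"), traj
    return float(np.log(n_final / n0)), traj


def lineage_fitness(n_on: int, schedule: EnvironmentSchedule,
                    initial_off_cells: float = DEFAULT_N0,
                    dt_out: float = 0.5) -> FitnessRecord:
    """Fitness of a memory lineage relative to its calibrated memory-less
    comparator over one environmental sequence.

    Both lineages start as ``initial_off_cells`` 'off' cells and run through
    the same seasons; the comparator has ``n_on = 1`` and leaching rate
    ``eps / n_on``.  Propagation is by matrix exponential, so ``dt_out``
    only sets the trajectory sampling, not the accuracy of N(t_max).
    """
    mem_sched = schedule.with_lineage(n_on)
    base_eps = mem_sched.seasons[0].params.epsilon
    eps_mless = memoryless_equivalent_epsilon(
        ModelParams(n_on=n_on, mu=1.0, epsilon=base_eps, birth=0.0, death=0.0))
    mless_sched = schedule.with_lineage(1, epsilon=eps_mless)

    t_max = schedule.total_duration
    g_m, traj_m = _log_growth(mem_sched, initial_off_cells, dt_out)
    g_ml, traj_ml = _log_growth(mless_sched, initial_off_cells, dt_out)
    if np.isinf(g_m) or np.isinf(g_ml):
        r = float("-inf") if np.isinf(g_m) else float("inf")
        extinct = True
    else:
        r = (g_m - g_ml) / t_max
        extinct = False
    return FitnessRecord(n_on=n_on, schedule_id=schedule.schedule_id,
                         treatment_length=schedule.treatment_length,
                         g_m=g_m, g_mless=g_ml, r=r, extinct=extinct)


def fitness_landscape(n_on_range=range(1, 32), grid=None,
                      initial_off_cells: float = DEFAULT_N0,
                      onset: float = DEFAULT_ONSET,
                      epsilon: float = DEFAULT_EPSILON,
                      dt_out: float = 1.0) -> pd.DataFrame:
    """Full cross of memory sizes x treatment schedules.

    Defaults reproduce the protocol's 31 x 84 = 2604 records.  Columns
    follow the landscape table contract: ``schedule_id, treatment_length,
    onset, n_on, epsilon, epsilon_memoryless, g_m, g_mless, r,
    extinct_flag``.
    """
    if grid is None:
        grid = make_grid(onset=onset, epsilon=epsilon)
    n_on_range = list(n_on_range)
    if not n_on_range or not grid:
        raise InvalidParameterError("empty n_on_range or schedule grid")
    rows = []
    for sched in grid:
        for n in n_on_range:
            rec = lineage_fitness(n, sched, initial_off_cells, dt_out=dt_out)
            rows.append({
                "schedule_id": sched.schedule_id,
                "treatment_length": rec.treatment_length,
                "onset": onset,
                "n_on": n,
                "epsilon": sched.seasons[0].params.epsilon,
                "epsilon_memoryless": sched.seasons[0].params.epsilon / n,
                "g_m": rec.g_m,
                "g_mless": rec.g_mless,
                "r": rec.r,
                "extinct_flag": int(rec.extinct),
            })
    return pd.DataFrame(rows)


def landscape_to_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
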