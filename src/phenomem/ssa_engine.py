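"""Exact stochastic simulation (Gillespie direct method) of the reaction
network, plus a first-passage residence-time sampler.

Reactions for a cell in compartment i (propensities are per-capita rate
times abundance):

* birth   ``X_i -> 2 X_i``        at ``b_i x_i``       (all i)
* death   ``X_i -> 0``            at ``d_i x_i``       (all i)
* leach   ``X_i -> X_{i-1}``      at ``eps x_i``       (i = 1..n)
* switch  ``X_0 -> X_n``          at ``mu x_0``

The direct method recomputes the full propensity vector after every event;
populations here are small, so simplicity and auditability win over the
next-reaction method.  Reproducibility contract: one named NumPy generator
per run seeded explicitly; the waiting time is an inverse-CDF exponential
draw and the reaction is picked by a single uniform draw against the
cumulative propensity vector in fixed order — for each compartment i
ascending: birth_i, death_i, leach_i (i >= 1); switch last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model_core import CompartmentState, InvalidParameterError, ModelParams
from .ode_dynamics import Trajectory

_EVENT_NAMES = ("birth", "death", "leach", "switch")


@dataclass(frozen=True)
class SSAConfig:
    """Run plumbing: seed, event cap, and output granularity."""

    seed: int = 0
    max_events: int = 10_000_000
    record_mode: str = "grid_sampled"  # or "full_event_log"

    def __post_init__(self) -> None:
        if self.seed < 0 or int(self.seed) != self.seed:
            raise InvalidParameterError("seed must be a non-negative integer")
        if self.max_events < 1:
            raise InvalidParameterError("max_events must be >= 1")
        if self.record_mode not in ("grid_sampled", "full_event_log"):
            raise InvalidParameterError(f"unknown record_mode {self.record_mode!r}")


@dataclass(frozen=True)
class ResidenceTimeSample:
    """First-passage times from compartment n_on down to 'off'."""

    durations: np.ndarray
    n_on: int
    epsilon: float
    seed: int

    def __post_init__(self) -> None:
        d = np.asarray(self.durations, dtype=float)
        if np.any(d <= 0):
            raise InvalidParameterError("durations must be positive")
        d.flags.writeable = False
        object.__setattr__(self, "durations", d)

    @property
    def n_samples(self) -> int:
        return self.durations.size


def _event_table(params: ModelParams):
    """Per-event (rate, type, compartment, delta) in the documented order."""
    n = params.n_on
    rates, kinds, comps, deltas = [], [], [], []
    for i in range(n + 1):
        rates.append(params.birth[i]); kinds.append(0); comps.append(i)
        d = np.zeros(n + 1); d[i] = +1; deltas.append(d)
        rates.append(params.death[i]); kinds.append(1); comps.append(i)
        d = np.zeros(n + 1); d[i] = -1; deltas.append(d)
        if i >= 1:
            rates.append(params.epsilon); kinds.append(2); comps.append(i)
            d = np.zeros(n + 1); d[i] = -1; d[i - 1] = +1; deltas.append(d)
    rates.append(params.mu); kinds.append(3); comps.append(0)
    d = np.zeros(n + 1); d[0] = -1; d[n] = +1; deltas.append(d)
    return (np.asarray(rates), np.asarray(kinds), np.asarray(comps),
            np.asarray(deltas, dtype=np.int64))


_BATCH = 8192


def gillespie(params: ModelParams, initial: CompartmentState, t_end: float,
              config: SSAConfig, dt_out: float = 0.1):
    """One exact realization of the continuous-time Markov chain.

    Returns an integer-valued :class:`~phenomem.ode_dynamics.Trajectory`
    sampled on a uniform grid of step ``dt_out`` (state recorded as of each
    grid time).  ``traj.flags`` carries ``extinct`` / ``truncated`` markers
    and, in ``full_event_log`` mode, the event log as a list of
    ``(time, event_type, compartment, state_copy)`` tuples.

    Extinction before ``t_end`` ends the trajectory at the extinction time
    with the flag set (not an error); exceeding ``max_events`` sets the
    truncation flag.
    """
    if not t_end > initial.time:
        raise InvalidParameterError("t_end must exceed the initial time")
    x = np.asarray(initial.abundances)
    if np.any(x != np.round(x)):
        raise InvalidParameterError("SSA requires integer initial abundances")
    x = x.astype(np.int64)
    if x.size != params.n_on + 1:
        raise InvalidParameterError("initial state incompatible with params")

    rng = np.random.default_rng(config.seed)
    rates, kinds, comps, deltas = _event_table(params)
    n_events_max = len(rates)

    grid = initial.time + dt_out * np.arange(
        int(np.floor((t_end - initial.time) / dt_out + 1e-9)) + 1)
    if t_end - grid[-1] > 1e-9:
        grid = np.append(grid, t_end)
    rec = np.empty((grid.size, x.size), dtype=np.int64)
    gi = 0  # next grid index to fill

    log = [] if config.record_mode == "full_event_log" else None
    t = initial.time
    n_events = 0
    extinct = truncated = False

    u = rng.random(2 * _BATCH)  # batched uniform draws: [wait, pick] pairs
    ui = 0
    prop = np.empty(n_events_max)
    while True:
        np.multiply(rates, x[comps], out=prop)
        # switch propensity uses x_0; leach/birth/death use their compartment
        total = prop.sum()
        if total <= 0.0:
            t = t_end  # absorbing state: constant to the end of the run
            break
        if ui >= 2 * _BATCH:
            u = rng.random(2 * _BATCH)
            ui = 0
        t_next = t - np.log1p(-u[ui]) / total  # inverse-CDF exponential
        ui += 1
        if t_next >= t_end:
            t = t_end
            ui += 1  # keep the draw pairing fixed
            break
        # record states for grid points passed before this event fires
        while gi < grid.size and grid[gi] < t_next:
            rec[gi] = x
            gi += 1
        t = t_next
        cum = np.cumsum(prop)
        j = int(np.searchsorted(cum, u[ui] * total, side="right"))
        j = min(j, n_events_max - 1)
        ui += 1
        x = x + deltas[j]
        n_events += 1
        if log is not None:
            log.append((float(t), _EVENT_NAMES[kinds[j]], int(comps[j]), x.copy()))
        if x.sum() == 0:
            extinct = True
            break
        if n_events >= config.max_events:
            truncated = True
            break

    while gi < grid.size and grid[gi] <= t + 1e-12:
        rec[gi] = x
        gi += 1
    times = grid[:gi]
    states = rec[:gi]
    if extinct and (times.size == 0 or times[-1] < t):
        times = np.append(times, t)
        states = np.vstack([states, x]) if states.size else x[None, :]

    flags = {"extinct": extinct, "truncated": truncated, "n_events": n_events,
             "seed": config.seed, "t_final": float(t)}
    if log is not None:
        flags["event_log"] = log
    return Trajectory(times=times, states=states.astype(float), flags=flags)


def sample_residence_times(n_on: int, epsilon: float, n_samples: int,
                           config: SSAConfig) -> ResidenceTimeSample:
    """First-passage times of a single cell from compartment n_on to 'off'.

    With births and deaths off, the cell's path is the pure leaching chain
    n -> n-1 -> ... -> 0 and the simulation reduces to drawing the n_on
    exponential(epsilon) sojourn times event-by-event; their sum is the
    residence time, gamma(n_on, epsilon) distributed by construction.
    """
    if n_on < 1 or n_samples < 1:
        raise InvalidParameterError("n_on and n_samples must be >= 1")
    if not epsilon > 0:
        raise InvalidParameterError("epsilon must be positive")
    rng = np.random.default_rng(config.seed)
    sojourns = rng.exponential(scale=1.0 / epsilon, size=(n_samples, n_on))
    return ResidenceTimeSample(durations=sojourns.sum(axis=1), n_on=n_on,
                               epsilon=epsilon, seed=config.seed)


# -- plain-text writers --------------------------------------------------

def write_event_log(traj: Trajectory, path) -> None:
    """Tab-separated ``time  event_type  compartment  x_0 ... x_n``."""
    log = traj.flags.get("event_log")
    if log is None:
        raise InvalidParameterError("trajectory carries no event log "
                                    "(run with record_mode='full_event_log')")
    n = traj.n_on
    header = "time\tevent_type\tcompartment\t" + "\t".join(
        f"x_{i}" for i in range(n + 1))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for t, kind, comp, state in log:
            fh.write(f"{t!r}\t{kind}\t{comp}\t"
                     + "\t".join(str(int(v)) for v in state) + "\n")


def write_residence_sample(sample: ResidenceTimeSample, path) -> None:
    """One duration per line, plus a ``<path>.meta`` key-value sidecar."""
    with open(path, "w") as fh:
        for d in sample.durations:
            fh.write(f"{float(d)!r}\n")
    with open(f"{path}.meta", "w") as fh:
        fh.write(f"n_on\t{sample.n_on}\nepsilon\t{sample.epsilon!r}\n"
                 f"seed\t{sample.seed}\nn_samples\t{sample.n_samples}\n")


def read_residence_durations(path) -> np.ndarray:
    return np.loadtxt(path, ndmin=1)
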