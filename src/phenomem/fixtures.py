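"""Seeded fixture generator: small synthetic inputs for tests and demos.

Everything is produced by the package's own engines (or by direct seeded
draws from the assumed law, for parameter-recovery fixtures), so the test
suite needs no external data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .environments import (
    default_permissive_params,
    default_treatment_params,
    make_treatment_schedule,
)
from .model_core import CompartmentState, ModelParams
from .ode_dynamics import integrate
from .ssa_engine import SSAConfig, gillespie, write_event_log, write_residence_sample, sample_residence_times


def generate_fixtures(seed: int, outdir) -> list:
    """Write the fixture set into ``outdir``; returns the paths written.

    * ``gamma_sample.txt`` — 5000 exact gamma(shape 2, rate 1) draws.
    * ``residence_sample.txt`` (+ ``.meta``) — 2000 first-passage times,
      n_on = 4, eps = 0.3.
    * ``ssa_event_log.tsv`` — a short full event log (20 cells, t = 2).
    * ``ode_trajectory.tsv`` — a transient with a known overshoot
      (n_on = 4, mu = 0.2, eps = 0.5, symmetric growth, all-'off' start).
    * ``schedule.tsv`` — a 3-season permissive/treatment/permissive file.
    * ``manifest.json`` — seed, package version and file list.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    written = []

    gamma_path = outdir / "gamma_sample.txt"
    draws = rng.gamma(shape=2.0, scale=1.0, size=5000)
    with open(gamma_path, "w") as fh:
        fh.writelines(f"{float(d)!r}\n" for d in draws)
    written.append(gamma_path)

    res_path = outdir / "residence_sample.txt"
    sample = sample_residence_times(4, 0.3, 2000, SSAConfig(seed=seed))
    write_residence_sample(sample, res_path)
    written += [res_path, Path(f"{res_path}.meta")]

    log_path = outdir / "ssa_event_log.tsv"
    params = ModelParams(n_on=4, mu=0.2, epsilon=0.5, birth=1.0, death=0.98)
    traj = gillespie(params, CompartmentState.all_off(4, 20), t_end=2.0,
                     config=SSAConfig(seed=seed, record_mode="full_event_log"))
    write_event_log(traj, log_path)
    written.append(log_path)

    ode_path = outdir / "ode_trajectory.tsv"
    ode = integrate(params, CompartmentState.all_off(4, 1000.0), t_end=60.0,
                    dt_out=0.05)
    ode.to_tsv(ode_path)
    written.append(ode_path)

    sched_path = outdir / "schedule.tsv"
    sched = make_treatment_schedule(5.0, 10.0, 30.0,
                                    default_permissive_params(4),
                                    default_treatment_params(4),
                                    schedule_id="fixture")
    sched.to_tsv(sched_path)
    written.append(sched_path)

    manifest = outdir / "manifest.json"
    with open(manifest, "w") as fh:
        json.dump({"seed": int(seed), "version": __version__,
                   "files": sorted(p.name for p in written)}, fh, indent=2)
        fh.write("\n")
    written.append(manifest)
    return written
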