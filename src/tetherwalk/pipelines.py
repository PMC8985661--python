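"""End-to-end assay pipelines composed from the library modules.

These mirror the laboratory workflows: simulate motors under a chosen
MAP7 condition, image them into noisy trajectories, run the step finder,
and pool the detected steps — or titrate run frequency against
concentration and fit the dose-response curve.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .decoration import MAPParams, decorate_equilibrium
from .lattice import EMPTY, LatticeGeometry, LatticeState
from .motors import MotorParams, RunRecord, TetherParams, simulate_run
from .presets import map_preset, motor_preset, noise_defaults, tether_defaults
from .stepfind import StepTable, find_steps
from .synthetic import NoiseModel, make_trajectory

__all__ = ["stepping_assay"]


def stepping_assay(
    concentration: float,
    n_runs: int = 200,
    seed: int | np.random.Generator = 1,
    motor: MotorParams | None = None,
    map_params: MAPParams | None = None,
    tether: TetherParams | None = None,
    noise: NoiseModel | None = None,
    geometry: LatticeGeometry | None = None,
    t_max: float = 60.0,
    penalty: float | None = None,
    start_axial: int = 50,
) -> tuple[pd.DataFrame, list[RunRecord]]:
    """Simulate, image and step-find a set of single-motor stepping traces.

    Motors are landed on random empty sites of column ``start_axial`` of a
    lattice equilibrated at ``concentration`` nM MAP7, run for up to
    ``t_max`` s under limiting-ATP stepping kinetics, sampled into noisy
    trajectories, and analysed with :func:`find_steps`.  Returns the
    pooled detected-step table and the underlying run records.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    motor = motor or motor_preset("K560_limiting_ATP")
    map_params = map_params or map_preset("FL_MAP7")
    tether = tether or tether_defaults()
    noise = noise or noise_defaults()
    geometry = geometry or LatticeGeometry(n_sites=400)
    frames: list[pd.DataFrame] = []
    records: list[RunRecord] = []
    for _ in range(n_runs):
        state = LatticeState.empty(geometry)
        decorate_equilibrium(state, map_params, concentration, rng)
        free_pfs = np.flatnonzero(state.occupancy[:, start_axial] == EMPTY)
        if free_pfs.size == 0:
            continue
        site = (int(free_pfs[rng.integers(free_pfs.size)]), start_axial)
        rec = simulate_run(state, motor, tether, map_params, concentration,
                           seed=rng, start_site=site, t_max=t_max)
        records.append(rec)
        traj = make_trajectory(rec, noise, seed=rng)
        if len(traj) < 10:
            continue
        table: StepTable = (find_steps(traj) if penalty is None
                            else find_steps(traj, penalty))
        if len(table):
            frames.append(table.steps)
    steps = (pd.concat(frames, ignore_index=True) if frames
             else pd.DataFrame(columns=["t_s", "frame", "dx_nm", "dy_nm", "class"]))
    return steps, records
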