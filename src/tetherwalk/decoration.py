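"""MAP7 binding kinetics and equilibrium decoration of the lattice.

MAP7 constructs bind tubulin-dimer sites through their microtubule-binding
domain (MTBD) with association rate ``k_on * c`` per empty site and
dissociation rate ``k_off`` per bound site, giving the Langmuir/Hill
occupancy theta = c^h / (c^h + K_D^h) at equilibrium.  Sites already held
by a motor are never bound (competitive exclusion).

Constructs lacking the MTBD still associate weakly with the flexible
C-terminal tubulin tails; this tail component does not occupy lattice
sites, does not block motors, and disappears when the tails are cleaved
(the subtilisin condition of the binding assay).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lattice import EMPTY, KINESIN, MAP7, LatticeGeometry, LatticeState

__all__ = [
    "MAPParams",
    "equilibrium_occupancy",
    "decorate_equilibrium",
    "simulate_decoration",
    "steady_state_occupancy",
    "binding_assay",
    "read_titration",
    "write_titration",
]

TITRATION_COLUMNS = ["concentration_nM", "response", "sd", "n"]


@dataclass(frozen=True)
class MAPParams:
    """Kinetic and structural parameters of one MAP construct.

    ``k_on`` is per-nM per-site per-s, ``k_off`` per-s; K_D = k_off/k_on.
    ``has_mtbd`` marks constructs that occupy lattice sites exclusively;
    ``has_projection`` marks constructs whose projection domain can recruit
    and tether kinesin; ``tail_weight`` scales the weak, non-exclusive
    tubulin-tail association (amplitude relative to a saturated MTBD
    signal) with its own affinity ``tail_kd_nM``.
    """

    name: str = "FL_MAP7"
    k_on: float = 1.0 / 111.0
    k_off: float = 1.0
    hill_h: float = 1.0
    has_mtbd: bool = True
    has_projection: bool = True
    tail_weight: float = 0.0
    tail_kd_nM: float = 2000.0

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off <= 0:
            raise ValueError("require k_on >= 0 and k_off > 0")
        if self.hill_h <= 0:
            raise ValueError("Hill coefficient must be positive")

    @property
    def kd(self) -> float:
        """Equilibrium dissociation constant K_D = k_off / k_on in nM."""
        if self.k_on == 0:
            return np.inf
        return self.k_off / self.k_on

    @property
    def tail_dependent(self) -> bool:
        """True when lattice binding relies solely on the tubulin tails."""
        return (not self.has_mtbd) and self.tail_weight > 0


def equilibrium_occupancy(params: MAPParams, concentration: float) -> float:
    """Hill-form equilibrium site occupancy theta = c^h / (c^h + K_D^h)."""
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    if not params.has_mtbd or params.k_on == 0 or concentration == 0:
        return 0.0
    ch = concentration ** params.hill_h
    return float(ch / (ch + params.kd ** params.hill_h))


def decorate_equilibrium(
    state: LatticeState,
    params: MAPParams,
    concentration: float,
    rng: np.random.Generator,
) -> LatticeState:
    """Draw an exact equilibrium decoration: each EMPTY site binds i.i.d. Bernoulli(theta).

    For independent-site kinetics the stationary law is a product measure,
    so this is the distribution the Gillespie simulation relaxes to; it is
    used to equilibrate the lattice before (quasi-static) motor runs.
    """
    theta = equilibrium_occupancy(params, concentration)
    if theta > 0:
        empty = state.occupancy == EMPTY
        bind = empty & (rng.random(state.occupancy.shape) < theta)
        state.occupancy[bind] = MAP7
    return state


def simulate_decoration(
    state: LatticeState,
    params: MAPParams,
    concentration: float,
    duration: float,
    seed: int | np.random.Generator = 0,
    n_samples: int = 200,
) -> tuple[LatticeState, np.ndarray, np.ndarray]:
    """Kinetic Monte Carlo (Gillespie) of MAP7 binding/unbinding on the lattice.

    Events are per-site binding (rate ``k_on * c`` for each EMPTY site, only
    if the construct has an MTBD) and unbinding (rate ``k_off`` per MAP7
    site).  Motor-occupied sites are excluded throughout.  Returns the final
    state plus ``(times, occupancy_fraction)`` sampled on an even grid —
    occupancy is the MAP7 fraction of *all* sites.

    The long-time mean converges to :func:`equilibrium_occupancy` within
    Monte-Carlo error (see the decoration tests).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    flat = state.occupancy.ravel()
    n_total = flat.size
    # index bookkeeping: swap-removal lists of bindable (EMPTY) and bound (MAP7) sites
    bindable = np.flatnonzero(flat == EMPTY).tolist()
    bound = np.flatnonzero(flat == MAP7).tolist()
    pos_in_bindable = {s: i for i, s in enumerate(bindable)}
    pos_in_bound = {s: i for i, s in enumerate(bound)}

    kon_c = params.k_on * concentration if params.has_mtbd else 0.0
    koff = params.k_off

    sample_times = np.linspace(0.0, duration, n_samples)
    occ = np.empty(n_samples)
    next_sample = 0
    t = 0.0

    def record_until(t_now: float) -> None:
        nonlocal next_sample
        frac = len(bound) / n_total
        while next_sample < n_samples and sample_times[next_sample] <= t_now:
            occ[next_sample] = frac
            next_sample += 1

    while True:
        rate_bind = kon_c * len(bindable)
        rate_unbind = koff * len(bound)
        total = rate_bind + rate_unbind
        if total == 0:
            break
        dt = rng.exponential(1.0 / total)
        if t + dt > duration:
            break
        record_until(t + dt)
        t += dt
        if rng.random() * total < rate_bind:
            i = rng.integers(len(bindable))
            s = bindable[i]
            last = bindable.pop()
            if last != s:
                bindable[i] = last
                pos_in_bindable[last] = i
            del pos_in_bindable[s]
            pos_in_bound[s] = len(bound)
            bound.append(s)
            flat[s] = MAP7
        else:
            i = rng.integers(len(bound))
            s = bound[i]
            last = bound.pop()
            if last != s:
                bound[i] = last
                pos_in_bound[last] = i
            del pos_in_bound[s]
            pos_in_bindable[s] = len(bindable)
            bindable.append(s)
            flat[s] = EMPTY
    record_until(duration)
    occ[next_sample:] = len(bound) / n_total
    return state, sample_times, occ


def steady_state_occupancy(
    params: MAPParams,
    concentration: float,
    geometry: LatticeGeometry | None = None,
    seed: int | np.random.Generator = 0,
    relax_times: float = 10.0,
) -> tuple[float, float]:
    """Gillespie steady-state MAP7 occupancy (mean, standard error).

    Runs the kinetic simulation for ``relax_times / k_off`` twice the burn-in
    and averages the second half of the occupancy trace.  The s.e. uses an
    effective sample size of one per relaxation time 1/k_off.
    """
    geometry = geometry or LatticeGeometry()
    state = LatticeState.empty(geometry)
    duration = 2.0 * relax_times / params.k_off
    _, times, occ = simulate_decoration(state, params, concentration, duration, seed)
    half = occ[times > duration / 2]
    mean = float(half.mean())
    # binomial scatter of one snapshot, decorrelated over ~1/k_off -> ~relax_times
    # effectively independent snapshots in the averaged window
    n_eff = max(1.0, relax_times)
    se = float(np.sqrt(max(mean * (1 - mean), 1e-12) / geometry.total_sites / n_eff))
    return mean, se


def binding_assay(
    params: MAPParams,
    lattice_condition: str = "bare",
    concentration: float = 1000.0,
    seed: int | np.random.Generator = 0,
    geometry: LatticeGeometry | None = None,
    reference: MAPParams | None = None,
) -> float:
    """Steady-state bound signal under an assay condition, normalized to FL on bare lattice.

    Conditions: ``bare`` (untreated lattice), ``kinesin_predecorated``
    (every site pre-filled with a rigor kinesin mutant, blocking all MTBD
    binding) and ``subtilisin`` (tubulin tails cleaved, abolishing the
    tail component).  The signal is the MTBD site occupancy plus the
    non-exclusive tail association ``tail_weight * c/(c + tail_kd)``.
    """
    conditions = ("bare", "kinesin_predecorated", "subtilisin")
    if lattice_condition not in conditions:
        raise ValueError(f"unknown lattice condition {lattice_condition!r}; pick from {conditions}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geometry = geometry or LatticeGeometry()

    def signal(p: MAPParams, condition: str) -> float:
        state = LatticeState.empty(geometry)
        if condition == "kinesin_predecorated":
            state.occupancy[:] = KINESIN
        decorate_equilibrium(state, p, concentration, rng)
        mtbd = state.fraction(MAP7)
        tail = 0.0
        if p.tail_weight > 0 and condition != "subtilisin":
            tail = p.tail_weight * concentration / (concentration + p.tail_kd_nM)
        return mtbd + tail

    ref = reference if reference is not None else _fl_reference()
    denom = signal(ref, "bare")
    return signal(params, lattice_condition) / denom


def _fl_reference() -> MAPParams:
    from .presets import map_preset

    return map_preset("FL_MAP7")


def write_titration(table: pd.DataFrame, path) -> None:
    """Write a titration table CSV with the canonical header."""
    table.loc[:, [c for c in TITRATION_COLUMNS if c in table.columns]].to_csv(path, index=False)


def read_titration(path) -> pd.DataFrame:
    """Read a titration table CSV (concentration_nM, response[, sd, n])."""
    table = pd.read_csv(path)
    missing = {"concentration_nM", "response"} - set(table.columns)
    if missing:
        raise ValueError(f"titration table missing columns {sorted(missing)}")
    if (table["concentration_nM"] < 0).any():
        raise ValueError("concentrations must be nonnegative")
    return table
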