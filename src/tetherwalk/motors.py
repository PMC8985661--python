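"""Stochastic motor runs on a MAP-decorated lattice.

A single labelled motor head is evolved by an exact continuous-time
(Gillespie) event loop.  While bound, the motor attempts catalytic steps
at rate ``k_step`` (direction drawn from the forward/sideways/backward
probabilities) and spontaneously detaches at rate ``k_detach0``.  A step
attempt whose target dimer is occupied by a MAP7 MTBD usually leaves the
motor paused in place; with probability ``p_detach_block`` the collision
dislodges it, in which case a motor that carries the MAP7-binding stalk
(and a MAP with a projection domain) stays tethered to the obstacle and
may rebind any free site within the tether reach — the "tethered
diffusion" that shows up as 16-64 nm jumps in trajectories.  Motors
without that linkage simply end their run.

The module also provides the motility observables (run frequency, run
length, velocity), and the two-motor kinesin-dynein assembly
directionality draw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decoration import MAPParams, decorate_equilibrium, equilibrium_occupancy
from .lattice import (
    DYNEIN,
    EMPTY,
    KINESIN,
    MAP7,
    LatticeGeometry,
    LatticeState,
)

__all__ = [
    "MotorParams",
    "TetherParams",
    "RunRecord",
    "RunFrequencyResult",
    "simulate_run",
    "run_frequency",
    "run_frequency_curve",
    "run_statistics",
    "assembly_direction",
    "calibrate_assembly_scale",
]

# event tags
LAND = "LAND"
STEP_F = "STEP_F"
STEP_B = "STEP_B"
STEP_S = "STEP_S"
TETHER = "TETHER"
TETHER_JUMP = "TETHER_JUMP"
DETACH = "DETACH"
BOUNDARY = "BOUNDARY"
TIMEOUT = "TIMEOUT"


@dataclass(frozen=True)
class MotorParams:
    """Kinetic parameter set defining a motor construct.

    ``polarity`` is +1 for plus-end (kinesin) and -1 for minus-end
    (dynein) motors; ``step_size_sites`` is the displacement of the
    labelled head per catalytic cycle in dimer sites (2 = 16 nm for the
    hand-over-hand kinesin head).  ``p_detach_block`` is the probability
    that a blocked step attempt dislodges the motor instead of pausing it.
    ``n_clear`` > 0 marks obstacle-sensitive motors (dynein): a scored
    processive run requires ``n_clear`` consecutively available sites
    counting the landing site.  ``activity0`` is the landing-competent
    fraction at zero MAP7; with ``map7_activation`` the remainder is
    relieved from autoinhibition in proportion to lattice MAP7 occupancy.
    """

    name: str = "K560"
    polarity: int = 1
    step_size_sites: int = 2
    k_step: float = 50.0
    p_forward0: float = 0.88
    p_side0: float = 0.09
    p_back0: float = 0.03
    k_detach0: float = 0.8
    p_detach_block: float = 0.18
    binds_map7: bool = True
    k_land_basal: float = 1.0
    recruitment_gain: float = 5.0
    n_clear: int = 0
    activity0: float = 1.0
    map7_activation: bool = False

    def __post_init__(self) -> None:
        if abs(self.p_forward0 + self.p_side0 + self.p_back0 - 1.0) > 1e-9:
            raise ValueError("direction probabilities must sum to 1")
        if self.polarity not in (1, -1):
            raise ValueError("polarity must be +1 or -1")
        if not 0.0 <= self.p_detach_block <= 1.0:
            raise ValueError("p_detach_block must be a probability")

    def activity(self, map_params: MAPParams, concentration: float) -> float:
        """Landing-competent fraction at the given MAP7 concentration."""
        if not self.map7_activation:
            return self.activity0
        theta = equilibrium_occupancy(map_params, concentration)
        return self.activity0 + (1.0 - self.activity0) * theta


@dataclass(frozen=True)
class TetherParams:
    """Geometry and kinetics of the MAP7 projection-domain tether.

    Rebinding targets within ``reach_nm`` of the anchor are drawn with
    Boltzmann weights of an entropic-spring tether, w(d) = exp(-d^2 /
    (2 sd_nm^2)), so nearby free sites are preferred; ``sd_nm = None``
    (or infinity) makes the draw uniform over the reach disk.
    """

    reach_nm: float = 50.0
    k_rebind: float = 10.0
    k_release: float = 2.0
    sd_nm: float | None = 16.0

    def __post_init__(self) -> None:
        if self.reach_nm <= 0:
            raise ValueError("reach must be positive")
        if self.k_rebind < 0 or self.k_release < 0:
            raise ValueError("rates must be nonnegative")
        if self.sd_nm is not None and self.sd_nm <= 0:
            raise ValueError("tether sd must be positive (or None for uniform)")


@dataclass
class RunRecord:
    """Complete event history of one motor run.

    ``times``/``sites``/``tags`` hold every event; positions are the
    labelled-head coordinates on the unrolled lattice.  The motor position
    between events is the last bound site (tether excursions are not
    resolved spatially).
    """

    geometry: LatticeGeometry
    times: list[float] = field(default_factory=list)
    sites: list[tuple[int, int]] = field(default_factory=list)
    tags: list[str] = field(default_factory=list)
    n_productive_steps: int = 0
    n_tether_jumps: int = 0
    end_tag: str = DETACH

    def append(self, t: float, site: tuple[int, int], tag: str) -> None:
        if self.times and t < self.times[-1]:
            raise ValueError("event times must be nondecreasing")
        self.times.append(t)
        self.sites.append(site)
        self.tags.append(tag)

    # -- derived quantities ----------------------------------------------------
    def positions(self) -> np.ndarray:
        return np.array([self.geometry.site_position(*s) for s in self.sites])

    @property
    def duration(self) -> float:
        return self.times[-1] - self.times[0] if self.times else 0.0

    @property
    def run_length(self) -> float:
        """|on-axis displacement| between first and last bound position, nm."""
        if len(self.sites) < 2:
            return 0.0
        x0 = self.geometry.site_position(*self.sites[0])[0]
        x1 = self.geometry.site_position(*self.sites[-1])[0]
        return abs(x1 - x0)

    @property
    def mean_velocity(self) -> float:
        """On-axis displacement / duration, nm/s (signed by travel direction)."""
        if self.duration == 0:
            return 0.0
        x0 = self.geometry.site_position(*self.sites[0])[0]
        x1 = self.geometry.site_position(*self.sites[-1])[0]
        return (x1 - x0) / self.duration

    def to_frame(self, run_id: int = 0) -> pd.DataFrame:
        pos = self.positions() if self.sites else np.zeros((0, 2))
        return pd.DataFrame(
            {
                "time_s": self.times,
                "pf": [s[0] for s in self.sites],
                "axial": [s[1] for s in self.sites],
                "x_nm": pos[:, 0] if len(pos) else [],
                "y_nm": pos[:, 1] if len(pos) else [],
                "event_tag": self.tags,
                "run_id": run_id,
            }
        )


def records_to_frame(records: list[RunRecord]) -> pd.DataFrame:
    """Concatenate run event tables (one row per event, run_id column)."""
    return pd.concat([r.to_frame(i) for i, r in enumerate(records)], ignore_index=True)


class _LiveExchange:
    """Lazy, exact MAP7 binding/unbinding kinetics during a motor run.

    Decoration sites are independent two-state processes (EMPTY <-> MAP7
    with rates a = k_on * c and b = k_off), so the lattice never needs to
    be evolved globally: whenever the run queries a site at time t, its
    state is resampled from the two-state propagator conditioned on the
    state recorded at its last query.  This is statistically identical to
    simulating every site continuously, at the cost of one random draw per
    query, and it lets the wake of sites vacated by the motor refill on
    the 1/(a+b) relaxation time instead of staying empty forever.
    """

    def __init__(self, state: LatticeState, map_params: MAPParams, concentration: float):
        self.state = state
        self.a = (map_params.k_on * concentration) if map_params.has_mtbd else 0.0
        self.b = map_params.k_off
        self.rate = self.a + self.b
        self.theta = self.a / self.rate if self.rate > 0 else 0.0
        self.last_t = np.zeros_like(state.occupancy, dtype=float)

    @property
    def active(self) -> bool:
        return self.a > 0

    def refresh_window(self, ax_lo: int, ax_hi: int, t: float,
                       rng: np.random.Generator) -> None:
        """Bring every decoration site in occupancy[:, ax_lo:ax_hi] up to time t."""
        if not self.active:
            return
        occ = self.state.occupancy[:, ax_lo:ax_hi]
        dt = t - self.last_t[:, ax_lo:ax_hi]
        exch = occ <= MAP7  # EMPTY and MAP7 sites only; motors are untouched
        decay = np.exp(-self.rate * np.clip(dt, 0.0, None))
        p_map7 = self.theta + ((occ == MAP7) - self.theta) * decay
        flip = rng.random(occ.shape) < p_map7
        occ[exch & flip] = MAP7
        occ[exch & ~flip] = EMPTY
        self.last_t[:, ax_lo:ax_hi] = t

    def refresh_site(self, site: tuple[int, int], t: float,
                     rng: np.random.Generator) -> None:
        if not self.active:
            return
        occ = int(self.state.occupancy[site])
        if occ > MAP7:
            return
        dt = max(t - self.last_t[site], 0.0)
        decay = math.exp(-self.rate * dt)
        p_map7 = self.theta + ((occ == MAP7) - self.theta) * decay
        self.state.occupancy[site] = MAP7 if rng.random() < p_map7 else EMPTY
        self.last_t[site] = t


def _ax_window(geom, site: tuple[int, int], radius_nm: float) -> tuple[int, int]:
    d_ax = int(math.ceil((radius_nm + geom.lateral_rise * geom.n_protofilaments)
                         / geom.axial_spacing)) + 1
    return max(0, site[1] - d_ax), min(geom.n_sites, site[1] + d_ax + 1)


def _empty_sites_within(
    state: LatticeState, site: tuple[int, int], radius_nm: float
):
    """EMPTY sites within the reach disk of `site`, with their distances."""
    geom = state.geometry
    x0, y0 = geom.site_position(*site)
    ax_lo, ax_hi = _ax_window(geom, site, radius_nm)
    sub = state.occupancy[:, ax_lo:ax_hi]
    pf = np.arange(geom.n_protofilaments)[:, None]
    ax = np.arange(ax_lo, ax_hi)[None, :]
    x = ax * geom.axial_spacing + pf * geom.lateral_rise
    y = pf * geom.pf_spacing + np.zeros_like(x)
    dist = np.hypot(x - x0, y - y0)
    mask = (dist <= radius_nm) & (sub == EMPTY)
    pfs, axs = np.nonzero(mask)
    sites = [(int(p), int(a + ax_lo)) for p, a in zip(pfs, axs)]
    return sites, dist[pfs, axs]


def _draw_rebind_site(
    state: LatticeState,
    anchor: tuple[int, int],
    tether: TetherParams,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """Rebinding target near the anchor, Boltzmann-weighted by tether extension."""
    candidates, dist = _empty_sites_within(state, anchor, tether.reach_nm)
    if not candidates:
        return None
    if tether.sd_nm is None or not np.isfinite(tether.sd_nm):
        return candidates[rng.integers(len(candidates))]
    w = np.exp(-0.5 * (dist / tether.sd_nm) ** 2)
    w /= w.sum()
    return candidates[rng.choice(len(candidates), p=w)]


def _map7_fraction_within(state: LatticeState, site: tuple[int, int], radius_nm: float):
    """(MAP7 fraction within reach, MAP7 sites, their distances from `site`)."""
    geom = state.geometry
    x0, y0 = geom.site_position(*site)
    ax_lo, ax_hi = _ax_window(geom, site, radius_nm)
    sub = state.occupancy[:, ax_lo:ax_hi]
    pf = np.arange(geom.n_protofilaments)[:, None]
    ax = np.arange(ax_lo, ax_hi)[None, :]
    x = ax * geom.axial_spacing + pf * geom.lateral_rise
    y = pf * geom.pf_spacing + np.zeros_like(x)
    dist = np.hypot(x - x0, y - y0)
    within = dist <= radius_nm
    n_within = int(within.sum())
    if n_within == 0:
        return 0.0, [], np.empty(0)
    map7 = within & (sub == MAP7)
    pfs, axs = np.nonzero(map7)
    sites = [(int(p), int(a + ax_lo)) for p, a in zip(pfs, axs)]
    return float(map7.sum() / n_within), sites, dist[pfs, axs]


def _draw_anchor(
    state: LatticeState,
    pos: tuple[int, int],
    tether: TetherParams,
    rng: np.random.Generator,
) -> tuple[int, int] | None:
    """MAP7 site whose projection catches the dislodged motor.

    The catching MAP7 is the one holding the motor's stalk, so candidates
    within reach of the motor's position are weighted by the same
    entropic-spring factor as rebinding; returns None when no MAP7 is in
    reach.
    """
    _, sites, dist = _map7_fraction_within(state, pos, tether.reach_nm)
    if not sites:
        return None
    if tether.sd_nm is None or not np.isfinite(tether.sd_nm):
        return sites[rng.integers(len(sites))]
    w = np.exp(-0.5 * (dist / tether.sd_nm) ** 2)
    w /= w.sum()
    return sites[rng.choice(len(sites), p=w)]


def simulate_run(
    state: LatticeState,
    motor: MotorParams,
    tether: TetherParams | None = None,
    map_params: MAPParams | None = None,
    concentration: float = 0.0,
    seed: int | np.random.Generator = 0,
    start_site: tuple[int, int] | None = None,
    t_max: float = math.inf,
    max_events: int = 1_000_000,
    live_exchange: bool = True,
) -> RunRecord:
    """Simulate one motor run by exact continuous-time Monte Carlo.

    The lattice must already be decorated at equilibrium for the given
    concentration.  With ``live_exchange`` (default) MAP7 keeps
    exchanging during the run — implemented by exact lazy resampling of
    each queried site from the two-state propagator, so sites vacated by
    the motor refill on the binding relaxation time.  With
    ``live_exchange=False`` the decoration is frozen for the whole run
    (quasi-static approximation).  ``start_site`` must be EMPTY (default:
    centre of the lattice).  The motor occupies its site while bound, so
    exclusion is enforced against the decoration at every event.  Returns
    the full :class:`RunRecord`; the lattice is restored (motor removed)
    before returning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tether = tether or TetherParams()
    map_params = map_params or MAPParams()
    geom = state.geometry
    if start_site is None:
        start_site = (geom.n_protofilaments // 2, geom.n_sites // 2)
    if state.tag_at(start_site) != EMPTY:
        raise ValueError(f"start site {start_site} is not empty")

    motor_tag = KINESIN if motor.polarity > 0 else DYNEIN
    can_tether = motor.binds_map7 and map_params.has_projection
    exch = _LiveExchange(state, map_params, concentration) if live_exchange else None
    if exch is not None and not exch.active:
        exch = None

    def refresh_around(center: tuple[int, int], when: float) -> None:
        if exch is not None:
            lo, hi = _ax_window(geom, center, tether.reach_nm)
            exch.refresh_window(lo, hi, when, rng)

    rec = RunRecord(geometry=geom)
    pos = start_site
    state.occupy(pos, motor_tag)
    bound = True
    anchor: tuple[int, int] | None = None
    t = 0.0
    rec.append(t, pos, LAND)
    p_dirs = np.array([motor.p_forward0, motor.p_side0, motor.p_back0])

    def end(tag: str) -> RunRecord:
        nonlocal bound
        if bound:
            state.vacate(pos, motor_tag)
            bound = False
        rec.end_tag = tag
        rec.append(t, pos, tag)
        return rec

    for _ in range(max_events):
        if bound:
            total = motor.k_step + motor.k_detach0
            if total <= 0:
                return end(TIMEOUT)
            t_next = t + rng.exponential(1.0 / total)
            if t_next > t_max:
                t = t_max
                return end(TIMEOUT)
            t = t_next
            if rng.random() * total < motor.k_step:
                # catalytic step attempt
                u = rng.random()
                if u < p_dirs[0]:
                    target = (pos[0], pos[1] + motor.polarity * motor.step_size_sites)
                    tag = STEP_F
                elif u < p_dirs[0] + p_dirs[1]:
                    dpf = 1 if rng.random() < 0.5 else -1
                    target = (pos[0] + dpf, pos[1])
                    tag = STEP_S
                else:
                    target = (pos[0], pos[1] - motor.polarity * motor.step_size_sites)
                    tag = STEP_B
                if not 0 <= target[0] < geom.n_protofilaments:
                    continue  # lateral edge of the unrolled sheet: failed attempt
                if not 0 <= target[1] < geom.n_sites:
                    return end(BOUNDARY)  # ran off the microtubule end
                if exch is not None:
                    exch.refresh_site(target, t, rng)
                occ = state.tag_at(target)
                if occ == EMPTY:
                    state.vacate(pos, motor_tag)
                    state.occupy(target, motor_tag)
                    pos = target
                    rec.n_productive_steps += 1
                    rec.append(t, pos, tag)
                else:
                    # obstacle: usually pause, sometimes get dislodged
                    if rng.random() < motor.p_detach_block:
                        if can_tether and occ == MAP7:
                            refresh_around(pos, t)
                            anchor = _draw_anchor(state, pos, tether, rng) or target
                            state.vacate(pos, motor_tag)
                            bound = False
                            rec.append(t, pos, TETHER)
                        else:
                            return end(DETACH)
            else:
                # spontaneous detachment, possibly rescued by a nearby projection domain
                if can_tether:
                    refresh_around(pos, t)
                    frac, map7_sites, _ = _map7_fraction_within(state, pos, tether.reach_nm)
                    if map7_sites and rng.random() < frac:
                        anchor = _draw_anchor(state, pos, tether, rng)
                        state.vacate(pos, motor_tag)
                        bound = False
                        rec.append(t, pos, TETHER)
                        continue
                return end(DETACH)
        else:
            # tethered to the MAP7 projection at `anchor`
            total = tether.k_rebind + tether.k_release
            if total <= 0:
                return end(DETACH)
            t_next = t + rng.exponential(1.0 / total)
            if t_next > t_max:
                t = t_max
                return end(TIMEOUT)
            t = t_next
            if rng.random() * total < tether.k_rebind:
                refresh_around(anchor, t)
                target = _draw_rebind_site(state, anchor, tether, rng)
                if target is None:
                    return end(DETACH)
                pos = target
                state.occupy(pos, motor_tag)
                bound = True
                rec.n_tether_jumps += 1
                rec.append(t, pos, TETHER_JUMP)
            else:
                return end(DETACH)
    return end(TIMEOUT)


@dataclass(frozen=True)
class RunFrequencyResult:
    """Landing-rate x completion-probability decomposition of run frequency."""

    frequency: float
    landing_rate: float
    completion_prob: float
    se: float
    n_trials: int
    theta: float


def _processive_threshold(motor: MotorParams, min_run_length: int) -> int:
    if motor.n_clear > 0:
        # n_clear consecutive free sites counting the landing site
        return max(min_run_length, motor.n_clear - 1)
    return min_run_length


def run_frequency(
    motor: MotorParams,
    map_params: MAPParams,
    concentration: float,
    n_trials: int = 500,
    seed: int | np.random.Generator = 0,
    tether: TetherParams | None = None,
    geometry: LatticeGeometry | None = None,
    min_run_length: int = 5,
    t_max: float = 60.0,
) -> RunFrequencyResult:
    """Processive-run initiation frequency (runs per site per s, arbitrary basal units).

    frequency = landing rate x P(landed motor completes a processive run),
    with landing rate = ``k_land_basal * activity(c) * (1 + recruitment_gain
    * theta_projection) * fraction_empty``.  The completion probability is
    estimated by Monte-Carlo: motors are landed on random empty sites of an
    equilibrated lattice and scored processive when they accumulate the
    productive-step threshold (``min_run_length``, or the obstacle-clearance
    criterion for ``n_clear`` motors).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tether = tether or TetherParams()
    geometry = geometry or LatticeGeometry()
    theta = equilibrium_occupancy(map_params, concentration)
    theta_proj = theta if (motor.binds_map7 and map_params.has_projection) else 0.0
    landing_rate = (
        motor.k_land_basal
        * motor.activity(map_params, concentration)
        * (1.0 + motor.recruitment_gain * theta_proj)
        * (1.0 - theta)
    )
    threshold = _processive_threshold(motor, min_run_length)
    margin = max(motor.step_size_sites * (threshold + 2), 20)
    completed = 0
    for _ in range(n_trials):
        state = LatticeState.empty(geometry)
        decorate_equilibrium(state, map_params, concentration, rng)
        empties = np.flatnonzero(state.occupancy[:, margin:-margin] == EMPTY)
        if empties.size == 0:
            continue
        s = int(empties[rng.integers(empties.size)])
        n_ax = geometry.n_sites - 2 * margin
        site = (s // n_ax, s % n_ax + margin)
        rec = simulate_run(
            state, motor, tether, map_params, concentration,
            seed=rng, start_site=site, t_max=t_max,
        )
        if rec.n_productive_steps >= threshold:
            completed += 1
    p = completed / n_trials
    se_p = math.sqrt(max(p * (1 - p), 1e-12) / n_trials)
    return RunFrequencyResult(
        frequency=landing_rate * p,
        landing_rate=landing_rate,
        completion_prob=p,
        se=landing_rate * se_p,
        n_trials=n_trials,
        theta=theta,
    )


def run_frequency_curve(
    motor: MotorParams,
    map_params: MAPParams,
    concentrations,
    n_trials: int = 500,
    seed: int = 0,
    normalize: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """Titration table of run frequency vs MAP concentration.

    Columns (concentration_nM, response, n); responses optionally
    normalized to the first (lowest-concentration) point.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for c in concentrations:
        res = run_frequency(motor, map_params, float(c), n_trials, rng, **kwargs)
        rows.append({"concentration_nM": float(c), "response": res.frequency, "n": n_trials})
    table = pd.DataFrame(rows)
    if normalize:
        ref = table["response"].iloc[0]
        if ref <= 0:
            raise ValueError("cannot normalize: zero response at the reference point")
        table["response"] /= ref
    return table


def run_statistics(
    records: list[RunRecord],
    n_boot: int = 1000,
    seed: int = 0,
    observation: tuple[int, float] | None = None,
) -> dict[str, float]:
    """Summary motility statistics over a set of runs.

    Returns mean run length (and a single-exponential survival fit of the
    run-length distribution), mean speed, and — when ``observation =
    (n_sites, total_time)`` is given — the run frequency per site per
    second.  Standard errors are seeded bootstrap (``n_boot`` resamples).
    """
    if not records:
        raise ValueError("run_statistics requires at least one record")
    rng = np.random.default_rng(seed)
    lengths = np.array([r.run_length for r in records], dtype=float)
    speeds = np.array([abs(r.mean_velocity) for r in records], dtype=float)

    def expfit_mean(x: np.ndarray) -> float:
        """Least-squares single-exponential fit of the empirical survival curve."""
        x = np.sort(x[x > 0])
        if x.size < 3:
            return float(np.mean(x)) if x.size else 0.0
        surv = 1.0 - (np.arange(1, x.size + 1) - 0.5) / x.size
        # linear fit of log-survival through the origin: log S = -x / lam
        lam = -np.sum(x * x) / np.sum(x * np.log(surv))
        return float(lam)

    boots_len = np.empty(n_boot)
    boots_vel = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(len(records), size=len(records))
        boots_len[i] = lengths[idx].mean()
        boots_vel[i] = speeds[idx].mean()
    out = {
        "mean_run_length_nm": float(lengths.mean()),
        "run_length_se_nm": float(boots_len.std(ddof=1)),
        "expfit_run_length_nm": expfit_mean(lengths),
        "mean_velocity_nm_s": float(speeds.mean()),
        "velocity_se_nm_s": float(boots_vel.std(ddof=1)),
        "n_runs": float(len(records)),
    }
    if observation is not None:
        n_sites, total_time = observation
        out["run_frequency_per_site_s"] = len(records) / (n_sites * total_time)
    return out


def calibrate_assembly_scale(
    kinesin: MotorParams,
    dynein: MotorParams,
    map_params: MAPParams,
    n_trials: int = 500,
    seed: int = 0,
    target_plus_fraction: float = 0.20,
    **kwargs,
) -> float:
    """Scale on the kinesin frequency fixing P(plus) at 0 nM MAP7.

    The tug-of-war weighting is interpretive, so the kinesin arm is
    calibrated once against the undecorated-lattice measurement (80%
    minus-end, i.e. 20% plus-end) and the same scale is reused at every
    other concentration.
    """
    rng = np.random.default_rng(seed)
    f_k = run_frequency(kinesin, map_params, 0.0, n_trials, rng, **kwargs).frequency
    f_d = run_frequency(dynein, map_params, 0.0, n_trials, rng, **kwargs).frequency
    if f_k <= 0 or f_d <= 0:
        raise ValueError("both motors need nonzero baseline frequency to calibrate")
    return (target_plus_fraction / (1.0 - target_plus_fraction)) * f_d / f_k


def assembly_direction(
    kinesin: MotorParams,
    dynein: MotorParams,
    map_params: MAPParams,
    concentration: float,
    n_assemblies: int = 200,
    seed: int = 0,
    kinesin_scale: float = 1.0,
    n_trials: int = 500,
    **kwargs,
) -> dict[str, float]:
    """Fraction of kinesin-dynein assemblies moving to the plus end.

    Each assembly's direction is one Bernoulli draw with
    P(plus) = f_k / (f_k + f_d), the two motors' run frequencies at the
    given MAP7 concentration (kinesin scaled by the 0-nM calibration).
    """
    if n_assemblies < 1:
        raise ValueError("n_assemblies must be >= 1")
    rng = np.random.default_rng(seed)
    f_k = kinesin_scale * run_frequency(
        kinesin, map_params, concentration, n_trials, rng, **kwargs
    ).frequency
    f_d = run_frequency(dynein, map_params, concentration, n_trials, rng, **kwargs).frequency
    if f_k + f_d <= 0:
        raise ValueError("both motor frequencies are zero; direction undefined")
    p_plus = f_k / (f_k + f_d)
    draws = rng.random(n_assemblies) < p_plus
    return {
        "p_plus": p_plus,
        "fraction_plus": float(draws.mean()),
        "fraction_minus": float(1.0 - draws.mean()),
        "n_assemblies": float(n_assemblies),
    }
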