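"""Motor run simulation: stepping statistics, obstacles, tethered diffusion."""

from dataclasses import replace

import numpy as np
import pytest

from tetherwalk import (
    EMPTY,
    KINESIN,
    LatticeGeometry,
    LatticeState,
    MotorParams,
    RunRecord,
    assembly_direction,
    decorate_equilibrium,
    equilibrium_occupancy,
    map_preset,
    motor_preset,
    run_frequency,
    run_statistics,
    simulate_run,
    tether_defaults,
)
from tetherwalk.motors import TETHER_JUMP


@pytest.fixture
def k560():
    return motor_preset("K560")


@pytest.fixture
def ddr():
    return motor_preset("DDR")


def _bare_run(motor, seed, t_max=2.0, n_sites=600):
    state = LatticeState.empty(LatticeGeometry(n_sites=n_sites))
    return simulate_run(state, motor, tether_defaults(), map_preset("FL_MAP7"),
                        0.0, seed=seed, start_site=(6, 50), t_max=t_max)


def test_mean_drift_matches_per_step_expectation(k560):
    """On an empty lattice the mean on-axis advance per productive step is
    16 nm x (p_forward - p_backward); Monte-Carlo mean vs closed form."""
    motor = replace(k560, k_detach0=0.0)
    rng = np.random.default_rng(0)
    disp, steps = 0.0, 0
    per_run = []
    for _ in range(200):
        rec = _bare_run(motor, rng)
        x = rec.positions()[:, 0]
        disp += x[-1] - x[0]
        steps += rec.n_productive_steps
        per_run.append((x[-1] - x[0]) / max(rec.n_productive_steps, 1))
    expected = 16.0 * (motor.p_forward0 - motor.p_back0)
    se = np.std(per_run) / np.sqrt(len(per_run))
    assert disp / steps == pytest.approx(expected, abs=3 * se)


def test_start_site_must_be_empty(k560):
    state = LatticeState.empty(LatticeGeometry())
    state.occupy((6, 150), KINESIN)
    with pytest.raises(ValueError):
        simulate_run(state, k560, start_site=(6, 150))


def test_lattice_restored_after_run(k560, fl_map7, rng):
    state = LatticeState.empty(LatticeGeometry(n_sites=200))
    decorate_equilibrium(state, fl_map7, 111.0, rng)
    simulate_run(state, k560, tether_defaults(), fl_map7, 111.0, seed=rng,
                 start_site=tuple(np.argwhere(state.occupancy == EMPTY)[0]), t_max=5.0)
    assert not np.any(state.occupancy == KINESIN)


def test_saturated_lattice_without_tether_gives_no_steps():
    """A motor that cannot be tethered makes no progress on a fully
    MAP7-saturated lattice and detaches without a single productive step."""
    motor = motor_preset("K490")  # no MAP7-binding stalk
    mtbd = map_preset("MTBD_only")
    state = LatticeState.empty(LatticeGeometry(n_sites=200))
    state.occupancy[:] = 1  # MAP7 everywhere
    state.occupancy[6, 100] = 0
    rec = simulate_run(state, motor, tether_defaults(), mtbd, 1e9,
                       seed=3, start_site=(6, 100), t_max=500.0, live_exchange=False)
    assert rec.n_productive_steps == 0
    assert rec.end_tag == "DETACH"


def test_mtbd_decoration_stalls_kinesin_and_atp_speeds_dissociation(k560):
    """On MTBD-only decoration kinesin is stuck (pausing at obstacles) and
    dissociates faster when catalytic cycling is faster."""
    mtbd = map_preset("MTBD_only")
    rng = np.random.default_rng(4)
    durations = {}
    for label, k_step in [("limiting", 1.0), ("saturating", 50.0)]:
        motor = replace(k560, k_step=k_step)
        outs = []
        for _ in range(100):
            state = LatticeState.empty(LatticeGeometry(n_sites=200))
            decorate_equilibrium(state, mtbd, 2000.0, rng)
            empties = np.argwhere(state.occupancy == EMPTY)
            site = tuple(empties[rng.integers(len(empties))])
            rec = simulate_run(state, motor, tether_defaults(), mtbd, 2000.0,
                               seed=rng, start_site=site, t_max=1000.0)
            outs.append(rec.duration)
        durations[label] = np.mean(outs)
    assert durations["saturating"] < durations["limiting"] / 5


def test_run_length_monotone_without_tethering(rng):
    """Without the projection-domain tether, MAP7 can only shorten runs."""
    motor = motor_preset("K490")
    mp = map_preset("FL_MAP7")
    means = []
    for c in [0.0, 50.0, 200.0]:
        lengths = []
        for _ in range(150):
            state = LatticeState.empty(LatticeGeometry(n_sites=600))
            decorate_equilibrium(state, mp, c, rng)
            empties = np.argwhere(state.occupancy[:, 50:51] == EMPTY)
            if len(empties) == 0:
                continue
            site = (int(empties[0][0]), 50)
            rec = simulate_run(state, motor, tether_defaults(), mp, c,
                               seed=rng, start_site=site, t_max=20.0)
            lengths.append(rec.run_length)
        means.append((np.mean(lengths), np.std(lengths) / np.sqrt(len(lengths))))
    for (m_lo, se_lo), (m_hi, se_hi) in zip(means[1:], means[:-1]):
        assert m_lo < m_hi + 3 * np.hypot(se_lo, se_hi)


def test_velocity_decreases_with_map7(k560, rng):
    """Pausing at MTBD obstacles slows kinesin even at low MAP7."""
    mp = map_preset("FL_MAP7")
    vels = []
    for c in [0.0, 50.0]:
        v = []
        for _ in range(150):
            state = LatticeState.empty(LatticeGeometry(n_sites=600))
            decorate_equilibrium(state, mp, c, rng)
            if state.occupancy[6, 50] != EMPTY:
                continue
            rec = simulate_run(state, k560, tether_defaults(), mp, c,
                               seed=rng, start_site=(6, 50), t_max=3.0)
            if rec.duration > 0.2:
                v.append(rec.mean_velocity)
        vels.append(np.mean(v))
    assert vels[1] < vels[0]


def test_tether_jump_reach_bound_and_band(rng):
    """Tether jumps stay within twice the reach (anchor within reach of the
    motor, rebind within reach of the anchor) and populate the 16-64 nm
    on-axis displacement band at high decoration."""
    motor = motor_preset("K560_limiting_ATP")
    mp = map_preset("FL_MAP7")
    tether = tether_defaults()
    jumps = []
    for _ in range(150):
        state = LatticeState.empty(LatticeGeometry(n_sites=400))
        decorate_equilibrium(state, mp, 1000.0, rng)
        free = np.flatnonzero(state.occupancy[:, 50] == EMPTY)
        if free.size == 0:
            continue
        rec = simulate_run(state, motor, tether, mp, 1000.0, seed=rng,
                           start_site=(int(free[0]), 50), t_max=60.0)
        pos = rec.positions()
        last_bound = pos[0]
        for i, tag in enumerate(rec.tags):
            if tag in ("STEP_F", "STEP_B", "STEP_S"):
                last_bound = pos[i]
            elif tag == TETHER_JUMP:
                jumps.append(pos[i] - last_bound)
                last_bound = pos[i]
    jumps = np.array(jumps)
    assert len(jumps) > 50
    dist = np.hypot(jumps[:, 0], jumps[:, 1])
    assert dist.max() <= 2 * tether.reach_nm + 16.0 + 1e-9
    in_band = (np.abs(jumps[:, 0]) >= 16.0) & (np.abs(jumps[:, 0]) <= 64.0)
    assert in_band.mean() > 0.2


def test_event_sequence_reproducible_given_seed(k560, fl_map7):
    recs = []
    for _ in range(2):
        state = LatticeState.empty(LatticeGeometry(n_sites=300))
        decorate_equilibrium(state, fl_map7, 111.0, np.random.default_rng(11))
        site = tuple(int(v) for v in np.argwhere(state.occupancy == EMPTY)[100])
        recs.append(simulate_run(state, k560, tether_defaults(), fl_map7, 111.0,
                                 seed=99, start_site=site, t_max=5.0))
    assert recs[0].times == recs[1].times
    assert recs[0].sites == recs[1].sites
    assert recs[0].tags == recs[1].tags


class TestRunFrequency:
    def test_zero_map7_baseline(self, k560):
        res = run_frequency(k560, map_preset("FL_MAP7"), 0.0, n_trials=200, seed=0,
                            t_max=5.0)
        assert res.landing_rate == pytest.approx(k560.k_land_basal)
        assert 0.8 < res.completion_prob <= 1.0
        assert res.frequency == pytest.approx(res.landing_rate * res.completion_prob)

    def test_dynein_completion_near_half_at_ic50(self, ddr, fl_map7):
        """Obstacle-clearance survival: at theta = IC50/(IC50+K_D) = 0.0826 an
        8-site clearance requirement halves the completion probability
        ((1-theta)^8 = 0.50; the simulated criterion tracks that closed form)."""
        res = run_frequency(ddr, fl_map7, 10.0, n_trials=1500, seed=1, t_max=5.0)
        oracle = (1 - equilibrium_occupancy(fl_map7, 10.0)) ** 8
        assert oracle == pytest.approx(0.50, abs=0.01)
        assert res.completion_prob == pytest.approx(oracle, abs=0.08)

    def test_biphasic_nonmonotone_with_tether_and_recruitment(self, k560, fl_map7):
        """The central claim: run frequency rises at intermediate MAP7 and
        falls below both endpoints at saturation."""
        rng = np.random.default_rng(5)
        f = {c: run_frequency(k560, fl_map7, c, n_trials=150, seed=rng, t_max=5.0).frequency
             for c in (0.0, 30.0, 1000.0)}
        assert f[30.0] > f[0.0]
        assert f[30.0] > f[1000.0]


class TestRunStatistics:
    @staticmethod
    def _straight_record(n_sites_travelled, duration, geometry):
        rec = RunRecord(geometry=geometry)
        rec.append(0.0, (6, 0), "LAND")
        rec.append(duration, (6, n_sites_travelled), "STEP_F")
        return rec

    def test_velocity_of_single_run(self, geometry):
        rec = self._straight_record(200, 2.0, geometry)  # 1600 nm in 2 s
        stats = run_statistics([rec], n_boot=10)
        assert stats["mean_velocity_nm_s"] == pytest.approx(800.0)

    def test_exponential_run_length_recovery(self, rng):
        """Survival-curve fit recovers the mean of exponential run lengths."""
        geometry = LatticeGeometry(n_sites=2000)
        lengths = rng.exponential(1000.0, size=500)
        recs = [self._straight_record(max(int(x / 8), 1), 1.0, geometry) for x in lengths]
        stats = run_statistics(recs, n_boot=200, seed=0)
        se = 1000.0 / np.sqrt(500)
        assert stats["expfit_run_length_nm"] == pytest.approx(np.mean(lengths), abs=3 * se)
        assert stats["mean_run_length_nm"] == pytest.approx(np.mean(lengths), abs=8)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            run_statistics([])


class TestAssemblyDirection:
    def test_pure_kinesin_when_dynein_inactive(self, k560, fl_map7):
        dead_dynein = replace(motor_preset("DDR"), k_land_basal=0.0)
        out = assembly_direction(k560, dead_dynein, fl_map7, 0.0, n_assemblies=50,
                                 seed=0, n_trials=100, t_max=5.0)
        assert out["fraction_plus"] == 1.0

    def test_both_dead_raises(self, fl_map7):
        dead_k = replace(motor_preset("K560"), k_land_basal=0.0)
        dead_d = replace(motor_preset("DDR"), k_land_basal=0.0)
        with pytest.raises(ValueError):
            assembly_direction(dead_k, dead_d, fl_map7, 0.0, n_assemblies=10,
                               seed=0, n_trials=50, t_max=5.0)


def test_direction_probabilities_must_sum_to_one():
    with pytest.raises(ValueError):
        MotorParams(p_forward0=0.9, p_side0=0.2, p_back0=0.03)
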