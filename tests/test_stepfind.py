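"""Changepoint step finder: recovery, false positives, the exact-DP oracle,
and direction classification."""

import numpy as np
import pandas as pd
import pytest

from tetherwalk import (
    DEFAULT_PENALTY,
    StepThresholds,
    Trajectory,
    classify_steps,
    find_steps,
    step_size_histogram,
)
from tetherwalk.stepfind import greedy_changepoints, robust_noise_sd

from helpers import dp_changepoints, staircase


class TestGreedyChangepoints:
    def test_noiseless_staircase_recovered_exactly(self):
        traj = staircase(11, 10)
        table = find_steps(traj)
        assert len(table) == 10
        assert np.allclose(table.steps.dx_nm, 16.0)
        assert np.allclose(table.steps.dy_nm, 0.0)
        assert list(table.steps.frame) == [10 * k for k in range(1, 11)]

    def test_flat_noisy_trace_false_positive_rate_below_5pct(self):
        """Penalty calibration: <5% of flat 2-nm-noise traces yield any step."""
        rng = np.random.default_rng(0)
        false_pos = 0
        for _ in range(100):
            z = rng.normal(0, 2.0, 200)
            false_pos += bool(greedy_changepoints(z, DEFAULT_PENALTY))
        assert false_pos < 5

    def test_16nm_steps_recovered_with_noise(self):
        """2-nm localization noise, 10-frame dwells: mean |dx| within 1 nm of
        16 and >=95% of true changepoints found within one frame."""
        rng = np.random.default_rng(1)
        hits, total, sizes = 0, 0, []
        for _ in range(50):
            traj = staircase(12, 10, noise_sd=2.0, rng=rng)
            table = find_steps(traj)
            sizes.extend(table.steps.dx_nm)
            found = list(table.steps.frame)
            for true_cp in (10 * k for k in range(1, 12)):
                total += 1
                hits += any(abs(f - true_cp) <= 1 for f in found)
        assert abs(np.mean(sizes) - 16.0) < 1.0
        assert hits / total >= 0.95

    def test_agrees_with_exact_dp_oracle(self):
        """Greedy insertion vs exact DP segmentation at the same model size:
        identical changepoint sets in >=95% of seeded short traces."""
        rng = np.random.default_rng(2)
        agree = trials = 0
        for _ in range(100):
            n_steps = int(rng.integers(1, 6))
            dwell = int(rng.integers(10, 200 // (n_steps + 1)))
            traj = staircase(n_steps + 1, dwell, noise_sd=2.0, rng=rng)
            cps = greedy_changepoints(traj.x, DEFAULT_PENALTY)
            if not cps:
                continue
            oracle = dp_changepoints(traj.x, len(cps))
            trials += 1
            agree += cps == oracle
        assert trials > 80
        assert agree / trials >= 0.95

    def test_residual_variance_matches_injected_noise(self):
        rng = np.random.default_rng(3)
        traj = staircase(12, 20, noise_sd=2.0, rng=rng)
        table = find_steps(traj)
        resid = []
        for _, p in table.plateaus.iterrows():
            seg = traj.x[int(p.start_frame):int(p.end_frame)]
            resid.extend(seg - seg.mean())
        assert np.var(resid) == pytest.approx(4.0, rel=0.2)

    def test_robust_noise_estimate_on_stepping_trace(self):
        rng = np.random.default_rng(4)
        traj = staircase(10, 20, noise_sd=2.0, rng=rng)
        assert robust_noise_sd(traj.x) == pytest.approx(2.0, rel=0.25)

    def test_short_trajectory_rejected(self):
        t = np.arange(5) * 0.1
        with pytest.raises(ValueError):
            find_steps(Trajectory(t, np.zeros(5), np.zeros(5), 0.1))


class TestClassification:
    def make_table(self, rows):
        return pd.DataFrame(rows, columns=["dx_nm", "dy_nm"]).assign(
            t_s=0.0, frame=0, **{"class": ""}
        )

    def test_pure_forward_staircase(self):
        frac = classify_steps(self.make_table([(16.0, 0.0)] * 20))
        assert frac.forward_pct == 100.0
        assert frac.sideways_pct == 0.0 and frac.backward_pct == 0.0

    @pytest.mark.parametrize(
        "dx, dy, expected",
        [
            (16.0, 0.0, "FORWARD"),
            (-16.0, 0.0, "BACKWARD"),
            (0.9, 6.0, "SIDEWAYS"),
            (0.9, -6.0, "SIDEWAYS"),
            (-16.0, 6.0, "BACKWARD"),   # longitudinal retreat wins over lateral
            (40.0, 6.0, "LARGE_JUMP"),  # tethered-diffusion band
            (2.0, 1.0, "FORWARD"),
        ],
    )
    def test_single_step_classes(self, dx, dy, expected):
        table = self.make_table([(dx, dy)])
        classify_steps(table)
        assert table["class"].iloc[0] == expected

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            classify_steps(self.make_table([]))

    def test_invariant_under_global_translation(self):
        """Classification depends only on displacements, so shifting the whole
        trajectory cannot change the fractions."""
        rng = np.random.default_rng(5)
        traj = staircase(12, 10, noise_sd=2.0, rng=rng, dy=6.0)
        shifted = Trajectory(traj.t, traj.x + 1234.5, traj.y - 987.0, 0.1)
        f0 = classify_steps(find_steps(traj))
        f1 = classify_steps(find_steps(shifted))
        assert f0 == f1

    def test_custom_thresholds(self):
        table = self.make_table([(0.5, 5.0)])
        frac = classify_steps(table, StepThresholds(lateral_min=6.0))
        assert frac.sideways_pct == 0.0


class TestStepSizeHistogram:
    def test_single_occupied_bin_at_16(self):
        table = pd.DataFrame({"dx_nm": [16.0] * 30, "dy_nm": [0.0] * 30})
        hist = step_size_histogram(table, bin_nm=4.0)
        assert hist.modal_forward_dx == 16.0
        assert hist.counts_dx.sum() == 30
        occupied = np.flatnonzero(hist.counts_dx)
        assert len(occupied) == 1

    def test_counts_conserved_and_bimodal_mixture(self):
        rng = np.random.default_rng(6)
        dx = np.concatenate([np.full(80, 16.0), rng.uniform(32, 64, 40)])
        table = pd.DataFrame({"dx_nm": dx, "dy_nm": np.zeros_like(dx)})
        hist = step_size_histogram(table, bin_nm=4.0)
        assert hist.counts_dx.sum() == len(dx)
        centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2
        band = (centers >= 30) & (centers <= 66)
        assert hist.counts_dx[band].sum() == 40
        assert hist.modal_forward_dx == 16.0

    def test_invalid_bin_rejected(self):
        with pytest.raises(ValueError):
            step_size_histogram(pd.DataFrame({"dx_nm": [1.0], "dy_nm": [0.0]}), 0.0)


def test_trajectory_requires_uniform_time_grid():
    with pytest.raises(ValueError):
        Trajectory(np.array([0.0, 0.1, 0.5]), np.zeros(3), np.zeros(3), 0.1)
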