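"""Step detection and direction classification for noisy 2D trajectories.

Trajectories are piecewise-constant head positions corrupted by Gaussian
localization noise.  Steps are recovered per coordinate by greedy
chi-square changepoint insertion (Kerssemakers-style): at every iteration
the single split that most reduces the residual sum of squares is placed,
and insertion stops once the best improvement, measured against a robust
noise estimate, falls below a dimensionless penalty.  Changepoints found
independently in the on-axis (x) and off-axis (y) coordinates that fall
within one frame of each other are merged into a single step event, since
a protofilament switch moves both coordinates at once.

Direction classes: a step is BACKWARD when its axial displacement retreats
by at least ``backward_min``; otherwise SIDEWAYS when the lateral
displacement reaches ``lateral_min`` (a protofilament switch); otherwise
LARGE_JUMP when the axial advance exceeds one full 16-nm step plus
tolerance (tethered-diffusion band); otherwise FORWARD.  Longitudinal
classes are resolved before lateral ones, mirroring the separate
longitudinal/sideways tallies of motility assays.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Trajectory",
    "StepTable",
    "StepThresholds",
    "DirectionFractions",
    "find_steps",
    "classify_steps",
    "step_size_histogram",
    "DEFAULT_PENALTY",
]

#: Default chi-square improvement threshold; calibrated so the false-positive
#: rate on flat 2-nm-noise traces stays below 5% (see the step-finder tests).
DEFAULT_PENALTY = 30.0

FORWARD, BACKWARD, SIDEWAYS, LARGE_JUMP = "FORWARD", "BACKWARD", "SIDEWAYS", "LARGE_JUMP"


@dataclass
class Trajectory:
    """Evenly sampled 2D head positions (t s, x on-axis nm, y off-axis nm).

    ``truth`` optionally carries the hidden ground-truth step annotations
    of a synthetic trace (frame, dx, dy, tag) for oracle tests; it is
    written to a sidecar file, never into the analysis input itself.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_interval: float
    noise_sd: float | None = None
    truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time stamps must increase with a constant interval")

    def __len__(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "x_nm": self.x, "y_nm": self.y})

    def to_csv(self, path) -> None:
        """Write the trajectory CSV; ground truth goes to `<stem>.truth.csv`."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        if self.truth is not None:
            self.truth.to_csv(path.with_suffix(".truth.csv"), index=False)

    @classmethod
    def from_csv(cls, path, load_truth: bool = True) -> "Trajectory":
        path = Path(path)
        df = pd.read_csv(path)
        truth_path = path.with_suffix(".truth.csv")
        truth = pd.read_csv(truth_path) if (load_truth and truth_path.exists()) else None
        t = df["t_s"].to_numpy()
        dt = float(t[1] - t[0]) if len(t) >= 2 else 1.0
        return cls(t, df["x_nm"].to_numpy(), df["y_nm"].to_numpy(), dt, truth=truth)


@dataclass(frozen=True)
class StepThresholds:
    """Classification thresholds in nm (config-exposed; defaults as documented)."""

    lateral_min: float = 4.0
    backward_min: float = 8.0
    large_jump_min: float = 20.0  # 16 nm + 4 nm tolerance


@dataclass
class StepTable:
    """Detected steps and the plateau partition they come from.

    ``steps`` rows: (t_step s, frame, dx nm, dy nm, class); ``plateaus``
    rows: (start_frame, end_frame, x_mean, y_mean, dwell_s).  Plateaus
    partition the trajectory, so the dx column telescopes to the
    difference between the last and first plateau levels.
    """

    steps: pd.DataFrame
    plateaus: pd.DataFrame

    def __len__(self) -> int:
        return len(self.steps)

    def to_csv(self, path) -> None:
        self.steps.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "StepTable":
        return cls(pd.read_csv(path), pd.DataFrame())


def robust_noise_sd(z: np.ndarray) -> float:
    """Noise sd from the median absolute successive difference.

    Steps are sparse among frame-to-frame differences, so the median |dz|
    estimates sqrt(2) sigma x 0.6745 robustly even on stepping traces.
    """
    dz = np.diff(z)
    if dz.size == 0:
        return 0.0
    return float(np.median(np.abs(dz - np.median(dz))) / 0.6745 / np.sqrt(2.0))


def _best_split(z: np.ndarray, csum: np.ndarray, lo: int, hi: int, min_size: int):
    """Best single changepoint in z[lo:hi]; returns (gain, split_index) or (0, -1).

    The gain is the residual-sum-of-squares reduction of splitting the
    segment into [lo, k) and [k, hi) at the best k:
    gain = n1*n2/(n1+n2) * (mean1 - mean2)^2.
    """
    n = hi - lo
    if n < 2 * min_size:
        return 0.0, -1
    total = csum[hi] - csum[lo]
    k = np.arange(lo + min_size, hi - min_size + 1)
    n1 = k - lo
    n2 = hi - k
    left = csum[k] - csum[lo]
    mean1 = left / n1
    mean2 = (total - left) / n2
    gain = n1 * n2 / (n1 + n2) * (mean1 - mean2) ** 2
    i = int(np.argmax(gain))
    return float(gain[i]), int(k[i])


def greedy_changepoints(
    z: np.ndarray, penalty: float = DEFAULT_PENALTY, min_size: int = 2
) -> list[int]:
    """Changepoint frames of a 1D piecewise-constant signal, greedy insertion.

    A changepoint at frame k means the level changes between frames k-1 and
    k.  Insertion stops when the best remaining split improves the residual
    chi-square by less than ``penalty`` noise variances.  On a noiseless
    trace the robust noise estimate vanishes and every genuine level change
    is recovered exactly (the threshold floor is tied to machine precision).
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    sigma2 = robust_noise_sd(z) ** 2
    # floor keeps zero-noise traces from chasing float rounding in the cumsums
    scale = 1.0 + float(np.max(np.abs(z - z.mean()))) if n else 1.0
    threshold = max(penalty * sigma2, (1e-7 * scale) ** 2)
    csum = np.concatenate([[0.0], np.cumsum(z)])
    # cache each segment's best split
    best: dict[tuple[int, int], tuple[float, int]] = {
        (0, n): _best_split(z, csum, 0, n, min_size)
    }
    cps: list[int] = []
    while True:
        seg, (gain, split) = max(best.items(), key=lambda kv: kv[1][0])
        if split < 0 or gain <= threshold:
            break
        lo, hi = seg
        del best[seg]
        best[(lo, split)] = _best_split(z, csum, lo, split, min_size)
        best[(split, hi)] = _best_split(z, csum, split, hi, min_size)
        cps.append(split)
    cps = sorted(cps)
    # local refinement: re-optimize each changepoint between its neighbours
    # (greedy insertion can land one frame off; this coordinate descent
    # strictly reduces the residual sum of squares until stable)
    for _ in range(10):
        moved = False
        bounds = [0] + cps + [n]
        for i in range(1, len(bounds) - 1):
            _, split = _best_split(z, csum, bounds[i - 1], bounds[i + 1], min_size)
            if split >= 0 and split != bounds[i]:
                bounds[i] = split
                moved = True
        cps = sorted(bounds[1:-1])
        if not moved:
            break
    return cps


def _segment_means(z: np.ndarray, bounds: list[int]) -> np.ndarray:
    return np.array([z[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])])


def find_steps(
    traj: Trajectory,
    penalty: float = DEFAULT_PENALTY,
    thresholds: StepThresholds | None = None,
    merge_frames: int = 0,
    min_size: int = 2,
) -> StepTable:
    """Detect steps in a 2D trajectory and build the step/plateau tables.

    x and y are segmented independently with the same penalty; changepoints landing in the same inter-frame gap (within ``merge_frames``
    frames of each other) are merged into one step event (the x frame wins).  Step vectors (dx, dy) are differences of adjacent
    plateau means in the merged segmentation, so a step carries both its
    axial and lateral displacement even when only one coordinate triggered
    detection.
    """
    if len(traj) < 10:
        raise ValueError("trajectory too short for step finding (need >= 10 frames)")
    thresholds = thresholds or StepThresholds()
    cps_x = greedy_changepoints(traj.x, penalty, min_size)
    cps_y = greedy_changepoints(traj.y, penalty, min_size)
    merged = list(cps_x)
    for cy in cps_y:
        if not any(abs(cy - cx) <= merge_frames for cx in cps_x):
            merged.append(cy)
    merged = sorted(set(merged))
    bounds = [0] + merged + [len(traj)]
    x_means = _segment_means(traj.x, bounds)
    y_means = _segment_means(traj.y, bounds)
    dwell = np.diff(bounds) * traj.frame_interval
    plateaus = pd.DataFrame(
        {
            "start_frame": bounds[:-1],
            "end_frame": bounds[1:],
            "x_mean": x_means,
            "y_mean": y_means,
            "dwell_s": dwell,
        }
    )
    dx = np.diff(x_means)
    dy = np.diff(y_means)
    steps = pd.DataFrame(
        {
            "t_s": traj.t[merged] if merged else np.array([], dtype=float),
            "frame": merged,
            "dx_nm": dx,
            "dy_nm": dy,
        }
    )
    steps["class"] = [_classify_one(a, b, thresholds) for a, b in zip(dx, dy)]
    return StepTable(steps, plateaus)


def _classify_one(dx: float, dy: float, th: StepThresholds) -> str:
    """Longitudinal classes first: a net retreat is backward whatever its lateral
    component, and a displacement beyond one full step is a (forward) jump of the
    tethered-diffusion band; only the remainder is scored by its lateral shift."""
    if dx <= -th.backward_min:
        return BACKWARD
    if dx > th.large_jump_min:
        return LARGE_JUMP
    if abs(dy) >= th.lateral_min:
        return SIDEWAYS
    return FORWARD


@dataclass(frozen=True)
class DirectionFractions:
    """Direction composition of a step table (percentages of all steps)."""

    forward_pct: float
    backward_pct: float
    sideways_pct: float
    large_jump_count: int
    n_steps: int


def classify_steps(
    steps: StepTable | pd.DataFrame, thresholds: StepThresholds | None = None
) -> DirectionFractions:
    """(Re)classify steps with the given thresholds and tally direction fractions."""
    df = steps.steps if isinstance(steps, StepTable) else steps
    if len(df) == 0:
        raise ValueError("cannot classify an empty step table")
    thresholds = thresholds or StepThresholds()
    cls = np.array(
        [_classify_one(a, b, thresholds) for a, b in zip(df["dx_nm"], df["dy_nm"])]
    )
    df["class"] = cls
    n = len(cls)
    return DirectionFractions(
        forward_pct=100.0 * np.mean((cls == FORWARD) | (cls == LARGE_JUMP)),
        backward_pct=100.0 * np.mean(cls == BACKWARD),
        sideways_pct=100.0 * np.mean(cls == SIDEWAYS),
        large_jump_count=int(np.sum(cls == LARGE_JUMP)),
        n_steps=n,
    )


@dataclass
class StepHistogram:
    """Signed-displacement histograms with 16-nm-centred bins."""

    bin_edges: np.ndarray
    counts_dx: np.ndarray
    counts_dy: np.ndarray
    modal_forward_dx: float
    modal_abs_dx: float


def step_size_histogram(steps: StepTable | pd.DataFrame, bin_nm: float = 4.0) -> StepHistogram:
    """Histogram dx and dy with bins centred on multiples of ``bin_nm``.

    Centring the bins (edges at (k - 1/2) * bin) keeps the canonical 16-nm
    step in the interior of a bin rather than on an edge.  The modal
    forward step is the centre of the most occupied dx > 0 bin.
    """
    if bin_nm <= 0:
        raise ValueError("bin width must be positive")
    df = steps.steps if isinstance(steps, StepTable) else steps
    dx = df["dx_nm"].to_numpy()
    dy = df["dy_nm"].to_numpy()
    lo = np.floor(min(dx.min(), dy.min(), -bin_nm) / bin_nm - 0.5)
    hi = np.ceil(max(dx.max(), dy.max(), bin_nm) / bin_nm + 0.5)
    edges = (np.arange(lo, hi + 1) - 0.5) * bin_nm
    counts_dx, _ = np.histogram(dx, edges)
    counts_dy, _ = np.histogram(dy, edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    fwd = centers > 0
    modal_fwd = float(centers[fwd][np.argmax(counts_dx[fwd])]) if fwd.any() else np.nan
    abs_edges = (np.arange(0, hi + 1) - 0.5) * bin_nm
    abs_counts, _ = np.histogram(np.abs(dx), abs_edges)
    abs_centers = (abs_edges[:-1] + abs_edges[1:]) / 2.0
    modal_abs = float(abs_centers[np.argmax(abs_counts)])
    return StepHistogram(edges, counts_dx, counts_dy, modal_fwd, modal_abs)
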