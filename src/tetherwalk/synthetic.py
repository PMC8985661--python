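"""Synthetic data generators for every analysis stage.

These emulate the statistical structure of single-molecule motility data:
piecewise-constant stepping traces sampled at a fixed frame interval with
additive Gaussian localization noise, titration tables with multiplicative
intensity noise and replicate structure, and kymographs rasterized from
run records.  Ground truth (the hidden changepoints of a trace) is carried
as a sidecar annotation so oracle tests can score detection without the
truth ever entering the analysis input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doseresponse import biphasic_hill, hill, langmuir_inhibition
from .motors import LAND, STEP_B, STEP_F, STEP_S, TETHER_JUMP, RunRecord
from .stepfind import Trajectory

__all__ = ["NoiseModel", "make_trajectory", "make_titration", "make_kymograph",
           "write_kymograph_tiff"]

_POSITION_TAGS = {STEP_F, STEP_B, STEP_S, TETHER_JUMP}


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise parameters of the emulated assays.

    ``localization_sd`` is the per-frame Gaussian localization error in nm
    (~2 nm for nanometer-precision tracking); ``intensity_cv`` the
    fractional multiplicative noise on titration intensities.
    """

    localization_sd: float = 2.0
    frame_interval: float = 0.1
    intensity_cv: float = 0.1

    def __post_init__(self) -> None:
        if self.localization_sd < 0 or self.intensity_cv < 0:
            raise ValueError("noise magnitudes must be nonnegative")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")


def make_trajectory(
    run: RunRecord,
    noise: NoiseModel | None = None,
    seed: int | np.random.Generator = 0,
    t_max: float | None = None,
) -> Trajectory:
    """Sample a run's labelled-head position into a noisy, evenly framed trace.

    The head position is piecewise constant between binding events (tether
    excursions are not spatially resolved); independent Gaussian noise of
    sd ``localization_sd`` is added to x and y.  The returned trajectory
    carries the ground-truth step annotations (frame, dx, dy, tag) of all
    position-changing events inside the sampled window.
    """
    if not run.times:
        raise ValueError("cannot sample an empty run record")
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_end = run.times[-1] if t_max is None else min(run.times[-1], t_max)
    n_frames = max(int(np.floor(t_end / noise.frame_interval)) + 1, 1)
    t = np.arange(n_frames) * noise.frame_interval

    times = np.asarray(run.times)
    pos = run.positions()
    # keep only events that change or define the bound position
    keep = [i for i, tag in enumerate(run.tags) if tag in _POSITION_TAGS or tag == LAND]
    times_k = times[keep]
    pos_k = pos[keep]
    idx = np.clip(np.searchsorted(times_k, t, side="right") - 1, 0, len(keep) - 1)
    x = pos_k[idx, 0].copy()
    y = pos_k[idx, 1].copy()
    if noise.localization_sd > 0:
        x += rng.normal(0.0, noise.localization_sd, n_frames)
        y += rng.normal(0.0, noise.localization_sd, n_frames)

    truth_rows = []
    for j, i in enumerate(keep):
        if run.tags[i] not in _POSITION_TAGS or times_k[j] > t[-1]:
            continue
        truth_rows.append(
            {
                "t_s": times_k[j],
                "frame": int(np.ceil(times_k[j] / noise.frame_interval - 1e-9)),
                "dx_nm": pos_k[j, 0] - pos_k[j - 1, 0],
                "dy_nm": pos_k[j, 1] - pos_k[j - 1, 1],
                "tag": run.tags[i],
            }
        )
    truth = pd.DataFrame(truth_rows,
                         columns=["t_s", "frame", "dx_nm", "dy_nm", "tag"])
    return Trajectory(t, x, y, noise.frame_interval,
                      noise_sd=noise.localization_sd, truth=truth)


_GENERATORS = {"hill": hill, "biphasic": biphasic_hill, "langmuir": langmuir_inhibition}


def make_titration(
    generator_model: str,
    params: dict[str, float],
    concentrations,
    noise: NoiseModel | None = None,
    n_per_point: int = 10,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Replicated titration table from a named dose-response curve.

    Draws ``n_per_point`` replicates per concentration with multiplicative
    Gaussian noise of coefficient of variation ``intensity_cv`` and
    reports mean, sd and n per concentration — the replicate structure of
    an intensity-vs-concentration experiment.
    """
    if n_per_point < 2:
        raise ValueError("n_per_point must be >= 2")
    concentrations = np.asarray(list(concentrations), dtype=float)
    if concentrations.size < 1:
        raise ValueError("need at least one concentration")
    noise = noise or NoiseModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    curve_fn = _GENERATORS[generator_model]
    truth = np.asarray(curve_fn(concentrations, **params), dtype=float)
    rows = []
    for c, mu in zip(concentrations, truth):
        reps = mu * (1.0 + noise.intensity_cv * rng.standard_normal(n_per_point))
        rows.append(
            {
                "concentration_nM": c,
                "response": float(np.mean(reps)),
                "sd": float(np.std(reps, ddof=1)),
                "n": n_per_point,
            }
        )
    return pd.DataFrame(rows)


def make_kymograph(
    records: list[RunRecord],
    pixel_nm: float = 80.0,
    line_interval_s: float = 0.5,
    duration_s: float | None = None,
) -> np.ndarray:
    """Rasterize on-axis positions vs time into a kymograph array.

    Rows are time lines, columns are on-axis pixels spanning the lattice;
    each motor bound at a line time adds one count to its pixel.
    Deterministic given its inputs.
    """
    if pixel_nm <= 0 or line_interval_s <= 0:
        raise ValueError("pixel size and line interval must be positive")
    if not records:
        raise ValueError("need at least one run record")
    length_nm = records[0].geometry.n_sites * records[0].geometry.axial_spacing
    n_px = int(np.ceil(length_nm / pixel_nm))
    t_end = duration_s if duration_s is not None else max(r.times[-1] for r in records)
    n_lines = max(int(np.ceil(t_end / line_interval_s)) + 1, 1)
    img = np.zeros((n_lines, n_px), dtype=np.uint16)
    line_t = np.arange(n_lines) * line_interval_s
    for rec in records:
        times = np.asarray(rec.times)
        pos = rec.positions()
        keep = [i for i, tag in enumerate(rec.tags) if tag in _POSITION_TAGS or tag == LAND]
        tk, pk = times[keep], pos[keep]
        live = (line_t >= times[0]) & (line_t <= times[-1])
        idx = np.clip(np.searchsorted(tk, line_t[live], side="right") - 1, 0, len(keep) - 1)
        px = np.clip((pk[idx, 0] / pixel_nm).astype(int), 0, n_px - 1)
        np.add.at(img, (np.nonzero(live)[0], px), 1)
    return img


def write_kymograph_tiff(img: np.ndarray, path) -> None:
    """Write a kymograph as 16-bit grayscale TIFF."""
    import tifffile

    tifffile.imwrite(path, img.astype(np.uint16))
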