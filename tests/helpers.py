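"""Shared test oracles: synthetic staircases and the exact-DP changepoint solver."""

import numpy as np

from tetherwalk import Trajectory


def staircase(n_levels, dwell, step=16.0, noise_sd=0.0, rng=None, dy=None):
    x = np.repeat(np.arange(n_levels) * step, dwell).astype(float)
    y = np.repeat(np.arange(n_levels) * dy, dwell).astype(float) if dy else np.zeros_like(x)
    if noise_sd and rng is not None:
        x = x + rng.normal(0, noise_sd, x.size)
        y = y + rng.normal(0, noise_sd, y.size)
    t = np.arange(x.size) * 0.1
    return Trajectory(t, x, y, 0.1, noise_sd=noise_sd or None)


def dp_changepoints(z, n_changepoints, min_size=2):
    """Exact minimum-RSS segmentation with a fixed number of changepoints.

    O(n^2 k) dynamic programme over segment cost C[i][j] = RSS of z[i:j];
    the independent oracle for the greedy insertion heuristic.
    """
    z = np.asarray(z, dtype=float)
    n = z.size
    csum = np.concatenate([[0.0], np.cumsum(z)])
    csq = np.concatenate([[0.0], np.cumsum(z * z)])

    def cost(i, j):
        s = csum[j] - csum[i]
        return (csq[j] - csq[i]) - s * s / (j - i)

    k_max = n_changepoints + 1
    inf = np.inf
    best = np.full((k_max + 1, n + 1), inf)
    arg = np.zeros((k_max + 1, n + 1), dtype=int)
    for j in range(min_size, n + 1):
        best[1][j] = cost(0, j)
    for k in range(2, k_max + 1):
        for j in range(k * min_size, n + 1):
            for i in range((k - 1) * min_size, j - min_size + 1):
                c = best[k - 1][i] + cost(i, j)
                if c < best[k][j]:
                    best[k][j] = c
                    arg[k][j] = i
    cps = []
    j = n
    for k in range(k_max, 1, -1):
        j = arg[k][j]
        cps.append(j)
    return sorted(cps)
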