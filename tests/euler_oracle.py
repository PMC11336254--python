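"""Brute-force diffusion-path oracle for the first-passage-time law.

Independent of the series-expansion density in the package: absorption
statistics are estimated by direct Euler discretization of the diffusion
(with in-step bridge absorption so the small-dt bias is O(dt)), and
densities by histogram counts.  Only used as a test oracle.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def euler_fpt(rng, n_paths, v, a, z, dt):
    """Simulate n_paths first passages; returns (boundary, time) arrays."""
    bounds = np.empty(n_paths, dtype=np.int8)
    times = np.empty(n_paths, dtype=np.float64)
    sq = math.sqrt(dt)
    for i in range(n_paths):
        x = z
        t = 0.0
        while True:
            xn = x + v * dt + sq * rng.standard_normal()
            t += dt
            if xn >= a:
                bounds[i] = 1
                break
            if xn <= 0.0:
                bounds[i] = 0
                break
            r = rng.random()
            p_up = math.exp(-2.0 * (a - x) * (a - xn) / dt)
            if r < p_up:
                bounds[i] = 1
                break
            if r < p_up + math.exp(-2.0 * x * xn / dt):
                bounds[i] = 0
                break
            x = xn
        times[i] = t - dt / 2.0
    return bounds, times


def density_estimate(bounds, times, boundary, t_center, half_width):
    """Histogram density estimate at one point with its standard error."""
    n = len(bounds)
    in_bin = (bounds == boundary) & (np.abs(times - t_center) < half_width)
    p = in_bin.mean()
    width = 2.0 * half_width
    dens = p / width
    se = math.sqrt(p * (1.0 - p) / n) / width
    return dens, se
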