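"""Two-boundary Wiener diffusion: first-passage-time density and samplers.

The decision process underlying every trial is a one-dimensional diffusion
with drift ``v``, diffusion coefficient ``s`` (fixed at 1 by the usual
scaling convention), absorbing boundaries at 0 and ``a``, and starting
point ``z_rel * a``.  The first-passage-time (FPT) density at each boundary
is *defective*: it integrates to the probability of absorption at that
boundary.  Response times add a non-decision offset ``t0``.

The density has two classical series representations — one that converges
quickly for small normalized times and one for large normalized times.
``wiener_logpdf`` evaluates whichever needs fewer terms for a requested
absolute tolerance (1e-7), following the standard truncation bounds, so the
result is accurate across the whole time axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "DiffusionParams",
    "wiener_logpdf",
    "wiener_pdf",
    "upper_prob",
    "sample_fpt",
]

#: absolute tolerance of the truncated series for the normalized density
SERIES_EPS = 1e-7

LOWER, UPPER = 0, 1


@dataclass(frozen=True)
class DiffusionParams:
    """Parameters of the two-boundary Wiener diffusion.

    v : drift rate (evidence units / s), signed toward the upper boundary.
    a : boundary separation (> 0, evidence units).
    z_rel : relative starting point in (0, 1); 0.5 = unbiased.
    t0 : non-decision time in seconds (>= 0).
    s : diffusion coefficient; fixed at 1.0 by convention.
    """

    v: float
    a: float
    z_rel: float = 0.5
    t0: float = 0.0
    s: float = 1.0

    def __post_init__(self) -> None:
        for name in ("v", "a", "z_rel", "t0", "s"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite diffusion parameter {name!r}")
        if self.a <= 0:
            raise ValueError("boundary separation a must be > 0")
        if not 0 < self.z_rel < 1:
            raise ValueError("relative start z_rel must lie in (0, 1)")
        if self.t0 < 0:
            raise ValueError("non-decision time t0 must be >= 0")
        if self.s <= 0:
            raise ValueError("diffusion coefficient s must be > 0")

    def with_(self, **kw) -> "DiffusionParams":
        return replace(self, **kw)


@njit(cache=True)
def _f0_lower(u: float, w: float) -> float:
    """Normalized lower-boundary FPT density (v=0, a=1, start w) at time u.

    Picks the small-time or large-time expansion by comparing the number of
    terms each needs for absolute accuracy SERIES_EPS.
    """
    if u <= 0.0:
        return 0.0
    # terms needed by the small-time expansion
    if 2.0 * math.sqrt(2.0 * math.pi * u) * SERIES_EPS < 1.0:
        ks = 2.0 + math.sqrt(-2.0 * u * math.log(2.0 * SERIES_EPS * math.sqrt(2.0 * math.pi * u)))
        ks = max(ks, math.sqrt(u) + 1.0)
    else:
        ks = 2.0
    # terms needed by the large-time expansion
    if math.pi * u * SERIES_EPS < 1.0:
        kl = math.sqrt(-2.0 * math.log(math.pi * u * SERIES_EPS) / (math.pi * math.pi * u))
        kl = max(kl, 1.0 / (math.pi * math.sqrt(u)))
    else:
        kl = 1.0 / (math.pi * math.sqrt(u))

    if ks < kl:  # small-time representation
        K = int(math.ceil(ks))
        lo = -(K - 1) // 2
        hi = (K - 1) // 2 + (K - 1) % 2
        acc = 0.0
        for k in range(lo, hi + 1):
            y = w + 2.0 * k
            acc += y * math.exp(-y * y / (2.0 * u))
        return acc / math.sqrt(2.0 * math.pi * u ** 3)
    K = int(math.ceil(kl))
    acc = 0.0
    for k in range(1, K + 1):
        acc += k * math.exp(-k * k * math.pi * math.pi * u / 2.0) * math.sin(k * math.pi * w)
    return math.pi * acc


@njit(cache=True)
def _wfpt_logpdf(t: float, boundary: int, v: float, a: float, w: float, t0: float) -> float:
    """Log FPT density at (t, boundary); -inf for t <= t0 (zero density)."""
    u = t - t0
    if u <= 0.0:
        return -np.inf
    if boundary == 1:  # upper boundary: reflect the process
        v = -v
        w = 1.0 - w
    f0 = _f0_lower(u / (a * a), w)
    if f0 <= 0.0:
        return -np.inf
    return math.log(f0) - 2.0 * math.log(a) - v * a * w - v * v * u / 2.0


def wiener_logpdf(t, boundary, params: DiffusionParams):
    """Log of the defective FPT density at time ``t`` and the given boundary.

    ``boundary`` is ``"upper"``/``"lower"`` (or 1/0).  ``t <= t0`` yields
    ``-inf`` — zero density, not an error — so likelihood code can treat
    impossible response times as rejections.  Accepts scalar or array ``t``.
    """
    b = _coerce_boundary(boundary)
    if params.s != 1.0:
        # rescale to the s = 1 convention: v/s, a/s leave the law unchanged
        params = params.with_(v=params.v / params.s, a=params.a / params.s, s=1.0)
    ts = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.empty(ts.shape, dtype=float)
    for i, ti in enumerate(ts):
        out[i] = _wfpt_logpdf(ti, b, params.v, params.a, params.z_rel, params.t0)
    return out[0] if np.isscalar(t) or np.asarray(t).ndim == 0 else out


def wiener_pdf(t, boundary, params: DiffusionParams):
    """Defective FPT density (natural scale); see :func:`wiener_logpdf`."""
    return np.exp(wiener_logpdf(t, boundary, params))


def _coerce_boundary(boundary) -> int:
    if boundary in ("upper", UPPER, True):
        return UPPER
    if boundary in ("lower", LOWER, False):
        return LOWER
    raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")


def upper_prob(params: DiffusionParams) -> float:
    """Exact probability of absorption at the upper boundary.

    P(upper) = (1 - exp(-2 v z / s^2)) / (1 - exp(-2 v a / s^2)) with
    z = z_rel * a; the driftless limit is z_rel.
    """
    v, a, w, s = params.v, params.a, params.z_rel, params.s
    z = w * a
    x = 2.0 * v / (s * s)
    if abs(x * a) < 1e-9:
        return w
    if -x * a > 700.0:  # strong negative drift: avoid overflow in expm1
        return math.exp(x * (z - a)) * -math.expm1(-x * z) if -x * z < 700.0 else 0.0
    return math.expm1(-x * z) / math.expm1(-x * a)


@njit(cache=True)
def _sample_fpt_kernel(rng, n, v, a, w, t0, dt):
    """Euler scheme with Brownian-bridge absorption between steps.

    The bridge correction accounts for excursions that cross a boundary
    inside a step and return, removing the leading O(sqrt(dt)) bias of the
    naive scheme.
    """
    bounds = np.empty(n, dtype=np.int8)
    times = np.empty(n, dtype=np.float64)
    sq = math.sqrt(dt)
    for i in range(n):
        x = w * a
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
            # bridge probability of having touched either boundary in-step
            p_up = math.exp(-2.0 * (a - x) * (a - xn) / dt)
            p_lo = math.exp(-2.0 * x * xn / dt)
            r = rng.random()
            if r < p_up:
                bounds[i] = 1
                break
            if r < p_up + p_lo:
                bounds[i] = 0
                break
            x = xn
        # absorption happened somewhere inside the last step: use its
        # midpoint, which removes the ~dt/2 upward bias of the full step
        times[i] = t0 + t - dt / 2.0
    return bounds, times


def sample_fpt(params: DiffusionParams, n: int, rng: np.random.Generator, dt: float = 1e-3):
    """Draw ``n`` (boundary, time) pairs from the joint FPT law.

    Returns ``(boundaries, times)`` where boundaries are 1 (upper) / 0
    (lower) and all times exceed ``t0``.  Reproducible for a given ``rng``
    state.  ``dt`` is the Euler step of the bridge-corrected scheme.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    v, a = params.v, params.a
    if params.s != 1.0:
        v, a = v / params.s, a / params.s
    return _sample_fpt_kernel(rng, n, v, a, params.z_rel, params.t0, dt)
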