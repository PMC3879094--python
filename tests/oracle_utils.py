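"""Independent numeric oracles used by the test suite.

The emergence-angle oracle integrates the planar heading ODE

    dx/ds = cos(alpha), dy/ds = sin(alpha), d(alpha)/ds = c

with RK4 from the occlusion point and finds where the path first
reaches distance R from the origin, refining the crossing with
sub-steps and linear interpolation.  It shares no trigonometric
identities with the closed-form implementation under test.
"""

from __future__ import annotations

import numpy as np


def _rk4_step(x, y, a, c, ds):
    # alpha evolves linearly, so the k-stages only differ in alpha
    k1x, k1y = np.cos(a), np.sin(a)
    am = a + c * ds / 2.0
    k2x, k2y = np.cos(am), np.sin(am)
    ae = a + c * ds
    k4x, k4y = np.cos(ae), np.sin(ae)
    x = x + ds / 6.0 * (k1x + 4.0 * k2x + k4x)
    y = y + ds / 6.0 * (k1y + 4.0 * k2y + k4y)
    return x, y, ae


def emergence_angle_oracle(
    curvatures: np.ndarray,
    orientations_deg: np.ndarray,
    radius: float,
    ds: float = 0.05,
    n_sub: int = 50,
) -> np.ndarray:
    """Emergence angles (clockwise degrees) by numeric arc stepping.

    Positive stimulus curvature turns the mathematical heading
    counter-clockwise; clockwise-positive orientation converts to a
    negated mathematical heading (the package's documented convention).
    """
    c = np.asarray(curvatures, dtype=float)
    a = -np.radians(np.asarray(orientations_deg, dtype=float))
    n = len(c)
    x = np.zeros(n)
    y = np.zeros(n)
    # bracket the crossing with coarse exact-order RK4 steps
    px, py, pa = x.copy(), y.copy(), a.copy()
    done = np.zeros(n, dtype=bool)
    bx, by, ba = x.copy(), y.copy(), a.copy()
    s_max = 2.5 * radius
    for _ in range(int(np.ceil(s_max / ds))):
        nx, ny, na = _rk4_step(px, py, pa, c, ds)
        crossed = ~done & (np.hypot(nx, ny) >= radius)
        bx[crossed], by[crossed], ba[crossed] = px[crossed], py[crossed], pa[crossed]
        done |= crossed
        px, py, pa = nx, ny, na
        if done.all():
            break
    if not done.all():
        raise RuntimeError("oracle failed to bracket a crossing")
    # refine within the bracketing step with fine sub-steps
    sub = ds / n_sub
    px, py, pa = bx, by, ba
    fx, fy = np.empty(n), np.empty(n)
    done = np.zeros(n, dtype=bool)
    for _ in range(n_sub + 1):
        nx, ny, na = _rk4_step(px, py, pa, c, sub)
        d0 = np.hypot(px, py)
        d1 = np.hypot(nx, ny)
        crossed = ~done & (d1 >= radius)
        t = np.where(d1 > d0, (radius - d0) / np.maximum(d1 - d0, 1e-300), 0.0)
        fx[crossed] = px[crossed] + t[crossed] * (nx[crossed] - px[crossed])
        fy[crossed] = py[crossed] + t[crossed] * (ny[crossed] - py[crossed])
        done |= crossed
        px, py, pa = nx, ny, na
    if not done.all():
        raise RuntimeError("oracle refinement failed")
    return -np.degrees(np.arctan2(fy, fx))


def ks_statistic_bruteforce(a, b) -> float:
    """Max |ECDF difference| scanned over every support point."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    support = np.unique(np.concatenate([a, b]))
    best = 0.0
    for x in support:
        best = max(best, abs(np.mean(a <= x) - np.mean(b <= x)))
    return best
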