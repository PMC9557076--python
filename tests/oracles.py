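"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by a route deliberately different from the
package implementation (event enumeration, fixed-point iteration, dense
grid search, curve_fit), so agreement is meaningful.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import curve_fit, minimize


def event_list_ti_table(
    offsets,
    rr_series,
    phase_duration_ms,
    acq_window_fraction,
    recovery_beats,
):
    """Brute-force timeline: place every inversion and every per-beat phase
    readout on an absolute time axis and collect, per phase and inversion,
    the first ``recovery_beats`` positive inversion times."""
    rr = list(rr_series)
    min_rr = min(rr)
    n_phases = math.floor(acq_window_fraction * min_rr / phase_duration_ms)
    centers = [(i + 0.5) * phase_duration_ms for i in range(n_phases)]

    def beat_start(m):
        return sum(rr[b % len(rr)] for b in range(m))

    table = []
    for c in centers:
        tis = []
        for off in offsets:
            t_inv = off  # inversion in the trigger beat, offset after R-wave
            got, m = 0, 0
            while got < recovery_beats:
                ti = beat_start(m) + c - t_inv
                if ti > 0:
                    tis.append(ti)
                    got += 1
                m += 1
        table.append(sorted(tis))
    return table


def count_dummy_pulses(rr_ms, acq_window_fraction, tr_ms):
    """Walk the pulse slots from the acquisition-window end to the R-wave."""
    t = acq_window_fraction * rr_ms
    n = 0
    while t + tr_ms <= rr_ms + 1e-9:
        n += 1
        t += tr_ms
    return n


def steady_state_by_iteration(t1_ms, flip_deg, tr_ms, m0=1.0, tol=1e-14):
    """Fixed point of the per-pulse recursion, iterated to convergence."""
    e1 = math.exp(-tr_ms / t1_ms)
    cos_a = math.cos(math.radians(flip_deg))
    mz = m0
    for _ in range(10_000_000):
        nxt = m0 + (mz * cos_a - m0) * e1
        if abs(nxt - mz) < tol * m0:
            return nxt
        mz = nxt
    raise RuntimeError("no convergence")


def apparent_t1_by_fit(t1_ms, flip_deg, tr_ms):
    """Fit the two-parameter model to a densely sampled noiseless pulsed
    recovery generated by direct per-pulse recursion."""
    e1 = math.exp(-tr_ms / t1_ms)
    a = math.radians(flip_deg)
    mss = steady_state_by_iteration(t1_ms, flip_deg, tr_ms)
    mz = -mss * math.cos(a)  # pulse then inversion at slot 0
    tis, sig = [], []
    n = int(6 * t1_ms / tr_ms)
    for k in range(1, n + 1):
        mz = 1.0 + (mz - 1.0) * e1
        tis.append(k * tr_ms)
        sig.append(mz * math.sin(a))
        mz *= math.cos(a)

    def f(ti, amp, t1s):
        return amp * (1 - 2 * np.exp(-np.asarray(ti) / t1s))

    popt, _ = curve_fit(f, tis, sig, p0=(max(np.abs(sig)), t1_ms))
    return popt[1]


def grid_fit_ir(ti, signal, n_a=201, n_t1=600):
    """2D grid search over (A, T1*) followed by Nelder-Mead refinement."""
    ti = np.asarray(ti, float)
    s = np.asarray(signal, float)
    a_max = max(np.max(np.abs(s)), 1e-12)
    a_grid = np.linspace(0.2 * a_max, 2.0 * a_max, n_a)
    t1_grid = np.geomspace(20.0, 5000.0, n_t1)
    model = 1.0 - 2.0 * np.exp(-ti[None, :] / t1_grid[:, None])  # (t1, ti)
    sse = ((a_grid[:, None, None] * model[None] - s[None, None, :]) ** 2).sum(-1)
    i, j = np.unravel_index(np.argmin(sse), sse.shape)

    def objective(x):
        return float(((x[0] * (1 - 2 * np.exp(-ti / x[1])) - s) ** 2).sum())

    res = minimize(
        objective,
        x0=(a_grid[i], t1_grid[j]),
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000},
    )
    return res.x[0], res.x[1], res.fun


def polarity_sweep_oracle(ti, magnitudes):
    """Exhaustive k sweep backed by the grid-search fit."""
    best = None
    for k in range(len(ti)):
        signed = np.array(magnitudes, float)
        signed[:k] *= -1
        _, _, sse = grid_fit_ir(ti, signed)
        if best is None or sse < best[1] - 1e-12:
            best = (k, sse)
    return best[0]


def piecewise_linear(series, n_target):
    """Segment-by-segment linear interpolation on the normalized axis."""
    y = list(map(float, series))
    n = len(y)
    out = []
    for m in range(n_target):
        x = m / (n_target - 1)  # position in [0, 1]
        pos = x * (n - 1)
        lo = min(int(math.floor(pos)), n - 2)
        frac = pos - lo
        out.append(y[lo] * (1 - frac) + y[lo + 1] * frac)
    return out
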