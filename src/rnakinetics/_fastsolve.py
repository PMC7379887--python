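"""Fixed-step exponential-midpoint integrator for the two-species system.

The premature/mature system is linear in the state for frozen rate values:
over a substep the rates are frozen at the midpoint time and the resulting
constant-coefficient system is advanced with its exact solution.  The scheme
is unconditionally stable (pure decaying exponentials), exact when all rates
are constant, and second-order accurate for time-varying rates — accurate to
well below typical replicate noise at the default step sizes, which is what
the fitting objective needs.  The adaptive LSODA path in :mod:`.kinetics`
remains the high-accuracy reference.

Rate functions are encoded positionally for numba: ``codes[i]`` is
0=constant, 1=sigmoid, 2=impulse and ``params[i]`` is a 6-wide row
(constant uses column 0; sigmoid columns 0-3 as h0,h1,t1,beta; impulse
columns 0-5 as h0,h1,h2,t1,t2,beta).
"""

from __future__ import annotations

import numpy as np
from numba import njit

FORM_CODES = {"constant": 0, "sigmoid": 1, "impulse": 2}

#: target (step x slope) product controlling accuracy on variable rates
_BETA_STEP = 0.25
#: minimum number of steps across the full requested span
_MIN_STEPS = 150
#: hard cap on total steps, whatever the slopes ask for
_MAX_STEPS = 4000


@njit(cache=True)
def _rate(code: int, p, t: float) -> float:
    if code == 0:
        return p[0]
    if code == 1:
        return p[0] + (p[1] - p[0]) / (1.0 + np.exp(-p[3] * (t - p[2])))
    first = p[0] + (p[1] - p[0]) / (1.0 + np.exp(-p[5] * (t - p[3])))
    second = p[2] + (p[1] - p[2]) / (1.0 + np.exp(p[5] * (t - p[4])))
    return first * second / p[1]


@njit(cache=True)
def _step(P: float, M: float, k1: float, k2: float, k3: float, h: float):
    # exact advance of dP/dt = k1 - k2*P, dM/dt = k2*P - k3*M with frozen rates
    Pss = k1 / k2
    Mss = k1 / k3
    dP = P - Pss
    e2 = np.exp(-k2 * h)
    e3 = np.exp(-k3 * h)
    P_new = Pss + dP * e2
    if abs(k3 - k2) > 1e-7 * (k2 + k3):
        B = k2 * dP / (k3 - k2)
        A = M - Mss - B
        M_new = Mss + A * e3 + B * e2
    else:
        # degenerate eigenvalue: t*exp(-kt) secular term
        M_new = Mss + (M - Mss) * e3 + k2 * dP * h * e3
    return P_new, M_new


@njit(cache=True)
def integrate(codes, params, times, h_max: float, P0: float, M0: float):
    """March the system across ``times``; returns an (n, 3) array of P, M, k1."""
    n = times.shape[0]
    out = np.empty((n, 3))
    P = P0
    M = M0
    out[0, 0] = P
    out[0, 1] = M
    out[0, 2] = _rate(codes[0], params[0], times[0])
    for i in range(1, n):
        ta = times[i - 1]
        tb = times[i]
        nsub = int(np.ceil((tb - ta) / h_max))
        if nsub < 1:
            nsub = 1
        h = (tb - ta) / nsub
        for j in range(nsub):
            tm = ta + (j + 0.5) * h
            k1 = _rate(codes[0], params[0], tm)
            k2 = _rate(codes[1], params[1], tm)
            k3 = _rate(codes[2], params[2], tm)
            P, M = _step(P, M, k1, k2, k3, h)
        out[i, 0] = P
        out[i, 1] = M
        out[i, 2] = _rate(codes[0], params[0], tb)
    return out


def step_size(codes: np.ndarray, params: np.ndarray, times: np.ndarray) -> float:
    """Choose a substep honouring the steepest slope among variable forms."""
    span = float(times[-1] - times[0])
    if span <= 0.0:
        return 1.0
    beta_max = 0.0
    for i in range(3):
        if codes[i] == 1:
            beta_max = max(beta_max, params[i, 3])
        elif codes[i] == 2:
            beta_max = max(beta_max, params[i, 5])
    h = span / _MIN_STEPS
    if beta_max > 0.0:
        h = min(h, _BETA_STEP / beta_max)
    return max(h, span / _MAX_STEPS)
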