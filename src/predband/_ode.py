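"""Compiled numerical core: Dormand-Prince 5(4) integration of the model ODEs.

The integrator is specialised for the three model families (signalling
cascade, its two-step simplification, and the three-mass oscillator) so that
the whole likelihood evaluation can run inside a single jitted Metropolis
loop.  Stimulation protocols are passed as flat arrays: piecewise-constant
segments ``(t0[i], t1[i], v[i])`` plus an optional sinusoid
``(amplitude, omega, phase, t_start)``.

Model ids: 0 = 4-step cascade (11 params), 1 = simplified 2-step cascade
(5 params), 2 = damped 3-mass oscillator (8 params).
"""

import numpy as np
from numba import njit

MODEL_CASCADE = 0
MODEL_SIMPLIFIED = 1
MODEL_OSCILLATOR = 2

STATUS_OK = 0
STATUS_STEP_UNDERFLOW = 1
STATUS_NONFINITE = 2
STATUS_MAXSTEPS = 3

#: Default step budget per trajectory solve during inference.  Parameter
#: vectors so stiff that the explicit Dormand-Prince pair cannot cross the
#: horizon within this budget (rate constants approaching the prior clip)
#: are reported as solver failures, which inference treats as zero
#: likelihood.  Direct simulation uses a much larger budget.
DEFAULT_MAX_STEPS = 5_000

_FASTMATH = {"contract", "reassoc", "arcp"}


@njit(cache=True, fastmath=_FASTMATH)
def protocol_value(t, seg_t0, seg_t1, seg_v, sin_par):
    """Input value at time t: containing segment's value plus the sinusoid
    A*sin(omega*(t - t_start) + phase) for t >= t_start; 0 where neither
    applies."""
    u = 0.0
    for i in range(seg_t0.shape[0]):
        if seg_t0[i] <= t < seg_t1[i]:
            u += seg_v[i]
            break
    if sin_par[0] != 0.0 and t >= sin_par[3]:
        u += sin_par[0] * np.sin(sin_par[1] * (t - sin_par[3]) + sin_par[2])
    return u


@njit(cache=True, fastmath=_FASTMATH)
def rhs(model_id, t, y, p, seg_t0, seg_t1, seg_v, sin_par, out):
    u = protocol_value(t, seg_t0, seg_t1, seg_v, sin_par)
    if model_id == MODEL_CASCADE:
        # p = (a1..a4, d1..d4, f1, f2, f3); K4 inhibits activation of steps 1-3
        k1, k2, k3, k4 = y[0], y[1], y[2], y[3]
        out[0] = p[0] * u * (1.0 - k1) / (1.0 + p[8] * k4) - p[4] * k1
        out[1] = p[1] * k1 * (1.0 - k2) / (1.0 + p[9] * k4) - p[5] * k2
        out[2] = p[2] * k2 * (1.0 - k3) / (1.0 + p[10] * k4) - p[6] * k3
        out[3] = p[3] * k3 * (1.0 - k4) - p[7] * k4
    elif model_id == MODEL_SIMPLIFIED:
        # p = (a1, d1, a4, d4, f1); K1 drives K4 directly
        k1, k4 = y[0], y[1]
        out[0] = p[0] * u * (1.0 - k1) / (1.0 + p[4] * k4) - p[1] * k1
        out[1] = p[2] * k1 * (1.0 - k4) - p[3] * k4
    else:
        # p = (m1, m2, m3, b1, b2, b3, k1, k2); chain m1-k1-m2-k2-m3,
        # dashpots to ground, force on mass 1; y = (x1, v1, x2, v2, x3, v3)
        x1, v1, x2, v2, x3, v3 = y[0], y[1], y[2], y[3], y[4], y[5]
        s1 = p[6] * (x2 - x1)
        s2 = p[7] * (x3 - x2)
        out[0] = v1
        out[1] = (s1 - p[3] * v1 + u) / p[0]
        out[2] = v2
        out[3] = (-s1 + s2 - p[4] * v2) / p[1]
        out[4] = v3
        out[5] = (-s2 - p[5] * v3) / p[2]


# Dormand-Prince 5(4) tableau
_C2, _C3, _C4, _C5 = 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (
    9017.0 / 3168.0,
    -355.0 / 33.0,
    46732.0 / 5247.0,
    49.0 / 176.0,
    -5103.0 / 18656.0,
)
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
_E1 = 35.0 / 384.0 - 5179.0 / 57600.0
_E3 = 500.0 / 1113.0 - 7571.0 / 16695.0
_E4 = 125.0 / 192.0 - 393.0 / 640.0
_E5 = -2187.0 / 6784.0 + 92097.0 / 339200.0
_E6 = 11.0 / 84.0 - 187.0 / 2100.0
_E7 = -1.0 / 40.0


@njit(cache=True, fastmath=_FASTMATH)
def _advance_to(
    model_id, p, seg_t0, seg_t1, seg_v, sin_par, t, y, t_end, h, rtol, atol, ws, budget
):
    """Adaptively integrate y from t to t_end in place.

    Returns (status, h, steps_used); h is the step-size estimate carried over
    to the next span.  ``ws`` is a (9, n) scratch array; ``budget`` caps the
    number of attempted steps.  The span is assumed free of protocol-segment
    discontinuities.
    """
    n = y.shape[0]
    k1 = ws[0]
    k2 = ws[1]
    k3 = ws[2]
    k4 = ws[3]
    k5 = ws[4]
    k6 = ws[5]
    k7 = ws[6]
    yt = ws[7]
    ynew = ws[8]
    rhs(model_id, t, y, p, seg_t0, seg_t1, seg_v, sin_par, k1)  # FSAL seed
    nsteps = 0
    while t < t_end:
        nsteps += 1
        if nsteps > budget:
            return STATUS_MAXSTEPS, h, nsteps
        if h > t_end - t:
            h = t_end - t
        # stage 2..6
        for i in range(n):
            yt[i] = y[i] + h * _A21 * k1[i]
        rhs(model_id, t + _C2 * h, yt, p, seg_t0, seg_t1, seg_v, sin_par, k2)
        for i in range(n):
            yt[i] = y[i] + h * (_A31 * k1[i] + _A32 * k2[i])
        rhs(model_id, t + _C3 * h, yt, p, seg_t0, seg_t1, seg_v, sin_par, k3)
        for i in range(n):
            yt[i] = y[i] + h * (_A41 * k1[i] + _A42 * k2[i] + _A43 * k3[i])
        rhs(model_id, t + _C4 * h, yt, p, seg_t0, seg_t1, seg_v, sin_par, k4)
        for i in range(n):
            yt[i] = y[i] + h * (_A51 * k1[i] + _A52 * k2[i] + _A53 * k3[i] + _A54 * k4[i])
        rhs(model_id, t + _C5 * h, yt, p, seg_t0, seg_t1, seg_v, sin_par, k5)
        for i in range(n):
            yt[i] = y[i] + h * (
                _A61 * k1[i] + _A62 * k2[i] + _A63 * k3[i] + _A64 * k4[i] + _A65 * k5[i]
            )
        rhs(model_id, t + h, yt, p, seg_t0, seg_t1, seg_v, sin_par, k6)
        for i in range(n):
            ynew[i] = y[i] + h * (
                _B1 * k1[i] + _B3 * k3[i] + _B4 * k4[i] + _B5 * k5[i] + _B6 * k6[i]
            )
        rhs(model_id, t + h, ynew, p, seg_t0, seg_t1, seg_v, sin_par, k7)
        # embedded 4th-order error estimate
        errnorm = 0.0
        ok = True
        for i in range(n):
            if not np.isfinite(ynew[i]):
                ok = False
                break
            e = h * (
                _E1 * k1[i] + _E3 * k3[i] + _E4 * k4[i] + _E5 * k5[i] + _E6 * k6[i] + _E7 * k7[i]
            )
            sc = atol + rtol * max(abs(y[i]), abs(ynew[i]))
            errnorm += (e / sc) ** 2
        if not ok:
            return STATUS_NONFINITE, h, nsteps
        errnorm = np.sqrt(errnorm / n)
        if errnorm <= 1.0:
            t = t + h
            for i in range(n):
                y[i] = ynew[i]
                k1[i] = k7[i]  # FSAL
            if errnorm == 0.0:
                fac = 5.0
            else:
                fac = min(5.0, max(0.2, 0.9 * errnorm ** -0.2))
            h = h * fac
        else:
            h = h * max(0.2, 0.9 * errnorm ** -0.2)
            if h < 1e-12:
                return STATUS_STEP_UNDERFLOW, h, nsteps
    return STATUS_OK, h, nsteps


@njit(cache=True, fastmath=_FASTMATH)
def integrate(
    model_id, p, y0, t_out, seg_t0, seg_t1, seg_v, sin_par, rtol, atol,
    max_steps=DEFAULT_MAX_STEPS,
):
    """Solve the model ODE, returning states at the requested times.

    Protocol segment edges are treated as hard breakpoints so the adaptive
    stepper never straddles an input discontinuity.
    Returns (values[len(t_out), n_state], status).
    """
    n = y0.shape[0]
    nt = t_out.shape[0]
    out = np.empty((nt, n))
    # stiffness guard: explicit RK45 needs h ~< 3/lambda for stability, so a
    # parameter vector whose fastest rate lambda implies more steps than the
    # budget is a guaranteed solver failure; reject it without integrating.
    if model_id == MODEL_CASCADE or model_id == MODEL_SIMPLIFIED:
        lam = 0.0
        if model_id == MODEL_CASCADE:
            # p = (a1..a4, d1..d4, ...)
            for i in range(4):
                r = p[i] + p[4 + i]
                if r > lam:
                    lam = r
        else:
            # p = (a1, d1, a4, d4, f1)
            lam = max(p[0] + p[1], p[2] + p[3])
        if lam * (t_out[nt - 1] - t_out[0]) / 3.0 > max_steps:
            return out, STATUS_MAXSTEPS
    ws = np.empty((9, n))
    y = y0.copy()
    t = t_out[0]
    for i in range(n):
        out[0, i] = y[i]
    # collect breakpoints inside the horizon
    t_end_total = t_out[nt - 1]
    h = (t_end_total - t) / 100.0 if t_end_total > t else 1e-3
    status = STATUS_OK
    budget = max_steps
    for j in range(1, nt):
        t_next = t_out[j]
        # integrate to t_next, splitting at any segment edge in (t, t_next)
        while True:
            t_stop = t_next
            for i in range(seg_t0.shape[0]):
                if t < seg_t0[i] < t_stop:
                    t_stop = seg_t0[i]
                if t < seg_t1[i] < t_stop:
                    t_stop = seg_t1[i]
            status, h, used = _advance_to(
                model_id, p, seg_t0, seg_t1, seg_v, sin_par, t, y, t_stop, h, rtol, atol,
                ws, budget,
            )
            budget -= used
            if status == STATUS_OK and budget <= 0 and t_stop < t_end_total:
                status = STATUS_MAXSTEPS
            if status != STATUS_OK:
                return out, status
            t = t_stop
            if t >= t_next:
                break
        for i in range(n):
            out[j, i] = y[i]
    return out, status


@njit(cache=True)
def integrate_batch(
    model_id, P, y0, t_out, seg_t0, seg_t1, seg_v, sin_par, rtol, atol,
    max_steps=DEFAULT_MAX_STEPS,
):
    """Integrate one trajectory per parameter row; returns (values, status)."""
    nb = P.shape[0]
    out = np.empty((nb, t_out.shape[0], y0.shape[0]))
    status = np.zeros(nb, dtype=np.int64)
    for b in range(nb):
        traj, st = integrate(
            model_id, P[b], y0, t_out, seg_t0, seg_t1, seg_v, sin_par, rtol, atol,
            max_steps,
        )
        out[b] = traj
        status[b] = st
    return out, status
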