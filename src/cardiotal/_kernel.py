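"""Compiled inner loop of the lumped-parameter circulation solver.

The circuit is flattened into plain integer/float arrays (see
:mod:`cardiotal.circuits`) so the right-hand side and the explicit time
stepping can be jit-compiled with numba.  When numba is unavailable the same
functions run as ordinary Python, bit-for-bit identical but slower.

State vector layout: the first ``n_storage`` entries are volumes (ml) of the
storage elements (capacitors and elastance chambers, in registry order); the
remaining entries are flows (ml/s) of the inertial branches.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(func):
            return func

        return wrap


# storage kinds
CAPACITOR = 0
CHAMBER = 1

# external pressure references for storage elements
REF_AMBIENT = 0
REF_INTRATHORACIC = 1
REF_INTRAMYOCARDIAL = 2  # gamma * P_lv (intramyocardial pump)

# branch kinds
B_RESISTOR = 0
B_VALVE = 1  # ideal diode in series with a resistance
B_RL = 2  # inductive branch, optionally with a series resistance
B_FLOWDEP = 3  # dP = R0*Q + k*Q*|Q|

# integrator status codes
OK = 0
NONFINITE_DERIVATIVE = 1
STATE_OUT_OF_BOUNDS = 2

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def activation(t, onset, tsys, period):
    """Raised-cosine activation in [0, 1]; zero outside the active window."""
    tau = (t - onset) % period
    if tau < tsys:
        return 0.5 * (1.0 - np.cos(TWO_PI * tau / tsys))
    return 0.0


@njit(cache=True)
def flowdep_flow(dp, r0, k):
    """Invert dP = R0*Q + k*Q*|Q| for Q (sign-preserving).

    Uses the rationalised root 2|dP| / (R0 + sqrt(R0^2 + 4k|dP|)), which is
    well-conditioned for any k >= 0 and reduces to Ohm's law at k = 0.
    """
    mag = abs(dp)
    denom = r0 + np.sqrt(r0 * r0 + 4.0 * k * mag)
    if denom == 0.0:
        return 0.0
    q = 2.0 * mag / denom
    return q if dp >= 0.0 else -q


@njit(cache=True)
def eval_rhs(
    t,
    y,
    P,
    Q,
    dy,
    # storage arrays
    s_node,
    s_kind,
    s_C,
    s_emax,
    s_emin,
    s_v0,
    s_onset,
    s_tsys,
    s_ref,
    node_store,
    # branch arrays
    b_kind,
    b_a,
    b_b,
    b_R,
    b_L,
    b_K,
    b_slot,
    # scalars
    period,
    pt,
    gamma,
    lv_node,
    rv_node,
    septum,
):
    """Fill node pressures P, branch flows Q and the state derivative dy."""
    ns = s_node.shape[0]
    nb = b_kind.shape[0]

    # elastance chambers first: their pressures may feed the intramyocardial
    # reference of the coronary compliance
    for i in range(ns):
        if s_kind[i] == CHAMBER:
            a = activation(t, s_onset[i], s_tsys[i], period)
            e = s_emin[i] + (s_emax[i] - s_emin[i]) * a
            ref = pt if s_ref[i] == REF_INTRATHORACIC else 0.0
            P[s_node[i]] = e * (y[i] - s_v0[i]) + ref

    if septum > 0.0 and lv_node >= 0 and rv_node >= 0:
        # linear interventricular cross-talk of transmural pressures
        plv_free = P[lv_node]
        prv_free = P[rv_node]
        P[lv_node] = plv_free + septum * (prv_free - pt)
        P[rv_node] = prv_free + septum * (plv_free - pt)

    plv = P[lv_node] if lv_node >= 0 else 0.0

    for i in range(ns):
        if s_kind[i] == CAPACITOR:
            if s_ref[i] == REF_AMBIENT:
                ref = 0.0
            elif s_ref[i] == REF_INTRATHORACIC:
                ref = pt
            else:
                ref = gamma * plv
            P[s_node[i]] = y[i] / s_C[i] + ref

    for i in range(y.shape[0]):
        dy[i] = 0.0

    for j in range(nb):
        pa = P[b_a[j]]
        pb = P[b_b[j]]
        kind = b_kind[j]
        if kind == B_RESISTOR:
            q = (pa - pb) / b_R[j]
        elif kind == B_VALVE:
            q = (pa - pb) / b_R[j] if pa > pb else 0.0
        elif kind == B_RL:
            q = y[b_slot[j]]
            dy[b_slot[j]] = (pa - pb - b_R[j] * q) / b_L[j]
        else:  # B_FLOWDEP
            q = flowdep_flow(pa - pb, b_R[j], b_K[j])
        Q[j] = q
        dy[node_store[b_a[j]]] -= q
        dy[node_store[b_b[j]]] += q


@njit(cache=True)
def integrate(
    y0,
    t0,
    n_steps,
    dt,
    rec_every,
    method,  # 0 = explicit Euler, 1 = classical RK4 (test oracle)
    bound,
    s_node,
    s_kind,
    s_C,
    s_emax,
    s_emin,
    s_v0,
    s_onset,
    s_tsys,
    s_ref,
    node_store,
    b_kind,
    b_a,
    b_b,
    b_R,
    b_L,
    b_K,
    b_slot,
    period,
    pt,
    gamma,
    lv_node,
    rv_node,
    septum,
):
    """March ``n_steps`` steps from (t0, y0), recording every ``rec_every``.

    Returns (status, bad_slot, n_recorded, T, Y, P, Q, y_final).
    """
    ny = y0.shape[0]
    nn = node_store.shape[0]
    nb = b_kind.shape[0]

    n_rec = n_steps // rec_every + 1
    T = np.empty(n_rec)
    Y = np.empty((n_rec, ny))
    PR = np.empty((n_rec, nn))
    QR = np.empty((n_rec, nb))

    y = y0.copy()
    P = np.empty(nn)
    Q = np.empty(nb)
    dy = np.empty(ny)
    # RK4 scratch
    yt = np.empty(ny)
    k2 = np.empty(ny)
    k3 = np.empty(ny)
    k4 = np.empty(ny)
    P2 = np.empty(nn)
    Q2 = np.empty(nb)

    status = OK
    bad = -1
    r = 0
    for step in range(n_steps + 1):
        t = t0 + step * dt
        eval_rhs(t, y, P, Q, dy, s_node, s_kind, s_C, s_emax, s_emin, s_v0,
                 s_onset, s_tsys, s_ref, node_store, b_kind, b_a, b_b, b_R,
                 b_L, b_K, b_slot, period, pt, gamma, lv_node, rv_node, septum)
        for i in range(ny):
            if not np.isfinite(dy[i]):
                status = NONFINITE_DERIVATIVE
                bad = i
                break
        if status != OK:
            break
        if step % rec_every == 0:
            T[r] = t
            for i in range(ny):
                Y[r, i] = y[i]
            for i in range(nn):
                PR[r, i] = P[i]
            for i in range(nb):
                QR[r, i] = Q[i]
            r += 1
        if step == n_steps:
            break

        if method == 0:
            for i in range(ny):
                y[i] += dt * dy[i]
        else:
            # classical 4th-order Runge-Kutta on the same equations
            for i in range(ny):
                yt[i] = y[i] + 0.5 * dt * dy[i]
            eval_rhs(t + 0.5 * dt, yt, P2, Q2, k2, s_node, s_kind, s_C,
                     s_emax, s_emin, s_v0, s_onset, s_tsys, s_ref, node_store,
                     b_kind, b_a, b_b, b_R, b_L, b_K, b_slot, period, pt,
                     gamma, lv_node, rv_node, septum)
            for i in range(ny):
                yt[i] = y[i] + 0.5 * dt * k2[i]
            eval_rhs(t + 0.5 * dt, yt, P2, Q2, k3, s_node, s_kind, s_C,
                     s_emax, s_emin, s_v0, s_onset, s_tsys, s_ref, node_store,
                     b_kind, b_a, b_b, b_R, b_L, b_K, b_slot, period, pt,
                     gamma, lv_node, rv_node, septum)
            for i in range(ny):
                yt[i] = y[i] + dt * k3[i]
            eval_rhs(t + dt, yt, P2, Q2, k4, s_node, s_kind, s_C, s_emax,
                     s_emin, s_v0, s_onset, s_tsys, s_ref, node_store, b_kind,
                     b_a, b_b, b_R, b_L, b_K, b_slot, period, pt, gamma,
                     lv_node, rv_node, septum)
            for i in range(ny):
                y[i] += dt / 6.0 * (dy[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])

        for i in range(ny):
            if not np.isfinite(y[i]) or abs(y[i]) > bound:
                status = STATE_OUT_OF_BOUNDS
                bad = i
                break
        if status != OK:
            break

    return status, bad, r, T, Y, PR, QR, y
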