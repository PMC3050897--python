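"""Compiled inner loops for integration and coupled learning.

Everything here operates on plain float64 arrays; shapes follow the
convention that batched states are stored column-wise, ``X[(neuron),
(batch)]``, so one kernel call advances an ensemble of networks that
share weights (recall tests, attractor censuses, bifurcation sweeps).

The kernels are jitted with numba when it is importable and fall back
to the same pure-Python code otherwise (slow, but semantically
identical).
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every test
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(fastmath=False)
def _act(u, beta, theta):
    return 1.0 / (1.0 + np.exp(-beta * (u - theta)))


@njit
def relax(
    Xh,
    Xo,
    J_ho,
    J_oh,
    I_ext,
    c_inh,
    beta,
    theta,
    tau,
    dt,
    n_steps,
    conv_tol,
    rec_every,
    rec_h,
    rec_o,
):
    """Advance a batch of networks with frozen weights.

    ``Xh`` (Nh, B) and ``Xo`` (No, B) are modified in place.  ``I_ext``
    (Nh, B) is the constant external drive per hidden neuron and batch
    column (``gamma * J_ih @ xi``; zeros for spontaneous activity).

    If ``conv_tol > 0`` the loop stops early once the largest rate
    drift per ``tau`` over the whole batch falls below ``conv_tol``.
    If ``rec_every > 0`` every ``rec_every``-th pre-update state is
    stored into ``rec_h`` (R, Nh, B) / ``rec_o`` (R, No, B).

    Returns ``(steps_done, n_recorded)``.
    """
    Nh, B = Xh.shape
    No = Xo.shape[0]
    a = dt / tau
    Ih = np.empty((Nh, B))
    Io = np.empty((No, B))
    n_rec = 0
    step = 0
    while step < n_steps:
        if rec_every > 0 and step % rec_every == 0 and n_rec < rec_h.shape[0]:
            for b in range(B):
                for i in range(Nh):
                    rec_h[n_rec, i, b] = Xh[i, b]
                for i in range(No):
                    rec_o[n_rec, i, b] = Xo[i, b]
            n_rec += 1
        max_drift = 0.0
        for b in range(B):
            Sh = 0.0
            for i in range(Nh):
                Sh += Xh[i, b]
            So = 0.0
            for i in range(No):
                So += Xo[i, b]
            for i in range(Nh):
                cur = I_ext[i, b] + c_inh * (Sh - Xh[i, b])
                for j in range(No):
                    cur += J_oh[i, j] * Xo[j, b]
                Ih[i, b] = cur
            for i in range(No):
                cur = c_inh * (So - Xo[i, b])
                for j in range(Nh):
                    cur += J_ho[i, j] * Xh[j, b]
                Io[i, b] = cur
        for b in range(B):
            for i in range(Nh):
                drift = -Xh[i, b] + _act(Ih[i, b], beta, theta)
                Xh[i, b] += a * drift
                if abs(drift) > max_drift:
                    max_drift = abs(drift)
            for i in range(No):
                drift = -Xo[i, b] + _act(Io[i, b], beta, theta)
                Xo[i, b] += a * drift
                if abs(drift) > max_drift:
                    max_drift = abs(drift)
        step += 1
        if conv_tol > 0.0 and max_drift < conv_tol:
            break
    return step, n_rec


@njit
def relax_track_min(
    Xh,
    Xo,
    J_ho,
    J_oh,
    I_ext,
    refs_h,
    refs_o,
    ref_norms,
    c_inh,
    beta,
    theta,
    tau,
    dt,
    n_steps,
    Dmin,
):
    """Advance a batch while tracking the running minimum distance.

    ``refs_h`` (Nh, K) / ``refs_o`` (No, K) hold K reference states
    (converged evoked states, hidden and output concatenated
    conceptually); ``ref_norms`` (K,) their Euclidean norms.  ``Dmin``
    (K, B) is updated in place with the minimum over the trajectory of
    the normalized distance between the full (hidden+output) state and
    each reference.
    """
    Nh, B = Xh.shape
    No = Xo.shape[0]
    K = refs_h.shape[1]
    a = dt / tau
    Ih = np.empty((Nh, B))
    Io = np.empty((No, B))
    for step in range(n_steps):
        for b in range(B):
            for k in range(K):
                s = 0.0
                for i in range(Nh):
                    diff = Xh[i, b] - refs_h[i, k]
                    s += diff * diff
                for i in range(No):
                    diff = Xo[i, b] - refs_o[i, k]
                    s += diff * diff
                dist = np.sqrt(s) / ref_norms[k]
                if dist < Dmin[k, b]:
                    Dmin[k, b] = dist
        for b in range(B):
            Sh = 0.0
            for i in range(Nh):
                Sh += Xh[i, b]
            So = 0.0
            for i in range(No):
                So += Xo[i, b]
            for i in range(Nh):
                cur = I_ext[i, b] + c_inh * (Sh - Xh[i, b])
                for j in range(No):
                    cur += J_oh[i, j] * Xo[j, b]
                Ih[i, b] = cur
            for i in range(No):
                cur = c_inh * (So - Xo[i, b])
                for j in range(Nh):
                    cur += J_ho[i, j] * Xh[j, b]
                Io[i, b] = cur
        for b in range(B):
            for i in range(Nh):
                Xh[i, b] += a * (-Xh[i, b] + _act(Ih[i, b], beta, theta))
            for i in range(No):
                Xo[i, b] += a * (-Xo[i, b] + _act(Io[i, b], beta, theta))
    return n_steps


@njit
def learn_step(
    xh,
    xo,
    J_ih,
    J_ho,
    J_oh,
    xi,
    target,
    gamma,
    c_inh,
    beta,
    theta,
    tau,
    dt,
    r0,
    eps_d,
    lambda_penalty,
    tau_f,
    tau_b,
    w_max,
    n_stab_steps,
    n_max_steps,
    bs_stab_scale,
    rec_every,
    d_rec,
    phase_rec,
    out_rec,
):
    """One coupled learning step (dynamics + plasticity) on one mapping.

    The input layer is clamped at ``gamma * xi``; the error
    ``d = ||x_out - target|| / ||target||`` selects the reward sign
    (+1 Hebbian when ``d < eps_d``, else -1 anti-Hebbian) that gates
    every plastic weight update.  The step succeeds when ``d < eps_d``
    has held for ``n_stab_steps`` contiguous integration steps, and
    times out at ``n_max_steps``.

    ``xh``/``xo`` (vectors) and the three weight matrices are updated
    in place.  Every ``rec_every``-th step the error, the phase flag
    (1 = stabilization) and the output rates are recorded.

    Returns ``(success, steps_done, n_recorded)``.
    """
    Nh = xh.shape[0]
    No = xo.shape[0]
    Ni = xi.shape[0]
    a = dt / tau
    tnorm = 0.0
    for i in range(No):
        tnorm += target[i] * target[i]
    tnorm = np.sqrt(tnorm)
    # constant external drive and clamped presynaptic input rates
    I_ext = np.empty(Nh)
    x_in = np.empty(Ni)
    for j in range(Ni):
        x_in[j] = gamma * xi[j]
    for i in range(Nh):
        cur = 0.0
        for j in range(Ni):
            cur += J_ih[i, j] * x_in[j]
        I_ext[i] = cur
    Ih = np.empty(Nh)
    Io = np.empty(No)
    stab_run = 0
    n_rec = 0
    success = 0
    step = 0
    while step < n_max_steps:
        # error and reward sign from the current state
        s = 0.0
        for i in range(No):
            diff = xo[i] - target[i]
            s += diff * diff
        d = np.sqrt(s) / tnorm
        if d < eps_d:
            delta = 1.0
            stab_run += 1
        else:
            delta = -1.0
            stab_run = 0
        if rec_every > 0 and step % rec_every == 0 and n_rec < d_rec.shape[0]:
            d_rec[n_rec] = d
            phase_rec[n_rec] = 1 if delta > 0 else 0
            for i in range(No):
                out_rec[n_rec, i] = xo[i]
            n_rec += 1
        if stab_run >= n_stab_steps:
            success = 1
            break
        # currents from the pre-update state
        Sh = 0.0
        for i in range(Nh):
            Sh += xh[i]
        So = 0.0
        for i in range(No):
            So += xo[i]
        for i in range(Nh):
            cur = I_ext[i] + c_inh * (Sh - xh[i])
            for j in range(No):
                cur += J_oh[i, j] * xo[j]
            Ih[i] = cur
        for i in range(No):
            cur = c_inh * (So - xo[i])
            for j in range(Nh):
                cur += J_ho[i, j] * xh[j]
            Io[i] = cur
        # plasticity from the pre-update rates; penalty (anti-Hebbian)
        # updates run at the asymmetric reward-penalty rate
        lam = 1.0 if delta > 0.0 else lambda_penalty
        af = lam * dt / tau_f
        ab = lam * dt / tau_b
        for i in range(Nh):
            post = delta * (xh[i] - r0)
            for j in range(Ni):
                if x_in[j] != 0.0:
                    w = J_ih[i, j] + af * post * x_in[j]
                    if w < 0.0:
                        w = 0.0
                    elif w > w_max:
                        w = w_max
                    J_ih[i, j] = w
        for i in range(No):
            post = delta * (xo[i] - r0)
            for j in range(Nh):
                w = J_ho[i, j] + af * post * xh[j]
                if w < 0.0:
                    w = 0.0
                elif w > w_max:
                    w = w_max
                J_ho[i, j] = w
        ab_eff = ab * bs_stab_scale if delta > 0.0 else ab
        if ab_eff != 0.0:
            for i in range(Nh):
                post = delta * (xh[i] - r0)
                for j in range(No):
                    w = J_oh[i, j] + ab_eff * post * xo[j]
                    if w < 0.0:
                        w = 0.0
                    elif w > w_max:
                        w = w_max
                    J_oh[i, j] = w
        # refresh the clamped-input drive (J_ih changed)
        for i in range(Nh):
            cur = 0.0
            for j in range(Ni):
                cur += J_ih[i, j] * x_in[j]
            I_ext[i] = cur
        # rate update
        for i in range(Nh):
            xh[i] += a * (-xh[i] + _act(Ih[i], beta, theta))
        for i in range(No):
            xo[i] += a * (-xo[i] + _act(Io[i], beta, theta))
        step += 1
    return success, step, n_rec
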