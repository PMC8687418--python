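"""Numba-compiled fixed-step integrator for the stacked moment ODE system.

The mean + upper-triangle covariance system of every interval is advanced
with classical fourth-order Runge-Kutta on normalised time.  Rate laws are
encoded as per-reaction factor tables (species index, polynomial
coefficients in ``g = offset + sign * x``), so one kernel serves every
mass-action network.  The numpy fallback in :mod:`mssfit.lna` implements the
identical scheme and is cross-checked against this kernel in the tests.
"""
from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _rhs_one(y, dt, S, theta_r, n_fac, fac_sp, fac_co, fac_off, fac_sg,
             inv_vol, iu_i, iu_j, mean_only, out, v, dv, fv, J, Sig):
    D, r = S.shape
    ncoef = fac_co.shape[2]
    for j in range(r):
        for l in range(D):
            dv[j, l] = 0.0
        nf = n_fac[j]
        prod = 1.0
        for f in range(nf):
            g = fac_off[j, f] + fac_sg[j, f] * y[fac_sp[j, f]]
            acc = 0.0
            for c in range(ncoef - 1, -1, -1):
                acc = acc * g + fac_co[j, f, c]
            fv[f] = acc
            prod *= acc
        v[j] = theta_r[j] * prod
        if not mean_only:
            for f in range(nf):
                g = fac_off[j, f] + fac_sg[j, f] * y[fac_sp[j, f]]
                dacc = 0.0
                for c in range(ncoef - 1, 0, -1):
                    dacc = dacc * g + c * fac_co[j, f, c]
                dacc *= fac_sg[j, f]
                oth = theta_r[j]
                for f2 in range(nf):
                    if f2 != f:
                        oth *= fv[f2]
                dv[j, fac_sp[j, f]] += oth * dacc
    for i in range(D):
        acc = 0.0
        for j in range(r):
            acc += S[i, j] * v[j]
        out[i] = acc * dt
    if mean_only:
        return
    for i in range(D):
        for l in range(D):
            acc = 0.0
            for j in range(r):
                acc += S[i, j] * dv[j, l]
            J[i, l] = acc
    T = iu_i.shape[0]
    for t in range(T):
        Sig[iu_i[t], iu_j[t]] = y[D + t]
        Sig[iu_j[t], iu_i[t]] = y[D + t]
    for t in range(T):
        a = iu_i[t]
        b = iu_j[t]
        acc = 0.0
        for l in range(D):
            acc += J[a, l] * Sig[l, b] + Sig[a, l] * J[b, l]
        dm = 0.0
        for j in range(r):
            dm += S[a, j] * S[b, j] * v[j]
        out[D + t] = (acc + dm * inv_vol) * dt


@njit(cache=True)
def rk4_batch(Y0, dts, n_steps, S, theta_r, n_fac, fac_sp, fac_co, fac_off,
              fac_sg, inv_vol, iu_i, iu_j, mean_only):
    n, W = Y0.shape
    out = Y0.copy()
    h = 1.0 / n_steps
    k1 = np.empty(W)
    k2 = np.empty(W)
    k3 = np.empty(W)
    k4 = np.empty(W)
    yt = np.empty(W)
    D, r = S.shape
    v = np.empty(r)
    dv = np.zeros((r, D))
    fv = np.empty(fac_sp.shape[1])
    J = np.zeros((D, D))
    Sig = np.zeros((D, D))
    for s in range(n):
        y = out[s]
        dt = dts[s]
        for _ in range(n_steps):
            _rhs_one(y, dt, S, theta_r, n_fac, fac_sp, fac_co, fac_off,
                     fac_sg, inv_vol, iu_i, iu_j, mean_only, k1, v, dv, fv, J, Sig)
            for w in range(W):
                yt[w] = y[w] + 0.5 * h * k1[w]
            _rhs_one(yt, dt, S, theta_r, n_fac, fac_sp, fac_co,
                     fac_off, fac_sg, inv_vol, iu_i, iu_j, mean_only, k2, v, dv, fv, J, Sig)
            for w in range(W):
                yt[w] = y[w] + 0.5 * h * k2[w]
            _rhs_one(yt, dt, S, theta_r, n_fac, fac_sp, fac_co,
                     fac_off, fac_sg, inv_vol, iu_i, iu_j, mean_only, k3, v, dv, fv, J, Sig)
            for w in range(W):
                yt[w] = y[w] + h * k3[w]
            _rhs_one(yt, dt, S, theta_r, n_fac, fac_sp, fac_co,
                     fac_off, fac_sg, inv_vol, iu_i, iu_j, mean_only, k4, v, dv, fv, J, Sig)
            for w in range(W):
                y[w] += (h / 6.0) * (k1[w] + 2.0 * k2[w] + 2.0 * k3[w] + k4[w])
    return out


def network_tables(net):
    """Factor tables for the kernel, cached on the network instance."""
    cached = getattr(net, "_kernel_tables", None)
    if cached is not None:
        return cached
    r = net.n_reactions
    maxf = max((len(rl.factors) for rl in net.rate_laws), default=0)
    maxf = max(maxf, 1)
    ncoef = 1
    for rl in net.rate_laws:
        for f in rl.factors:
            ncoef = max(ncoef, len(f.coeffs))
    n_fac = np.zeros(r, dtype=np.int64)
    fac_sp = np.zeros((r, maxf), dtype=np.int64)
    fac_co = np.zeros((r, maxf, ncoef))
    fac_off = np.zeros((r, maxf))
    fac_sg = np.ones((r, maxf))
    param_idx = np.zeros(r, dtype=np.int64)
    for j, rl in enumerate(net.rate_laws):
        param_idx[j] = rl.param_index
        n_fac[j] = len(rl.factors)
        for f, fac in enumerate(rl.factors):
            fac_sp[j, f] = fac.species
            fac_co[j, f, : len(fac.coeffs)] = fac.coeffs
            fac_off[j, f] = fac.offset
            fac_sg[j, f] = float(fac.sign)
    tables = {
        "S": np.asarray(net.S, dtype=float),
        "n_fac": n_fac,
        "fac_sp": fac_sp,
        "fac_co": fac_co,
        "fac_off": fac_off,
        "fac_sg": fac_sg,
        "param_idx": param_idx,
        "inv_vol": 1.0 / net.volume,
    }
    net._kernel_tables = tables
    return tables


@njit(cache=True)
def rk4_chain(obs_data, hid0, obs_ix, hid_ix, dts, n_steps, S, theta_r,
              n_fac, fac_sp, fac_co, fac_off, fac_sg, inv_vol, iu_i, iu_j):
    """Sequential hidden-state chain: interval i starts from the observed
    datum at t_{i-1} merged with the hidden part of interval i-1's mean
    solution.  Returns per-interval full means, packed covariances and the
    hidden initial states used."""
    n = dts.shape[0]
    D, r = S.shape
    T = iu_i.shape[0]
    W = D + T
    means = np.empty((n, D))
    covs_packed = np.empty((n, T))
    hidden_path = np.empty((n, hid_ix.shape[0]))
    y = np.empty(W)
    cur = np.empty(D)
    k1 = np.empty(W)
    k2 = np.empty(W)
    k3 = np.empty(W)
    k4 = np.empty(W)
    yt = np.empty(W)
    v = np.empty(r)
    dv = np.zeros((r, D))
    fv = np.empty(fac_sp.shape[1])
    J = np.zeros((D, D))
    Sig = np.zeros((D, D))
    h = 1.0 / n_steps
    for k in range(obs_ix.shape[0]):
        cur[obs_ix[k]] = obs_data[0, k]
    for k in range(hid_ix.shape[0]):
        cur[hid_ix[k]] = hid0[k]
    for i in range(n):
        for k in range(hid_ix.shape[0]):
            hidden_path[i, k] = cur[hid_ix[k]]
        for w in range(D):
            y[w] = cur[w]
        for w in range(D, W):
            y[w] = 0.0
        dt = dts[i]
        for _ in range(n_steps):
            _rhs_one(y, dt, S, theta_r, n_fac, fac_sp, fac_co, fac_off,
                     fac_sg, inv_vol, iu_i, iu_j, False, k1, v, dv, fv, J, Sig)
            for w in range(W):
                yt[w] = y[w] + 0.5 * h * k1[w]
            _rhs_one(yt, dt, S, theta_r, n_fac, fac_sp, fac_co, fac_off,
                     fac_sg, inv_vol, iu_i, iu_j, False, k2, v, dv, fv, J, Sig)
            for w in range(W):
                yt[w] = y[w] + 0.5 * h * k2[w]
            _rhs_one(yt, dt, S, theta_r, n_fac, fac_sp, fac_co, fac_off,
                     fac_sg, inv_vol, iu_i, iu_j, False, k3, v, dv, fv, J, Sig)
            for w in range(W):
                yt[w] = y[w] + h * k3[w]
            _rhs_one(yt, dt, S, theta_r, n_fac, fac_sp, fac_co, fac_off,
                     fac_sg, inv_vol, iu_i, iu_j, False, k4, v, dv, fv, J, Sig)
            for w in range(W):
                y[w] += (h / 6.0) * (k1[w] + 2.0 * k2[w] + 2.0 * k3[w] + k4[w])
        for w in range(D):
            means[i, w] = y[w]
        for t in range(T):
            covs_packed[i, t] = y[D + t]
        if i + 1 < n:
            for k in range(obs_ix.shape[0]):
                cur[obs_ix[k]] = obs_data[i + 1, k]
            for k in range(hid_ix.shape[0]):
                cur[hid_ix[k]] = y[hid_ix[k]]
    return means, covs_packed, hidden_path
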