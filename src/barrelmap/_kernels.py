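"""Compiled inner loops for the recurrent sheet.

The lateral-inhibitory projection is the computational bottleneck: every
neuron carries an individual weight for each neuron inside a window four
supra-barrel widths across (7,056 connections per neuron on the default
105x105 sheet).  The settling kernel therefore switches per step between

* a *sparse* gather that loops over the list of currently active presynaptic
  neurons (cheap once activity has condensed into bubbles), and
* a *dense* gather that streams each candidate's full weight window against a
  zero-padded activity array (cheap when a large fraction of the sheet is
  active, because the reads are unit-stride).

Both routes compute the same sums; the switch depends only on the active
count, so runs are deterministic for a fixed seed.  Settling reads a
single-precision mirror of the inhibitory weights (half the memory traffic);
the master weights, and all learning, stay in double precision.

A slow pure-NumPy reference (`settle_reference`) implements the identical
dynamics for cross-checking on small sheets.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "settle_kernel",
    "inhib_update_kernel",
    "weight_dir_corr_accumulate",
    "settle_reference",
    "piecewise_sigmoid",
]


def piecewise_sigmoid(x, delta: float, beta: float):
    """Piecewise-linear sigmoid: 0 below ``delta``, 1 above ``beta``, linear between."""
    if not beta > delta:
        raise ValueError(f"require beta > delta, got delta={delta}, beta={beta}")
    x = np.asarray(x, dtype=float)
    out = (x - delta) / (beta - delta)
    return np.clip(out, 0.0, 1.0)


@njit(inline="always")
def _sigma(x, delta, beta):
    if x <= delta:
        return 0.0
    if x >= beta:
        return 1.0
    return (x - delta) / (beta - delta)


@njit(cache=True)
def settle_kernel(
    drive,          # (H, W) float64, held constant over settling
    excit_w,        # (H, W, Ke, Ke) float64, fixed lateral-excitatory weights
    inhib_w32,      # (H, W, Ki, Ki) float32 mirror of inhibitory weights
    klo_e,          # window offset of excitatory field (-(Ke//2))
    klo_i,          # window offset of inhibitory field (-(Ki//2))
    gamma_E, gamma_I, delta, beta,
    n_steps,
    history,        # (n_steps+1, H, W) or (0, 0, 0) to skip recording
    changes,        # (n_steps,) out: max |activity change| per step
    sparse_threshold,
):
    H, W = drive.shape
    Ke = excit_w.shape[2]
    Ki = inhib_w32.shape[2]
    record = history.shape[0] > 0

    act = np.zeros((H, W))
    new = np.zeros((H, W))
    act_pad = np.zeros((H + Ki, W + Ki), dtype=np.float32)

    # active / candidate bookkeeping
    ar = np.empty(H * W, np.int64)
    ac = np.empty(H * W, np.int64)
    av = np.empty(H * W, np.float64)
    cr = np.empty(H * W, np.int64)
    cc = np.empty(H * W, np.int64)
    stamp = np.zeros((H, W), np.int64)

    # cells with afferent drive; only these (plus neighbours of active cells)
    # can ever activate, since the sigmoid threshold is nonnegative
    ndriven = 0
    dr_r = np.empty(H * W, np.int64)
    dr_c = np.empty(H * W, np.int64)
    for r in range(H):
        for c in range(W):
            if drive[r, c] > 0.0:
                dr_r[ndriven] = r
                dr_c[ndriven] = c
                ndriven += 1

    # step 0: feed-forward response only
    for r in range(H):
        for c in range(W):
            act[r, c] = _sigma(drive[r, c], delta, beta)
    if record:
        for r in range(H):
            for c in range(W):
                history[0, r, c] = act[r, c]

    for t in range(1, n_steps + 1):
        # active list
        na = 0
        for r in range(H):
            for c in range(W):
                v = act[r, c]
                if v > 0.0:
                    ar[na] = r
                    ac[na] = c
                    av[na] = v
                    na += 1

        # candidates: driven cells plus the 3x3 dilation of active cells
        ncand = 0
        for i in range(ndriven):
            r = dr_r[i]
            c = dr_c[i]
            if stamp[r, c] != t:
                stamp[r, c] = t
                cr[ncand] = r
                cc[ncand] = c
                ncand += 1
        for i in range(na):
            for dr in range(-1, 2):
                rr = ar[i] + dr
                if rr < 0 or rr >= H:
                    continue
                for dc in range(-1, 2):
                    c2 = ac[i] + dc
                    if c2 < 0 or c2 >= W:
                        continue
                    if stamp[rr, c2] != t:
                        stamp[rr, c2] = t
                        cr[ncand] = rr
                        cc[ncand] = c2
                        ncand += 1

        dense = na >= sparse_threshold
        if dense:
            act_pad[:, :] = 0.0
            for i in range(na):
                act_pad[ar[i] - klo_i, ac[i] - klo_i] = np.float32(av[i])

        max_change = 0.0
        for q in range(ncand):
            r = cr[q]
            c = cc[q]
            # lateral excitation over the (clipped) 3x3 neighbourhood
            e = 0.0
            for dr in range(Ke):
                rr = r + klo_e + dr
                if rr < 0 or rr >= H:
                    continue
                for dc in range(Ke):
                    c2 = c + klo_e + dc
                    if c2 < 0 or c2 >= W:
                        continue
                    a = act[rr, c2]
                    if a > 0.0:
                        e += excit_w[r, c, dr, dc] * a
            # lateral inhibition over the wide window
            inh = 0.0
            if dense:
                wrow = inhib_w32[r, c]
                acc = np.float32(0.0)
                for dr in range(Ki):
                    rbase = r + dr
                    for dc in range(Ki):
                        acc += wrow[dr, dc] * act_pad[rbase, c + dc]
                inh = float(acc)
            else:
                for i in range(na):
                    dr = ar[i] - r - klo_i
                    if 0 <= dr < Ki:
                        dc = ac[i] - c - klo_i
                        if 0 <= dc < Ki:
                            inh += inhib_w32[r, c, dr, dc] * av[i]
            v = _sigma(drive[r, c] + gamma_E * e - gamma_I * inh, delta, beta)
            new[r, c] = v
            d = abs(v - act[r, c])
            if d > max_change:
                max_change = d
        changes[t - 1] = max_change

        # commit: only candidate cells can change; others are 0 in both arrays
        for q in range(ncand):
            act[cr[q], cc[q]] = new[cr[q], cc[q]]
        if record:
            for r in range(H):
                for c in range(W):
                    history[t, r, c] = act[r, c]
    return act


@njit(cache=True)
def inhib_update_kernel(
    inhib_w,        # (H, W, Ki, Ki) float64 master weights, updated in place
    inhib_w32,      # float32 mirror, kept in sync
    alpha,          # (H, W) per-neuron learning rate c_I / N_CF
    klo_i,
    ar, ac, av, na,  # settled-active neurons (presynaptic == postsynaptic list)
):
    Ki = inhib_w.shape[2]
    for p in range(na):
        r = ar[p]
        c = ac[p]
        inc = alpha[r, c] * av[p]  # av[p] is the postsynaptic activity
        slab = inhib_w[r, c]
        for i in range(na):
            dr = ar[i] - r - klo_i
            if 0 <= dr < Ki:
                dc = ac[i] - c - klo_i
                if 0 <= dc < Ki:
                    slab[dr, dc] += inc * av[i]
        s = 0.0
        for dr in range(Ki):
            for dc in range(Ki):
                s += slab[dr, dc]
        inv = 1.0 / s
        slab32 = inhib_w32[r, c]
        for dr in range(Ki):
            for dc in range(Ki):
                v = slab[dr, dc] * inv
                slab[dr, dc] = v
                slab32[dr, dc] = np.float32(v)


@njit(cache=True)
def weight_dir_corr_accumulate(inhib_w, pref, klo_i):
    """Stream Pearson accumulators over every in-sheet inhibitory connection.

    x = connection weight, y = circular absolute difference of the two
    neurons' preferred directions.  Returns (n, sx, sy, sxx, syy, sxy).
    """
    H, W, Ki, _ = inhib_w.shape
    pi = np.pi
    n = 0
    sx = 0.0
    sy = 0.0
    sxx = 0.0
    syy = 0.0
    sxy = 0.0
    for r in range(H):
        for c in range(W):
            pj = pref[r, c]
            for dr in range(Ki):
                rr = r + klo_i + dr
                if rr < 0 or rr >= H:
                    continue
                for dc in range(Ki):
                    c2 = c + klo_i + dc
                    if c2 < 0 or c2 >= W:
                        continue
                    w = inhib_w[r, c, dr, dc]
                    d = abs(pj - pref[rr, c2])
                    if d > pi:
                        d = 2.0 * pi - d
                    n += 1
                    sx += w
                    sy += d
                    sxx += w * w
                    syy += d * d
                    sxy += w * d
    return n, sx, sy, sxx, syy, sxy


def settle_reference(
    drive, excit_w, inhib_w, klo_e, klo_i, gamma_E, gamma_I,
    delta, beta, n_steps,
):
    """Pure-NumPy settling with identical semantics (for small sheets / tests)."""
    H, W = drive.shape
    Ke = excit_w.shape[2]
    Ki = inhib_w.shape[2]
    act = piecewise_sigmoid(drive, delta, beta)
    history = [act.copy()]
    for _ in range(n_steps):
        pad_e = np.zeros((H + Ke, W + Ke))
        pad_e[-klo_e : -klo_e + H, -klo_e : -klo_e + W] = act
        exc = np.zeros((H, W))
        for dr in range(Ke):
            for dc in range(Ke):
                exc += excit_w[:, :, dr, dc] * pad_e[dr : dr + H, dc : dc + W]
        pad_i = np.zeros((H + Ki, W + Ki))
        pad_i[-klo_i : -klo_i + H, -klo_i : -klo_i + W] = act
        inh = np.zeros((H, W))
        for dr in range(Ki):
            for dc in range(Ki):
                inh += inhib_w[:, :, dr, dc] * pad_i[dr : dr + H, dc : dc + W]
        act = piecewise_sigmoid(drive + gamma_E * exc - gamma_I * inh, delta, beta)
        history.append(act.copy())
    return act, history
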