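"""Numba kernels for the micro-stepped random walk.

The walk takes +/- ``step`` moves with equal probability at the micro
time step tau = step**2 / (2 D), so frame binning averages 1e3-1e5
micro-steps; the kernels fuse stepping with per-frame efficiency
accumulation to avoid materializing the micro trajectory.
Reflection at [0, x_max]; a single fold per step suffices because
step <= 0.1 register units.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def walk_positions(n_steps, x_init, step, x_max, seed):
    """Positions after each of ``n_steps`` micro-steps (x_max < 0 = unbounded)."""
    np.random.seed(seed)
    out = np.empty(n_steps)
    x = x_init
    for i in range(n_steps):
        if np.random.random() < 0.5:
            x += step
        else:
            x -= step
        if x_max >= 0.0:
            if x < 0.0:
                x = -x
            elif x > x_max:
                x = 2.0 * x_max - x
        out[i] = x
    return out


@njit(cache=True)
def walk_frame_efficiency(n_frames, steps_per_frame, x_init, step, x_max,
                          center, r2, inv_r0_sq, rise, seed):
    """Frame-averaged two-color FRET of a reflected walk.

    ``center`` is the register coordinate at which donor and acceptor
    are axially aligned; efficiency uses
    E = 1 / (1 + ((r^2 + (rise*(x-center))^2) / R0^2)^3).
    Coin flips are drawn 30 at a time from one random integer.
    Returns (per-frame mean efficiency, final position).
    """
    np.random.seed(seed)
    e = np.zeros(n_frames)
    x = x_init
    bits = np.int64(0)
    n_bits = 0
    for f in range(n_frames):
        acc = 0.0
        for _ in range(steps_per_frame):
            if n_bits == 0:
                bits = np.random.randint(0, 1073741824)  # 30 fresh coin flips
                n_bits = 30
            if bits & 1:
                x += step
            else:
                x -= step
            bits >>= 1
            n_bits -= 1
            if x < 0.0:
                x = -x
            elif x > x_max:
                x = 2.0 * x_max - x
            dx = rise * (x - center)
            u = (r2 + dx * dx) * inv_r0_sq
            acc += 1.0 / (1.0 + u * u * u)
        e[f] = acc / steps_per_frame
    return e, x


@njit(cache=True)
def walk_frame_partition3(n_frames, steps_per_frame, x_init, step, x_max,
                          center1, center2, r2, inv_r01_sq, inv_r02_sq,
                          rise, seed):
    """Frame-averaged donor-photon partition for two acceptors.

    Per micro-step the donor excitation is split among donor / acceptor-1 /
    acceptor-2 according to the two Forster rate ratios
    k_i = (R0_i / L_i)^6: f_Ai = k_i / (1 + k1 + k2).
    Returns (per-frame mean f_A1, per-frame mean f_A2, final position).
    """
    np.random.seed(seed)
    f1 = np.zeros(n_frames)
    f2 = np.zeros(n_frames)
    x = x_init
    bits = np.int64(0)
    n_bits = 0
    for f in range(n_frames):
        a1 = 0.0
        a2 = 0.0
        for _ in range(steps_per_frame):
            if n_bits == 0:
                bits = np.random.randint(0, 1073741824)  # 30 fresh coin flips
                n_bits = 30
            if bits & 1:
                x += step
            else:
                x -= step
            bits >>= 1
            n_bits -= 1
            if x < 0.0:
                x = -x
            elif x > x_max:
                x = 2.0 * x_max - x
            dx1 = rise * (x - center1)
            u1 = (r2 + dx1 * dx1) * inv_r01_sq
            k1 = 1.0 / (u1 * u1 * u1)
            dx2 = rise * (x - center2)
            u2 = (r2 + dx2 * dx2) * inv_r02_sq
            k2 = 1.0 / (u2 * u2 * u2)
            denom = 1.0 + k1 + k2
            a1 += k1 / denom
            a2 += k2 / denom
        f1[f] = a1 / steps_per_frame
        f2[f] = a2 / steps_per_frame
    return f1, f2, x
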