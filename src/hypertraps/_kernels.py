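"""Numba inner loops for the biased path walkers.

Each walker takes a known number of steps (one per mode still to acquire),
and each step consumes exactly one uniform variate, so the caller pre-draws
all randomness from its numpy Generator and passes it in — runs stay
bit-reproducible from the seed while the hot loop runs compiled.

Log acquisition rates are maintained incrementally (acquiring mode j adds
theta[:, j]) and re-centred by the running maximum over absent modes before
exponentiation, so rate sums never overflow even at the prior bounds.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(cache=True)
def walk_log_weights(A, B, theta, n_paths, U):
    """Log importance weights of biased walks from A rows towards B rows.

    A, B: (n_obs, L) uint8 with A <= B rowwise.  U: flat uniforms, one per
    (observation, path, step), observation-major.  Returns
    (n_obs * n_paths,) log weights.
    """
    n_obs, L = A.shape
    logw = np.zeros(n_obs * n_paths)
    u_idx = 0
    s = np.empty(L, dtype=np.uint8)
    lr = np.empty(L)
    for i in range(n_obs):
        for p in range(n_paths):
            w = i * n_paths + p
            for m in range(L):
                s[m] = A[i, m]
            for m in range(L):
                acc = theta[m, m]
                for j in range(L):
                    if s[j]:
                        acc += theta[m, j]
                lr[m] = acc
            nrem = 0
            for m in range(L):
                if B[i, m] and not s[m]:
                    nrem += 1
            while nrem > 0:
                mx = -1e300
                for m in range(L):
                    if not s[m] and lr[m] > mx:
                        mx = lr[m]
                Z = 0.0
                T = 0.0
                for m in range(L):
                    if not s[m]:
                        e = math.exp(lr[m] - mx)
                        Z += e
                        if B[i, m]:
                            T += e
                logw[w] += math.log(T) - math.log(Z)
                r = U[u_idx] * T
                u_idx += 1
                c = 0.0
                chosen = -1
                for m in range(L):
                    if not s[m] and B[i, m]:
                        c += math.exp(lr[m] - mx)
                        if c > r:
                            chosen = m
                            break
                if chosen < 0:
                    for m in range(L - 1, -1, -1):
                        if not s[m] and B[i, m]:
                            chosen = m
                            break
                s[chosen] = 1
                for m in range(L):
                    lr[m] += theta[m, chosen]
                nrem -= 1
    return logw


@njit(cache=True)
def walk_orders(start, theta, n_paths, U):
    """Full monotone walks from ``start``; returns (n_paths, n_steps) orders.

    U: flat uniforms, one per (path, step), path-major.
    """
    L = start.shape[0]
    n_start = 0
    for m in range(L):
        if start[m]:
            n_start += 1
    n_steps = L - n_start
    orders = np.empty((n_paths, n_steps), dtype=np.int64)
    s = np.empty(L, dtype=np.uint8)
    lr = np.empty(L)
    u_idx = 0
    for p in range(n_paths):
        for m in range(L):
            s[m] = start[m]
        for m in range(L):
            acc = theta[m, m]
            for j in range(L):
                if s[j]:
                    acc += theta[m, j]
            lr[m] = acc
        for k in range(n_steps):
            mx = -1e300
            for m in range(L):
                if not s[m] and lr[m] > mx:
                    mx = lr[m]
            Z = 0.0
            for m in range(L):
                if not s[m]:
                    Z += math.exp(lr[m] - mx)
            r = U[u_idx] * Z
            u_idx += 1
            c = 0.0
            chosen = -1
            for m in range(L):
                if not s[m]:
                    c += math.exp(lr[m] - mx)
                    if c > r:
                        chosen = m
                        break
            if chosen < 0:
                for m in range(L - 1, -1, -1):
                    if not s[m]:
                        chosen = m
                        break
            orders[p, k] = chosen
            s[chosen] = 1
            for m in range(L):
                lr[m] += theta[m, chosen]
    return orders
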