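"""The parameterized monotone walk on the L-hypercube.

A walk starts from some state and acquires one absent mode per step until it
reaches the all-ones state.  Acquisition of mode i from state s carries rate

    r_i(s) = exp(theta[i, i] + sum_{j acquired in s} theta[i, j])

so the diagonal of ``theta`` holds base log-rates and the off-diagonal entry
theta[i, j] is the additive log-rate modification to mode i once mode j is
on board (the standard two-way parameterization of hypercubic
trait-accumulation models).  Only the embedded jump chain matters for
acquisition orderings, so step probabilities are the rates normalized over
the absent modes; absolute dwell times are out of scope.

The module also provides an exact hitting-probability oracle: a dynamic
program over the sublattice between two states, feasible whenever the two
states differ in at most ``max_diff`` modes.  At L = 22 the full state space
(2^22) makes this a test-and-validation device, not a production likelihood.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.special import logsumexp

from .trait_data import State

DEFAULT_ORACLE_LIMIT = 14


def save_params(theta: np.ndarray, path, mode_names: list[str] | None = None,
                variant: str = "two_way") -> None:
    """Write a parameter matrix as CSV with a JSON sidecar.

    The sidecar records the mode order the rows/columns refer to and the
    model variant, so a matrix can never be silently reattached to the
    wrong trait list.
    """
    import json
    from pathlib import Path

    theta = validate_theta(theta)
    path = Path(path)
    np.savetxt(path, theta, delimiter=",")
    sidecar = {"n_modes": theta.shape[0],
               "mode_names": mode_names, "variant": variant}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def load_params(path) -> tuple[np.ndarray, dict]:
    """Read a parameter matrix and its JSON sidecar metadata."""
    import json
    from pathlib import Path

    path = Path(path)
    theta = validate_theta(np.loadtxt(path, delimiter=",", ndmin=2))
    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}
    if "n_modes" in meta and meta["n_modes"] != theta.shape[0]:
        raise ValueError("sidecar mode count does not match matrix dimension")
    return theta, meta


def validate_theta(theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] != theta.shape[1]:
        raise ValueError("theta must be a square matrix")
    if not np.isfinite(theta).all():
        raise ValueError("theta entries must be finite")
    return theta


def _log_rates(bits: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Log acquisition rates for every mode given acquired-bit vector(s).

    Accepts a single (L,) vector or a batch (n, L); present modes must be
    masked by the caller before normalization.
    """
    return bits @ theta.T + np.diag(theta)


def step_probabilities(s: State, theta: np.ndarray) -> np.ndarray:
    """Jump-chain probabilities over absent modes from state ``s``.

    Returns a length-L vector: zero at acquired modes, the normalized
    competing-exponential rates at absent modes.  Raises on the all-ones
    state, which has no outgoing moves.
    """
    theta = validate_theta(theta)
    bits = s.bits.astype(float)
    if len(s) != theta.shape[0]:
        raise ValueError("state length does not match theta dimension")
    absent = bits == 0
    if not absent.any():
        raise ValueError("no moves from the all-ones state")
    lr = _log_rates(bits, theta)
    lr = np.where(absent, lr, -np.inf)
    lr -= lr.max()
    p = np.exp(lr)
    return p / p.sum()


def simulate_path(theta: np.ndarray, start: State | None = None,
                  rng: np.random.Generator | None = None) -> list[int]:
    """One monotone walk to the all-ones state; returns acquired mode indices in order."""
    theta = validate_theta(theta)
    rng = np.random.default_rng() if rng is None else rng
    L = theta.shape[0]
    s = State.zero(L) if start is None else start
    path: list[int] = []
    while s.n_acquired < L:
        p = step_probabilities(s, theta)
        j = int(rng.choice(L, p=p))
        path.append(j)
        s = s.with_mode(j)
    return path


def simulate_orders(theta: np.ndarray, n_paths: int,
                    rng: np.random.Generator,
                    start: State | None = None) -> np.ndarray:
    """Vectorized batch of full monotone walks from ``start`` (default empty).

    Returns an integer array of shape (n_paths, n_steps): row p lists the
    modes acquired by walk p in order.  All walks share ``theta``.
    """
    from ._kernels import walk_orders
    theta = validate_theta(theta)
    L = theta.shape[0]
    start_bits = (np.zeros(L, dtype=np.uint8) if start is None
                  else start.bits.astype(np.uint8))
    n_steps = L - int(start_bits.sum())
    U = rng.random(n_paths * n_steps)
    return walk_orders(np.ascontiguousarray(start_bits),
                       np.ascontiguousarray(theta, dtype=float), n_paths, U)


def exact_hitting_probability(a: State, b: State, theta: np.ndarray,
                              max_diff: int = DEFAULT_ORACLE_LIMIT) -> float:
    """Probability that a walk from ``a`` passes through ``b``, by exact DP.

    Forward recursion over the sublattice {r : a <= r <= b}: f(a) = 1 and
    each state pushes its mass one acquisition at a time, with step
    probabilities normalized over *all* absent modes (including those
    outside b — that is what makes hitting b uncertain).  Feasible for
    |b \\ a| <= max_diff.
    """
    theta = validate_theta(theta)
    if not a <= b:
        raise ValueError("a must be a subset of b")
    diff = np.flatnonzero(b.bits & ~a.bits)
    d = diff.size
    if d == 0:
        return 1.0
    if d > max_diff:
        raise ValueError(
            f"sublattice has 2^{d} states (> 2^{max_diff}); use the path sampler"
        )
    L = len(a)
    base = a.bits.astype(float)
    diag = np.diag(theta)

    # f[mask] = probability the walk visits state a | diff-bits(mask)
    f = np.zeros(1 << d)
    f[0] = 1.0
    # enumerate masks in order of popcount so predecessors are final
    for size in range(d):
        for combo in combinations(range(d), size):
            mask = 0
            for c in combo:
                mask |= 1 << c
            if f[mask] == 0.0:
                continue
            bits = base.copy()
            for c in combo:
                bits[diff[c]] = 1.0
            lr = bits @ theta.T + diag
            lr = np.where(bits == 0, lr, -np.inf)
            logZ = logsumexp(lr)
            for c in range(d):
                if mask & (1 << c):
                    continue
                p_step = np.exp(lr[diff[c]] - logZ)
                f[mask | (1 << c)] += f[mask] * p_step
    return float(f[(1 << d) - 1])
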