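"""Importance-sampling estimator of hitting probabilities (the HyperTraPS core).

The probability that a monotone walk from state a passes through state b is
estimated by sampling *biased* walks that are forced to stay inside the
sublattice below b: at each step only moves towards b are proposed, chosen
proportionally to their true step probabilities, and the walk's importance
weight accumulates the compatible-move mass

    beta(r) = sum_{j in b\\r} P(j | r)

at every step.  The product of betas is an unbiased estimator of the exact
hitting probability (every sampled walk reaches b, so the estimate is
strictly positive whenever rates are finite).  Weights are accumulated in
log space; at L = 22 the raw products underflow double precision.

All estimators are vectorized: a dataset's observations are expanded into a
single batch of walkers advanced in lock step, which is what makes
pseudo-marginal MCMC affordable in pure numpy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .hypercube import exact_hitting_probability, validate_theta
from .trait_data import State, TransitionObservation


@dataclass(frozen=True)
class LikelihoodEstimate:
    """A Monte Carlo hitting-probability estimate with diagnostics."""

    value: float
    n_paths: int
    variance_estimate: float
    log_value: float

    @property
    def standard_error(self) -> float:
        return float(np.sqrt(self.variance_estimate / self.n_paths))


def _batch_log_weights(A: np.ndarray, B: np.ndarray, theta: np.ndarray,
                       n_paths: int, rng: np.random.Generator) -> np.ndarray:
    """Log importance weights for n_paths biased walks per (a, b) row pair.

    A, B: boolean arrays (n_obs, L) with A <= B rowwise.  Returns
    (n_obs * n_paths,) log weights, observation-major.  Each walker consumes
    one pre-drawn uniform per step, so output is a deterministic function of
    (inputs, rng state).
    """
    from ._kernels import walk_log_weights
    A8 = np.ascontiguousarray(A, dtype=np.uint8)
    B8 = np.ascontiguousarray(B, dtype=np.uint8)
    n_steps = int((B8.astype(np.int64) - A8.astype(np.int64)).sum()) * n_paths
    U = rng.random(n_steps)
    return walk_log_weights(A8, B8, np.ascontiguousarray(theta, dtype=float),
                            n_paths, U)


def _per_obs_log_estimates(A: np.ndarray, B: np.ndarray, theta: np.ndarray,
                           n_paths: int, rng: np.random.Generator) -> np.ndarray:
    logw = _batch_log_weights(A, B, theta, n_paths, rng)
    logw = logw.reshape(A.shape[0], n_paths)
    return logsumexp(logw, axis=1) - np.log(n_paths)


def sample_hitting_probability(a: State, b: State, theta: np.ndarray,
                               n_paths: int,
                               rng: np.random.Generator) -> LikelihoodEstimate:
    """Unbiased importance-sampling estimate of P(walk from a passes through b)."""
    theta = validate_theta(theta)
    if not a <= b:
        raise ValueError("irreversibility violated: a must be a subset of b")
    if n_paths < 1:
        raise ValueError("n_paths must be >= 1")
    A = a.bits.astype(bool)[None, :]
    B = b.bits.astype(bool)[None, :]
    logw = _batch_log_weights(A, B, theta, n_paths, rng)
    w = np.exp(logw)
    value = float(w.mean())
    var = float(w.var(ddof=1)) if n_paths > 1 else 0.0
    log_value = float(logsumexp(logw) - np.log(n_paths))
    return LikelihoodEstimate(value=value, n_paths=n_paths,
                              variance_estimate=var, log_value=log_value)


def _observation_arrays(obs: Sequence[TransitionObservation]):
    A = np.array([o.ancestor.bits for o in obs], dtype=bool)
    B = np.array([o.descendant.bits for o in obs], dtype=bool)
    w = np.array([o.weight for o in obs], dtype=float)
    return A, B, w


def dataset_log_likelihood(obs: Sequence[TransitionObservation],
                           theta: np.ndarray, n_paths: int,
                           rng: np.random.Generator) -> float:
    """Weighted sum of log hitting-probability estimates over a dataset.

    Degenerate observations (ancestor == descendant) contribute log 1 = 0.
    Each observation gets an independent fresh estimate, as pseudo-marginal
    MCMC requires.
    """
    theta = validate_theta(theta)
    live = [o for o in obs if not o.is_degenerate]
    if not live:
        return 0.0
    A, B, w = _observation_arrays(live)
    log_est = _per_obs_log_estimates(A, B, theta, n_paths, rng)
    return float(np.dot(w, log_est))


def dataset_log_likelihood_exact(obs: Sequence[TransitionObservation],
                                 theta: np.ndarray,
                                 max_diff: int = 14) -> float:
    """Exact counterpart of :func:`dataset_log_likelihood` via the DP oracle.

    Feasible only when every observation's ancestor/descendant differ in at
    most ``max_diff`` modes; used for validation and small-L inference.
    """
    theta = validate_theta(theta)
    total = 0.0
    for o in obs:
        if o.is_degenerate:
            continue
        p = exact_hitting_probability(o.ancestor, o.descendant, theta,
                                      max_diff=max_diff)
        total += o.weight * np.log(p)
    return float(total)
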