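"""Pseudo-marginal Metropolis-Hastings over the hypercube rate parameters.

The likelihood of a transition dataset is intractable at L = 22, so each
proposal is scored with a fresh unbiased importance-sampling estimate
(:mod:`hypertraps.sampler`).  Replacing the likelihood by an unbiased
estimate leaves the exact posterior invariant (the pseudo-marginal
construction), at the cost of extra acceptance noise controlled by the
per-observation path count.

Priors are independent uniforms on [-prior_bound, prior_bound] per theta
entry; proposals are a single symmetric Gaussian perturbation of the full
matrix.  No adaptation is used — a fixed kernel makes runs bit-reproducible
from their seed, which the whole downstream pipeline relies on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sampler import dataset_log_likelihood, dataset_log_likelihood_exact
from .trait_data import (TransitionObservation, observations_from_frame,
                         observations_to_frame)


@dataclass
class ChainConfig:
    """MCMC settings; defaults are desk-scale for L around 8.

    ``likelihood`` selects the pseudo-marginal sampled estimator ("sampled",
    the production route) or the exact sublattice DP ("exact", feasible only
    for small state differences and used for validation).
    """

    n_iterations: int = 50_000
    burn_in: int = 25_000
    thin: int = 50
    proposal_scale: float = 0.05
    prior_bound: float = 10.0
    n_paths: int = 200
    seed: int = 0
    likelihood: str = "sampled"

    def __post_init__(self):
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.proposal_scale <= 0 or self.prior_bound <= 0:
            raise ValueError("proposal_scale and prior_bound must be positive")
        if self.likelihood not in ("sampled", "exact"):
            raise ValueError("likelihood must be 'sampled' or 'exact'")


@dataclass
class PosteriorSample:
    """Retained draws from a (possibly continued) chain, plus restart state."""

    thetas: np.ndarray              # (n_retained, L, L)
    log_likelihoods: np.ndarray     # (n_retained,)
    iterations: np.ndarray          # absolute iteration index of each draw
    trace: np.ndarray               # per-iteration log-likelihood estimates
    acceptance_rate: float
    config: ChainConfig
    n_accepted: int
    n_proposed: int
    final_theta: np.ndarray
    final_log_likelihood: float
    rng_state: dict
    observations: list[TransitionObservation] = field(repr=False, default_factory=list)

    @property
    def n_modes(self) -> int:
        return self.final_theta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.thetas.shape[0]


def _log_likelihood(obs, theta, cfg: ChainConfig, rng) -> float:
    if cfg.likelihood == "exact":
        return dataset_log_likelihood_exact(obs, theta)
    return dataset_log_likelihood(obs, theta, cfg.n_paths, rng)


def run_chain(obs: Sequence[TransitionObservation], cfg: ChainConfig,
              rng: np.random.Generator | None = None) -> PosteriorSample:
    """Run pseudo-marginal Metropolis-Hastings from theta = 0.

    Out-of-prior proposals are rejected outright (without burning a
    likelihood estimate).  Identical seed and inputs give bit-identical
    output.
    """
    if not obs:
        raise ValueError("at least one transition observation is required")
    L = len(obs[0].ancestor)
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    theta = np.zeros((L, L))
    current_ll = _log_likelihood(obs, theta, cfg, rng)
    return _advance(list(obs), cfg, rng, theta, current_ll,
                    start_iteration=0, n_iterations=cfg.n_iterations,
                    prev=None)


def continue_chain(ps: PosteriorSample, extra_iterations: int,
                   rng: np.random.Generator | None = None) -> PosteriorSample:
    """Extend a chain; run(N) then continue(M) reproduces run(N+M) exactly.

    The stored generator state and current pseudo-marginal likelihood
    estimate are both part of the chain state and are restored verbatim.
    """
    if extra_iterations < 0:
        raise ValueError("extra_iterations must be >= 0")
    if extra_iterations == 0:
        return ps
    if rng is None:
        rng = np.random.default_rng()
        rng.bit_generator.state = ps.rng_state
    cfg = replace(ps.config, n_iterations=ps.config.n_iterations + extra_iterations)
    return _advance(ps.observations, cfg, rng,
                    ps.final_theta.copy(), ps.final_log_likelihood,
                    start_iteration=ps.config.n_iterations,
                    n_iterations=extra_iterations, prev=ps)


def _advance(obs, cfg: ChainConfig, rng, theta, current_ll,
             start_iteration: int, n_iterations: int,
             prev: PosteriorSample | None) -> PosteriorSample:
    L = theta.shape[0]
    kept_thetas, kept_lls, kept_iters, trace = [], [], [], []
    n_accepted = n_proposed = 0
    for step in range(n_iterations):
        it = start_iteration + step + 1
        proposal = theta + cfg.proposal_scale * rng.standard_normal((L, L))
        n_proposed += 1
        if np.abs(proposal).max() <= cfg.prior_bound:
            prop_ll = _log_likelihood(obs, proposal, cfg, rng)
            if np.log(rng.random()) < prop_ll - current_ll:
                theta, current_ll = proposal, prop_ll
                n_accepted += 1
        trace.append(current_ll)
        if it > cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            kept_thetas.append(theta.copy())
            kept_lls.append(current_ll)
            kept_iters.append(it)

    if prev is not None:
        thetas = np.concatenate([prev.thetas,
                                 np.array(kept_thetas).reshape(-1, L, L)])
        lls = np.concatenate([prev.log_likelihoods, np.array(kept_lls)])
        iters = np.concatenate([prev.iterations, np.array(kept_iters, dtype=int)])
        full_trace = np.concatenate([prev.trace, np.array(trace)])
        n_accepted += prev.n_accepted
        n_proposed += prev.n_proposed
    else:
        thetas = np.array(kept_thetas).reshape(-1, L, L)
        lls = np.array(kept_lls)
        iters = np.array(kept_iters, dtype=int)
        full_trace = np.array(trace)

    if n_proposed and n_accepted == 0:
        import warnings
        warnings.warn("no proposals accepted; consider a smaller proposal_scale",
                      stacklevel=2)
    return PosteriorSample(
        thetas=thetas, log_likelihoods=lls, iterations=iters, trace=full_trace,
        acceptance_rate=n_accepted / max(n_proposed, 1), config=cfg,
        n_accepted=n_accepted, n_proposed=n_proposed,
        final_theta=theta, final_log_likelihood=current_ll,
        rng_state=rng.bit_generator.state, observations=list(obs),
    )


def posterior_from_thetas(thetas: Sequence[np.ndarray]) -> PosteriorSample:
    """Wrap known parameter matrices as a degenerate posterior.

    Used to push a ground-truth theta (or any fixed parameter set) through
    the posterior-summary machinery.
    """
    arr = np.array([np.asarray(t, dtype=float) for t in thetas])
    L = arr.shape[1]
    cfg = ChainConfig(n_iterations=2, burn_in=1, thin=1)
    return PosteriorSample(
        thetas=arr, log_likelihoods=np.zeros(arr.shape[0]),
        iterations=np.arange(arr.shape[0]), trace=np.zeros(arr.shape[0]),
        acceptance_rate=1.0, config=cfg, n_accepted=0, n_proposed=0,
        final_theta=arr[-1].copy(), final_log_likelihood=0.0,
        rng_state=np.random.default_rng(0).bit_generator.state,
        observations=[],
    )


def save_posterior(ps: PosteriorSample, directory) -> None:
    """Serialize a posterior as CSVs plus a JSON metadata sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    L = ps.n_modes
    flat = ps.thetas.reshape(ps.n_samples, L * L)
    cols = [f"theta_{i}_{j}" for i in range(L) for j in range(L)]
    samples = pd.DataFrame(flat, columns=cols)
    samples.insert(0, "iteration", ps.iterations)
    samples.insert(1, "log_likelihood", ps.log_likelihoods)
    samples.to_csv(directory / "samples.csv", index=False)
    pd.DataFrame({"log_likelihood": ps.trace}).to_csv(
        directory / "trace.csv", index=False)
    observations_to_frame(ps.observations).to_csv(
        directory / "observations.csv", index=False)
    meta = {
        "config": ps.config.__dict__,
        "acceptance_rate": ps.acceptance_rate,
        "n_accepted": ps.n_accepted,
        "n_proposed": ps.n_proposed,
        "n_modes": L,
        "final_theta": ps.final_theta.tolist(),
        "final_log_likelihood": ps.final_log_likelihood,
        "rng_state": _jsonify(ps.rng_state),
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))


def load_posterior(directory) -> PosteriorSample:
    directory = Path(directory)
    meta = json.loads((directory / "metadata.json").read_text())
    L = meta["n_modes"]
    samples = pd.read_csv(directory / "samples.csv")
    thetas = samples[[c for c in samples.columns if c.startswith("theta_")]]
    obs_df = pd.read_csv(directory / "observations.csv",
                         dtype={"ancestor": str, "descendant": str})
    return PosteriorSample(
        thetas=thetas.to_numpy().reshape(-1, L, L),
        log_likelihoods=samples["log_likelihood"].to_numpy(),
        iterations=samples["iteration"].to_numpy(dtype=int),
        trace=pd.read_csv(directory / "trace.csv")["log_likelihood"].to_numpy(),
        acceptance_rate=meta["acceptance_rate"],
        config=ChainConfig(**meta["config"]),
        n_accepted=meta["n_accepted"], n_proposed=meta["n_proposed"],
        final_theta=np.array(meta["final_theta"]),
        final_log_likelihood=meta["final_log_likelihood"],
        rng_state=_unjsonify(meta["rng_state"]),
        observations=observations_from_frame(obs_df) if len(obs_df) else [],
    )


def _jsonify(state):
    if isinstance(state, dict):
        return {k: _jsonify(v) for k, v in state.items()}
    if isinstance(state, np.ndarray):
        return {"__ndarray__": state.tolist(), "dtype": str(state.dtype)}
    if isinstance(state, (np.integer,)):
        return int(state)
    return state


def _unjsonify(state):
    if isinstance(state, dict):
        if "__ndarray__" in state:
            return np.array(state["__ndarray__"], dtype=state["dtype"])
        return {k: _unjsonify(v) for k, v in state.items()}
    return state
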