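"""Predictions of unobserved and next-acquired tool-use modes.

Two simulation-based procedures, both driven by full monotone walks drawn
under each retained posterior parameter draw:

* *unobserved presence* — a visited state is compatible with a group's
  observation if it contains every observed presence (the absence marks may
  be unobserved modes, not genuine absences).  Pooling all compatible
  state-visits, the presence probability of an unobserved mode is the
  fraction of pooled visits in which it is present.  This adopts a uniform
  prior over which recorded absences are really unobserved presences;
  per-cell priors can be layered on top by reweighting the output.
* *next acquisition* — whenever a walk occupies exactly the observed state,
  the next acquired mode is recorded; normalizing gives the distribution of
  the next mode to emerge, conditional on the state being visited at all.

Because walks are monotone, compatibility is permanent once attained and a
state is visited at most once per walk, so both procedures reduce to closed
forms over each walk's acquisition positions — no state sets need to be
materialized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorSample
from .summaries import _posterior_orders
from .trait_data import State, TraitMatrix, binarize


@dataclass
class PredictionTable:
    """Taxa × modes probabilities with observed-cell markers."""

    probabilities: pd.DataFrame     # NaN where undefined / already observed
    observed: pd.DataFrame          # boolean: mode already observed in taxon
    kind: str                       # "unobserved_presence" | "next_acquisition"
    highlight_threshold: float

    def reweight(self, prior: pd.DataFrame) -> "PredictionTable":
        """Adjust presence probabilities by expert per-cell priors.

        ``prior`` holds, per (taxon, mode) cell, the prior probability that
        the recorded absence is really an unobserved presence; the default
        analysis is the uniform 0.5 for every cell.  Cells judged
        infeasible (prior 0) are forced to probability 0; the update is the
        standard odds reweighting p' = p q / (p q + (1 - p)(1 - q)).
        """
        if self.kind != "unobserved_presence":
            raise ValueError("only presence tables accept per-cell priors")
        q = prior.reindex(index=self.probabilities.index,
                          columns=self.probabilities.columns).fillna(0.5)
        p = self.probabilities
        adjusted = (p * q) / (p * q + (1 - p) * (1 - q))
        return PredictionTable(probabilities=adjusted, observed=self.observed,
                               kind=self.kind,
                               highlight_threshold=self.highlight_threshold)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for taxon in self.probabilities.index:
            for mode in self.probabilities.columns:
                p = self.probabilities.loc[taxon, mode]
                rows.append({
                    "taxon": taxon, "mode": mode, "probability": p,
                    "observed": bool(self.observed.loc[taxon, mode]),
                    "highlighted": bool(p > self.highlight_threshold)
                    if not np.isnan(p) else False,
                    "kind": self.kind,
                })
        return pd.DataFrame(rows)


def _positions(orders: np.ndarray) -> np.ndarray:
    """pos[p, m] = 1-based step at which walk p acquires mode m."""
    n, L = orders.shape
    pos = np.empty((n, L), dtype=np.int64)
    np.put_along_axis(pos, orders, np.arange(1, L + 1)[None, :].repeat(n, 0),
                      axis=1)
    return pos


def presence_from_orders(orders: np.ndarray, observed: State,
                         per_path: bool = False) -> np.ndarray:
    """Presence probabilities of modes not in ``observed`` from path orders.

    Default pooling counts each compatible state-visit once; ``per_path``
    instead gives each walk a single vote (its average over its own
    compatible visits).
    """
    n, L = orders.shape
    pos = _positions(orders)
    obs_idx = np.flatnonzero(observed.bits)
    # first step at which the walk's state contains every observed presence
    k0 = pos[:, obs_idx].max(axis=1) if obs_idx.size else np.zeros(n, dtype=np.int64)
    visits = L - k0 + 1                        # compatible states per walk
    present_counts = (L - np.maximum(k0[:, None], pos) + 1).astype(float)
    if per_path:
        contrib = (present_counts / visits[:, None]).sum(axis=0)
        total = float(n)
    else:
        contrib = present_counts.sum(axis=0)
        total = float(visits.sum())
    probs = contrib / total
    probs[obs_idx] = np.nan
    return probs


def next_from_orders(orders: np.ndarray,
                     observed: State) -> tuple[np.ndarray, float]:
    """Next-mode distribution and visitation frequency of ``observed``.

    A walk visits the observed state exactly when its first |observed|
    acquisitions are the observed mode set.  Returns (length-L distribution
    with NaN for walks-never-visit, visitation frequency).
    """
    n, L = orders.shape
    k = observed.n_acquired
    if k == L:
        raise ValueError("no next acquisition from the all-ones state")
    obs_idx = np.flatnonzero(observed.bits)
    if k == 0:
        hit = np.ones(n, dtype=bool)
    else:
        pos = _positions(orders)
        hit = pos[:, obs_idx].max(axis=1) == k
    n_hit = int(hit.sum())
    if n_hit == 0:
        return np.full(L, np.nan), 0.0
    nxt = orders[hit, k]
    dist = np.bincount(nxt, minlength=L).astype(float) / n_hit
    return dist, n_hit / n


def predict_unobserved(ps: PosteriorSample, observed: State,
                       paths_per_sample: int, rng: np.random.Generator,
                       per_path: bool = False) -> pd.Series:
    """Posterior probability that each unobserved mode is present (pooled visits)."""
    orders = _posterior_orders(ps, paths_per_sample, rng)
    probs = presence_from_orders(orders, observed, per_path=per_path)
    return pd.Series(probs, index=[f"mode_{i}" for i in range(len(observed))])


def predict_next(ps: PosteriorSample, observed: State,
                 paths_per_sample: int,
                 rng: np.random.Generator) -> tuple[pd.Series, float]:
    """Distribution over the next acquired mode from the observed state."""
    orders = _posterior_orders(ps, paths_per_sample, rng)
    dist, freq = next_from_orders(orders, observed)
    return pd.Series(dist, index=[f"mode_{i}" for i in range(len(observed))]), freq


def prediction_tables(ps: PosteriorSample, m: TraitMatrix,
                      paths_per_sample: int, rng: np.random.Generator,
                      include_human_influenced: bool = True,
                      highlight_threshold: float = 0.90,
                      per_path: bool = False
                      ) -> tuple[PredictionTable, PredictionTable]:
    """Both prediction tables for every taxon in a trait matrix.

    A single shared batch of simulated walks serves all taxa.  Taxa with
    every mode observed are excluded from the next-acquisition table (there
    is nothing left to acquire); cells whose state was never visited in the
    simulation budget are reported as NaN.  Presence probabilities above
    ``highlight_threshold`` (default 0.90) are flagged.
    """
    binary = binarize(m, include_human_influenced=include_human_influenced)
    orders = _posterior_orders(ps, paths_per_sample, rng)
    L = m.n_modes
    pres = pd.DataFrame(np.nan, index=m.taxa, columns=m.modes)
    nxt = pd.DataFrame(np.nan, index=m.taxa, columns=m.modes)
    observed_mask = pd.DataFrame(binary.to_numpy().astype(bool),
                                 index=m.taxa, columns=m.modes)
    for taxon in m.taxa:
        state = State(binary.loc[taxon].to_numpy())
        if state.n_acquired < L:
            pres.loc[taxon] = presence_from_orders(orders, state,
                                                   per_path=per_path)
            dist, _freq = next_from_orders(orders, state)
            dist = dist.copy()
            dist[state.bits == 1] = np.nan
            nxt.loc[taxon] = dist
    full = observed_mask.all(axis=1)
    nxt = nxt.loc[~full]
    presence_table = PredictionTable(probabilities=pres, observed=observed_mask,
                                     kind="unobserved_presence",
                                     highlight_threshold=highlight_threshold)
    next_table = PredictionTable(probabilities=nxt,
                                 observed=observed_mask.loc[~full],
                                 kind="next_acquisition",
                                 highlight_threshold=highlight_threshold)
    return presence_table, next_table
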