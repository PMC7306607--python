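"""Trait observation tables, coarse taxonomies, and transition observations.

The raw input is a ternary taxon-by-mode table: 0 = mode never observed,
1 = observed in the wild, 2 = observed but human influence cannot be
discounted.  Modes are treated as binary traits that a lineage acquires
irreversibly, so every usable likelihood unit is an (ancestor state,
descendant state) pair with ancestor ⊆ descendant.

Two limiting treatments of shared traits are supported:

* *inherited* — traits shared across sibling clades are attributed to their
  common ancestor.  Ancestral states are the elementwise AND of descendant
  states (the maximal state that never asserts an unobserved acquisition),
  and each tree edge contributes one transition observation.
* *convergent* — every observed group is assumed to have acquired its traits
  independently, contributing a single transition from the all-zero state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("aquatic", "primate", "bird", "rank")

_VALID_ENTRIES = (0, 1, 2)


class State:
    """Immutable vertex of the L-dimensional hypercube (a 0/1 acquisition pattern)."""

    __slots__ = ("_bits",)

    def __init__(self, bits: Iterable[int]):
        arr = np.asarray(list(bits) if not isinstance(bits, np.ndarray) else bits,
                         dtype=np.uint8)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("State requires a non-empty 1-D bit vector")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("State bits must be 0 or 1")
        arr = arr.copy()
        arr.setflags(write=False)
        self._bits = arr

    @classmethod
    def zero(cls, length: int) -> "State":
        return cls(np.zeros(length, dtype=np.uint8))

    @classmethod
    def ones(cls, length: int) -> "State":
        return cls(np.ones(length, dtype=np.uint8))

    @classmethod
    def from_bitstring(cls, s: str) -> "State":
        return cls([int(c) for c in s])

    @property
    def bits(self) -> np.ndarray:
        return self._bits

    @property
    def n_acquired(self) -> int:
        return int(self._bits.sum())

    def bitstring(self) -> str:
        return "".join(str(int(b)) for b in self._bits)

    def with_mode(self, index: int) -> "State":
        """Return the state with one additional acquired mode."""
        if self._bits[index]:
            raise ValueError(f"mode {index} already acquired")
        arr = self._bits.copy()
        arr[index] = 1
        return State(arr)

    def __len__(self) -> int:
        return self._bits.size

    def __eq__(self, other) -> bool:
        return isinstance(other, State) and np.array_equal(self._bits, other._bits)

    def __hash__(self) -> int:
        return hash(self._bits.tobytes())

    def __le__(self, other: "State") -> bool:
        """Subset order: every acquired mode of self is acquired in other."""
        return bool(np.all(self._bits <= other._bits))

    def __repr__(self) -> str:
        return f"State({self.bitstring()})"


@dataclass(frozen=True)
class TransitionObservation:
    """An (ancestor, descendant) pair: the unit of likelihood.

    The walk is monotone, so the ancestor must be a subset of the descendant;
    a pair with ancestor == descendant is degenerate and contributes
    likelihood 1.
    """

    ancestor: State
    descendant: State
    weight: float = 1.0

    def __post_init__(self):
        if len(self.ancestor) != len(self.descendant):
            raise ValueError("ancestor and descendant must have equal length")
        if not self.ancestor <= self.descendant:
            raise ValueError(
                "irreversibility violated: ancestor "
                f"{self.ancestor.bitstring()} is not a subset of descendant "
                f"{self.descendant.bitstring()}"
            )
        if not self.weight > 0:
            raise ValueError("weight must be positive")

    @property
    def is_degenerate(self) -> bool:
        return self.ancestor == self.descendant


@dataclass
class TraitMatrix:
    """Ternary observations of L tool-use modes across taxonomic groups.

    ``values`` is a taxa × modes integer table with entries in {0, 1, 2};
    ``annotations`` carries the per-taxon aquatic/primate/bird flags and the
    taxonomic rank at which the observation was catalogued.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self):
        vals = self.values.to_numpy()
        if vals.size and not np.isin(vals, _VALID_ENTRIES).all():
            bad = np.argwhere(~np.isin(vals, _VALID_ENTRIES))[0]
            raise ValueError(
                f"entry {vals[bad[0], bad[1]]!r} at taxon "
                f"{self.values.index[bad[0]]!r}, mode "
                f"{self.values.columns[bad[1]]!r} is not one of 0/1/2"
            )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate taxon name: {dup!r}")
        if self.values.columns.duplicated().any():
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate mode name: {dup!r}")
        if len(self.values.columns) < 1:
            raise ValueError("at least one mode column is required")
        missing = set(ANNOTATION_COLUMNS) - set(self.annotations.columns)
        if missing:
            raise ValueError(f"annotations missing keys: {sorted(missing)}")
        if not self.annotations.index.equals(self.values.index):
            raise ValueError("annotation rows must match value rows")

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def modes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_modes(self) -> int:
        return len(self.values.columns)

    def to_csv(self, path) -> None:
        out = pd.concat([self.values, self.annotations], axis=1)
        out.index.name = "taxon"
        out.to_csv(path)


def read_trait_matrix(path) -> TraitMatrix:
    """Read a trait matrix CSV: taxon column, L mode columns, then annotations."""
    raw = pd.read_csv(path, index_col=0)
    missing = set(ANNOTATION_COLUMNS) - set(raw.columns)
    if missing:
        raise ValueError(f"annotation columns missing from {path}: {sorted(missing)}")
    mode_cols = [c for c in raw.columns if c not in ANNOTATION_COLUMNS]
    values = raw[mode_cols]
    try:
        values = values.astype(int)
    except (TypeError, ValueError):
        for col in mode_cols:
            coerced = pd.to_numeric(values[col], errors="coerce")
            bad = coerced.isna() | (coerced != coerced.round())
            if bad.any():
                raise ValueError(
                    f"malformed entry {values[col][bad].iloc[0]!r} at taxon "
                    f"{values.index[bad][0]!r}, mode {col!r}"
                ) from None
        values = values.astype(int)
    annotations = raw[list(ANNOTATION_COLUMNS)].copy()
    for flag in ("aquatic", "primate", "bird"):
        annotations[flag] = annotations[flag].astype(bool)
    return TraitMatrix(values=values, annotations=annotations)


def binarize(m: TraitMatrix, include_human_influenced: bool = True) -> pd.DataFrame:
    """Collapse the ternary table to presence/absence.

    Wild observations (1) are always presences; human-influence-possible
    observations (2) are presences only when the flag is set.
    """
    vals = m.values.to_numpy()
    if include_human_influenced:
        binary = (vals >= 1).astype(np.uint8)
    else:
        binary = (vals == 1).astype(np.uint8)
    return pd.DataFrame(binary, index=m.values.index, columns=m.values.columns)


def subset(m: TraitMatrix, predicate) -> TraitMatrix:
    """Row-filter a trait matrix by an annotation predicate.

    ``predicate`` is either a callable taking the annotation row (as a dict)
    or a mapping {key: value or list-of-values}.  Modes are never filtered:
    a subset in which a mode has no positive observations simply carries no
    information about it (the prior is recovered).
    """
    if callable(predicate):
        keep = m.annotations.apply(lambda row: bool(predicate(row.to_dict())), axis=1)
    else:
        for key in predicate:
            if key not in m.annotations.columns:
                raise KeyError(f"unknown annotation key: {key!r}")
        keep = pd.Series(True, index=m.annotations.index)
        for key, val in predicate.items():
            allowed = val if isinstance(val, (list, tuple, set, frozenset)) else [val]
            keep &= m.annotations[key].isin(list(allowed))
    if not keep.any():
        raise ValueError("subset predicate matched no taxa; relax the filter")
    return TraitMatrix(values=m.values.loc[keep].copy(),
                       annotations=m.annotations.loc[keep].copy())


class Taxonomy:
    """A rooted coarse taxonomy with named nodes.

    Observed groups are matched to tree nodes (leaf or internal — catalogued
    observations range from species to orders) by exact name.  Unnamed
    internal nodes are assigned stable surrogate labels on load.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        if tree.seed_node is None:
            raise ValueError("taxonomy must have a root")
        self._label_to_node: dict[str, dendropy.Node] = {}
        counter = 0
        for node in tree.preorder_node_iter():
            label = node.taxon.label if node.taxon is not None else node.label
            if label is None:
                label = f"__node{counter}"
                node.label = label
                counter += 1
            label = label.replace(" ", "_")
            if node.taxon is not None:
                node.taxon.label = label
            else:
                node.label = label
            if label in self._label_to_node:
                raise ValueError(f"duplicate node label in taxonomy: {label!r}")
            self._label_to_node[label] = node

    @classmethod
    def read_newick(cls, path) -> "Taxonomy":
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
        return cls(tree)

    @classmethod
    def from_newick_string(cls, newick: str) -> "Taxonomy":
        tree = dendropy.Tree.get(data=newick, schema="newick",
                                 preserve_underscores=True,
                                 suppress_internal_node_taxa=True)
        return cls(tree)

    def node_label(self, node: dendropy.Node) -> str:
        return node.taxon.label if node.taxon is not None else node.label

    def node_for(self, name: str) -> dendropy.Node:
        try:
            return self._label_to_node[name]
        except KeyError:
            raise KeyError(f"taxon {name!r} not found in taxonomy") from None

    @property
    def labels(self) -> list[str]:
        return list(self._label_to_node)

    def edges(self) -> list[tuple[str, str]]:
        """(parent label, child label) for every edge, preorder."""
        out = []
        for node in self.tree.preorder_node_iter():
            for child in node.child_nodes():
                out.append((self.node_label(node), self.node_label(child)))
        return out

    def n_edges(self) -> int:
        return len(self.edges())


def reconstruct_ancestors(binary_table: pd.DataFrame,
                          taxonomy: Taxonomy) -> dict[str, State]:
    """Assign a state to every tree node under the inherited limiting case.

    Observed nodes carry their observed state directly.  An unobserved node
    carries the elementwise AND of its mapped descendants' states — the
    unique maximal ancestor that never asserts an acquisition no descendant
    shows.  Nodes with no observation and no mapped descendants default to
    the all-zero state (logged, not fatal).
    """
    L = binary_table.shape[1]
    observed = {taxon: np.asarray(binary_table.loc[taxon].to_numpy(), dtype=np.uint8)
                for taxon in binary_table.index}
    for taxon in observed:
        taxonomy.node_for(taxon)  # raises if unmapped

    states: dict[str, np.ndarray | None] = {}
    for node in taxonomy.tree.postorder_node_iter():
        label = taxonomy.node_label(node)
        if label in observed:
            states[label] = observed[label]
            continue
        child_states = [states[taxonomy.node_label(c)] for c in node.child_nodes()]
        child_states = [s for s in child_states if s is not None]
        if not child_states:
            states[label] = None
            continue
        acc = child_states[0].copy()
        for s in child_states[1:]:
            acc &= s
        states[label] = acc

    out: dict[str, State] = {}
    for label, arr in states.items():
        if arr is None:
            logger.info("node %r has no mapped descendants; assigned all-zero state",
                        label)
            arr = np.zeros(L, dtype=np.uint8)
        out[label] = State(arr)
    return out


def transitions_inherited(ancestors: Mapping[str, State],
                          taxonomy: Taxonomy,
                          keep_identical: bool = True) -> list[TransitionObservation]:
    """One transition observation per tree edge under the inherited case.

    Edges whose endpoints carry identical states contribute likelihood 1;
    they are retained by default so dataset weights are stable across
    subsets.
    """
    out = []
    for parent, child in taxonomy.edges():
        a, d = ancestors[parent], ancestors[child]
        if not a <= d:
            raise RuntimeError(
                f"internal error: reconstructed ancestor {parent!r} "
                f"({a.bitstring()}) is not a subset of {child!r} ({d.bitstring()})"
            )
        if a == d and not keep_identical:
            continue
        out.append(TransitionObservation(ancestor=a, descendant=d, weight=1.0))
    return out


def transitions_convergent(binary_table: pd.DataFrame) -> list[TransitionObservation]:
    """One transition from the all-zero state per observed taxon (convergent case)."""
    L = binary_table.shape[1]
    zero = State.zero(L)
    return [
        TransitionObservation(ancestor=zero,
                              descendant=State(binary_table.loc[t].to_numpy()),
                              weight=1.0)
        for t in binary_table.index
    ]


def observations_to_frame(obs: Iterable[TransitionObservation]) -> pd.DataFrame:
    """Serialize transition observations as bitstring rows (CSV-friendly)."""
    rows = [(o.ancestor.bitstring(), o.descendant.bitstring(), o.weight) for o in obs]
    return pd.DataFrame(rows, columns=["ancestor", "descendant", "weight"])


def observations_from_frame(df: pd.DataFrame) -> list[TransitionObservation]:
    return [
        TransitionObservation(State.from_bitstring(r.ancestor),
                              State.from_bitstring(r.descendant),
                              float(r.weight))
        for r in df.itertuples()
    ]


def load_packaged_matrix() -> TraitMatrix:
    """The packaged tool-use trait matrix (22 modes × coarse animal groups).

    The mode list is the catalogued 22 tool-use modes; the observation
    pattern is a synthetic stand-in assembled from groups and behaviours
    named in the source literature, not a transcription of any published
    observation table.
    """
    ref = resources.files("hypertraps.data") / "tool_use_matrix_synthetic.csv"
    with resources.as_file(ref) as path:
        return read_trait_matrix(path)


def load_packaged_taxonomy() -> Taxonomy:
    """The packaged coarse taxonomy (synthetic stand-in, mirrors common-tree shape)."""
    ref = resources.files("hypertraps.data") / "taxonomy_synthetic.nwk"
    with resources.as_file(ref) as path:
        return Taxonomy.read_newick(path)
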