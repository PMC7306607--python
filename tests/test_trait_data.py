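import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hypertraps as ht
from hypertraps.synthetic import random_taxonomy
from hypertraps.trait_data import (State, TransitionObservation,
                                   observations_from_frame,
                                   observations_to_frame)

from conftest import matrix_from_csv_text


class TestState:
    def test_subset_order_and_identity(self):
        a = State([1, 0, 0])
        b = State([1, 1, 0])
        assert a <= b and not b <= a
        assert a == State.from_bitstring("100")
        assert hash(a) == hash(State([1, 0, 0]))
        assert State.zero(3).n_acquired == 0
        assert State.ones(3).bitstring() == "111"

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            State([0, 2, 1])

    def test_bits_are_immutable(self):
        s = State([0, 1])
        with pytest.raises(ValueError):
            s.bits[0] = 1


class TestTransitionObservation:
    def test_irreversibility_enforced(self):
        with pytest.raises(ValueError, match="irreversibility"):
            TransitionObservation(State([1, 0]), State([0, 1]))

    def test_positive_weight_required(self):
        with pytest.raises(ValueError):
            TransitionObservation(State([0, 0]), State([1, 0]), weight=0.0)

    def test_round_trip_frame(self):
        obs = [TransitionObservation(State([0, 0]), State([1, 1]), 2.0)]
        back = observations_from_frame(observations_to_frame(obs))
        assert back[0].ancestor == obs[0].ancestor
        assert back[0].descendant == obs[0].descendant
        assert back[0].weight == 2.0


class TestReadTraitMatrix:
    def test_round_trip(self, tiny_matrix, tmp_path):
        path = tmp_path / "m.csv"
        tiny_matrix.to_csv(path)
        again = ht.read_trait_matrix(path)
        pd.testing.assert_frame_equal(again.values, tiny_matrix.values)
        pd.testing.assert_frame_equal(again.annotations, tiny_matrix.annotations)

    def test_invalid_entry_names_row_and_column(self):
        text = ("taxon,poke,drop,aquatic,primate,bird,rank\n"
                "wren,1,3,False,False,True,family\n")
        with pytest.raises(ValueError, match="wren.*drop|drop.*wren"):
            matrix_from_csv_text(text)

    def test_duplicate_taxon_rejected(self):
        text = ("taxon,poke,aquatic,primate,bird,rank\n"
                "wren,1,False,False,True,family\n"
                "wren,0,False,False,True,family\n")
        with pytest.raises(ValueError, match="duplicate taxon"):
            matrix_from_csv_text(text)

    def test_missing_annotations_rejected(self):
        with pytest.raises(ValueError, match="annotation"):
            matrix_from_csv_text("taxon,poke\nwren,1\n")


class TestBinarize:
    def test_human_influence_flag_semantics(self, tiny_matrix):
        with_flag = ht.binarize(tiny_matrix, include_human_influenced=True)
        without = ht.binarize(tiny_matrix, include_human_influenced=False)
        # value 2 kept only when the flag is set; value 1 always kept
        assert with_flag.loc["wren", "carry"] == 1
        assert without.loc["wren", "carry"] == 0
        assert without.loc["wren", "poke"] == 1

    @given(st.lists(st.integers(0, 2), min_size=6, max_size=6))
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_flag(self, entries):
        values = pd.DataFrame(np.array(entries).reshape(2, 3),
                              index=["a", "b"], columns=["x", "y", "z"])
        ann = pd.DataFrame({"aquatic": False, "primate": False, "bird": False,
                            "rank": "genus"}, index=values.index)
        m = ht.TraitMatrix(values=values, annotations=ann)
        narrow = ht.binarize(m, include_human_influenced=False).to_numpy()
        wide = ht.binarize(m, include_human_influenced=True).to_numpy()
        assert (narrow <= wide).all()


def _binary_frame(rows: dict[str, str]) -> pd.DataFrame:
    return pd.DataFrame({t: [int(c) for c in bits] for t, bits in rows.items()}
                        ).T.rename(columns=lambda i: f"m{i}")


class TestReconstructAncestors:
    def test_parent_is_bitwise_and(self):
        tx = ht.Taxonomy.from_newick_string("((a,b)p,c)root;")
        table = _binary_frame({"a": "1100", "b": "1010", "c": "0001"})
        anc = ht.reconstruct_ancestors(table, tx)
        assert anc["p"] == State.from_bitstring("1000")

    def test_single_child_passes_through(self):
        tx = ht.Taxonomy.from_newick_string("((a)p,c)root;")
        table = _binary_frame({"a": "0110", "c": "0000"})
        anc = ht.reconstruct_ancestors(table, tx)
        assert anc["p"] == State.from_bitstring("0110")

    def test_three_level_tree_root(self):
        tx = ht.Taxonomy.from_newick_string("(((a,b)ab,c)abc)root;")
        table = _binary_frame({"a": "1100", "b": "1110", "c": "0111"})
        anc = ht.reconstruct_ancestors(table, tx)
        assert anc["ab"] == State.from_bitstring("1100")
        assert anc["abc"] == State.from_bitstring("0100")
        assert anc["root"] == State.from_bitstring("0100")

    def test_matches_brute_force_and_over_subtrees(self):
        # exhaustive oracle: each node's state is the AND over every observed
        # leaf below it, on random trees
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(4, 30))
            tx = random_taxonomy(n, rng)
            L = int(rng.integers(2, 8))
            leaves = [tx.node_label(nd) for nd in tx.tree.leaf_node_iter()]
            table = pd.DataFrame(rng.integers(0, 2, (len(leaves), L)),
                                 index=leaves,
                                 columns=[f"m{i}" for i in range(L)])
            anc = ht.reconstruct_ancestors(table, tx)
            for node in tx.tree.preorder_node_iter():
                below = [tx.node_label(lf) for lf in node.leaf_iter()]
                expected = np.ones(L, dtype=np.uint8)
                for lf in below:
                    expected &= table.loc[lf].to_numpy().astype(np.uint8)
                assert anc[tx.node_label(node)] == State(expected)

    def test_idempotent_on_reconstructed_leaves(self):
        tx = ht.Taxonomy.from_newick_string("((a,b)p,(c,d)q)root;")
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.integers(0, 2, (4, 5)),
                             index=["a", "b", "c", "d"],
                             columns=[f"m{i}" for i in range(5)])
        anc1 = ht.reconstruct_ancestors(table, tx)
        anc2 = ht.reconstruct_ancestors(table, tx)
        assert anc1 == anc2


class TestTransitions:
    def test_inherited_chain(self):
        tx = ht.Taxonomy.from_newick_string("((leaf)mid)root;")
        table = _binary_frame({"leaf": "1100", "mid": "1000", "root": "0000"})
        anc = ht.reconstruct_ancestors(table, tx)
        obs = ht.transitions_inherited(anc, tx)
        pairs = {(o.ancestor.bitstring(), o.descendant.bitstring()) for o in obs}
        assert pairs == {("0000", "1000"), ("1000", "1100")}

    def test_inherited_star(self):
        tx = ht.Taxonomy.from_newick_string("(a,b,c)root;")
        table = _binary_frame({"a": "110", "b": "101", "c": "100"})
        anc = ht.reconstruct_ancestors(table, tx)
        obs = ht.transitions_inherited(anc, tx)
        assert len(obs) == 3
        assert all(o.ancestor == State.from_bitstring("100") for o in obs)

    def test_inherited_matches_edge_walker(self, packaged_matrix,
                                           packaged_taxonomy):
        # independent per-edge enumeration over the dendropy structure
        binary = ht.binarize(packaged_matrix)
        anc = ht.reconstruct_ancestors(binary, packaged_taxonomy)
        obs = ht.transitions_inherited(anc, packaged_taxonomy)
        expected = []
        for node in packaged_taxonomy.tree.preorder_node_iter():
            for child in node.child_nodes():
                expected.append((anc[packaged_taxonomy.node_label(node)],
                                 anc[packaged_taxonomy.node_label(child)]))
        assert len(obs) == packaged_taxonomy.n_edges() == len(expected)
        assert [(o.ancestor, o.descendant) for o in obs] == expected

    def test_convergent_counts_and_root(self, tiny_matrix):
        binary = ht.binarize(tiny_matrix)
        obs = ht.transitions_convergent(binary)
        assert len(obs) == len(tiny_matrix.taxa)
        assert all(o.ancestor == State.zero(3) for o in obs)
        # all-zero taxon gives a degenerate observation
        slug = obs[tiny_matrix.taxa.index("slug")]
        assert slug.is_degenerate

    def test_every_observation_is_monotone(self, packaged_matrix,
                                           packaged_taxonomy):
        binary = ht.binarize(packaged_matrix)
        anc = ht.reconstruct_ancestors(binary, packaged_taxonomy)
        for o in (ht.transitions_inherited(anc, packaged_taxonomy)
                  + ht.transitions_convergent(binary)):
            assert o.ancestor <= o.descendant


class TestSubset:
    def test_flag_filter(self, tiny_matrix):
        aq = ht.subset(tiny_matrix, {"aquatic": True})
        assert aq.taxa == ["slug"]
        assert aq.modes == tiny_matrix.modes  # modes never filtered

    def test_rank_filter(self, packaged_matrix):
        fam = ht.subset(packaged_matrix,
                        {"rank": ["family", "genus", "species"]})
        assert 0 < len(fam.taxa) < len(packaged_matrix.taxa)
        assert set(fam.annotations["rank"]) <= {"family", "genus", "species"}

    def test_callable_predicate(self, tiny_matrix):
        sub = ht.subset(tiny_matrix, lambda ann: ann["bird"] or ann["primate"])
        assert sorted(sub.taxa) == ["ape", "wren"]

    def test_empty_result_is_an_error(self, tiny_matrix):
        with pytest.raises(ValueError, match="no taxa"):
            ht.subset(tiny_matrix, lambda ann: False)

    def test_unknown_key_is_an_error(self, tiny_matrix):
        with pytest.raises(KeyError):
            ht.subset(tiny_matrix, {"habitat": "reef"})
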