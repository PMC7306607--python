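from itertools import permutations

import numpy as np
import pandas as pd
import pytest

import hypertraps as ht
from hypertraps.inference import posterior_from_thetas
from hypertraps.prediction import (next_from_orders, prediction_tables,
                                   presence_from_orders)
from hypertraps.trait_data import State


def all_orders(L: int) -> np.ndarray:
    """Every full acquisition order once: the uniform-model path ensemble."""
    return np.array(list(permutations(range(L))), dtype=np.int64)


class TestPresencePooling:
    def test_l2_pooled_presence_is_two_thirds(self):
        # observed {mode 0}: order (0,1) contributes visits 10, 11 and order
        # (1,0) contributes only 11, so mode 1 is present in 2 of 3 visits
        orders = np.array([[0, 1], [1, 0]])
        probs = presence_from_orders(orders, State([1, 0]))
        assert np.isnan(probs[0])
        assert probs[1] == pytest.approx(2 / 3)

    def test_per_path_pooling_variant(self):
        # one vote per path: path (0,1) votes 1/2 for mode 1, path (1,0)
        # votes 1 (its only compatible visit has mode 1 present)
        orders = np.array([[0, 1], [1, 0]])
        probs = presence_from_orders(orders, State([1, 0]), per_path=True)
        assert probs[1] == pytest.approx(0.75)

    def test_empty_observation_matches_enumeration_at_l3(self):
        # every visited state is compatible; enumerate all 6 orders and all
        # 4 states per path by hand
        orders = all_orders(3)
        expected = np.zeros(3)
        n_visits = 0
        for path in orders:
            states = [set()]
            for j in path:
                states.append(states[-1] | {j})
            for s in states:
                n_visits += 1
                for m in s:
                    expected[m] += 1
        probs = presence_from_orders(orders, State.zero(3))
        np.testing.assert_allclose(probs, expected / n_visits)

    def test_uniform_monotone_in_observed_size(self):
        # under the uniform model, observing more modes can only raise the
        # presence probability of any remaining mode (enumeration at L = 4)
        orders = all_orders(4)
        for m in range(4):
            others = [i for i in range(4) if i != m]
            for k in range(len(others)):
                small = np.zeros(4, dtype=int)
                small[others[:k]] = 1
                big = small.copy()
                big[others[k]] = 1
                p_small = presence_from_orders(orders, State(small))[m]
                p_big = presence_from_orders(orders, State(big))[m]
                assert p_big >= p_small - 1e-12


class TestNextAcquisition:
    def test_empty_state_uniform(self):
        dist, freq = next_from_orders(all_orders(4), State.zero(4))
        np.testing.assert_allclose(dist, 0.25)
        assert freq == 1.0

    def test_matches_first_step_probabilities(self, rng):
        theta = rng.normal(0, 1, (4, 4))
        orders = ht.simulate_orders(theta, 40_000, rng)
        dist, _ = next_from_orders(orders, State.zero(4))
        expected = ht.step_probabilities(State.zero(4), theta)
        np.testing.assert_allclose(dist, expected, atol=0.01)

    def test_uniform_two_observed_enumeration(self):
        # observed {0, 1}: visited by 4 of 24 orders (1/6, matching the
        # exact hitting probability); next mode is 2 or 3 equally
        dist, freq = next_from_orders(all_orders(4), State([1, 1, 0, 0]))
        assert freq == pytest.approx(1 / 6)
        np.testing.assert_allclose(dist[[2, 3]], 0.5)
        np.testing.assert_allclose(dist[[0, 1]], 0.0)

    def test_all_ones_rejected(self):
        with pytest.raises(ValueError):
            next_from_orders(all_orders(3), State.ones(3))

    def test_never_visited_reports_missing(self):
        orders = np.array([[0, 1, 2]])  # only one realized order
        dist, freq = next_from_orders(orders, State([0, 1, 0]))
        assert freq == 0.0
        assert np.isnan(dist).all()


class TestPredictionTables:
    @pytest.fixture
    def posterior(self):
        return posterior_from_thetas([np.zeros((3, 3))])

    @pytest.fixture
    def matrix(self):
        values = pd.DataFrame(
            [[1, 0, 0], [1, 1, 1], [0, 0, 0]],
            index=pd.Index(["partial", "complete", "naive"], name="taxon"),
            columns=["m0", "m1", "m2"])
        ann = pd.DataFrame({"aquatic": False, "primate": False,
                            "bird": False, "rank": "genus"},
                           index=values.index)
        return ht.TraitMatrix(values=values, annotations=ann)

    def test_tables_shapes_and_exclusions(self, posterior, matrix, rng):
        presence, nxt = prediction_tables(posterior, matrix, 2000, rng)
        # fully observed taxa are excluded from next-acquisition
        assert "complete" not in nxt.probabilities.index
        assert "partial" in nxt.probabilities.index
        # observed cells carry no presence probability
        assert np.isnan(presence.probabilities.loc["partial", "m0"])
        assert presence.observed.loc["partial", "m0"]
        # next-acquisition rows sum to one over unobserved modes
        row = nxt.probabilities.loc["partial"].dropna()
        assert row.sum() == pytest.approx(1.0)

    def test_highlighting_threshold(self, posterior, matrix, rng):
        presence, _ = prediction_tables(posterior, matrix, 500, rng,
                                        highlight_threshold=0.2)
        long = presence.to_long()
        defined = long.dropna(subset=["probability"])
        assert (defined["highlighted"]
                == (defined["probability"] > 0.2)).all()

    def test_predict_functions_agree_with_enumeration(self):
        # uniform L = 2: pooled presence of the unobserved mode is 2/3
        ps2 = posterior_from_thetas([np.zeros((2, 2))])
        probs = ht.predict_unobserved(ps2, State([1, 0]), 50_000,
                                      np.random.default_rng(0))
        assert probs.iloc[1] == pytest.approx(2 / 3, abs=0.01)
        dist, freq = ht.predict_next(ps2, State.zero(2), 5000,
                                     np.random.default_rng(1))
        np.testing.assert_allclose(dist, 0.5, atol=0.03)
        assert freq == 1.0

    def test_held_out_presences_rank_above_absences(self):
        # taxa truncated from known dynamics: the unobserved-presence score
        # of modes the full path really contains should exceed that of
        # modes it does not
        theta = ht.make_chain_params(6, 3.0)
        spec = ht.GeneratorSpec(L=6, regime="chain", strength=3.0, n_taxa=30,
                                stop_range=(2, 4), seed=5)
        m, truth = ht.simulate_dataset(spec)
        ps = posterior_from_thetas([theta])
        rng = np.random.default_rng(6)
        presence, _ = prediction_tables(ps, m, 2000, rng)
        scores_present, scores_absent = [], []
        for t, taxon in enumerate(m.taxa):
            stop = truth.stop_sizes[t]
            future = set(truth.orders[t, stop:stop + 2])  # held-out truths
            row = presence.probabilities.loc[taxon]
            for i, mode in enumerate(m.modes):
                p = row[mode]
                if np.isnan(p):
                    continue
                (scores_present if i in future else scores_absent).append(p)
        assert np.mean(scores_present) > np.mean(scores_absent)


class TestPriorReweighting:
    def test_uniform_prior_is_identity_and_zero_prior_vetoes(self):
        ps = posterior_from_thetas([np.zeros((3, 3))])
        values = pd.DataFrame([[1, 0, 0]], index=pd.Index(["t"], name="taxon"),
                              columns=["m0", "m1", "m2"])
        ann = pd.DataFrame({"aquatic": False, "primate": False,
                            "bird": False, "rank": "genus"}, index=values.index)
        m = ht.TraitMatrix(values=values, annotations=ann)
        presence, _ = prediction_tables(ps, m, 2000, np.random.default_rng(0))
        flat = presence.reweight(
            pd.DataFrame(0.5, index=["t"], columns=["m0", "m1", "m2"]))
        pd.testing.assert_frame_equal(flat.probabilities,
                                      presence.probabilities)
        veto = presence.reweight(
            pd.DataFrame(0.0, index=["t"], columns=["m0", "m1", "m2"]))
        assert veto.probabilities.loc["t", "m1"] == 0.0
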