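"""One-hot encoding, data splits, model training, and beam search."""

import numpy as np
import pytest

from motifspace.design import allowed_bases_by_position, build_design, enumerate_design
from motifspace.ml import (
    DEFAULT_GRID,
    BeamSearchParams,
    HyperParams,
    MLError,
    SearchNode,
    SearchTree,
    beam_search,
    evaluate_regression,
    fitness_split,
    fraction_explored,
    grid_search,
    one_hot_decode,
    one_hot_encode,
    precision,
    random_split,
    train_model,
)
from motifspace.simulate import make_toy_landscape


class _OracleModel:
    """Scores sequences by a fixed lookup table (a perfect fitness oracle)."""

    def __init__(self, table):
        self.table = table

    def predict(self, seqs):
        return np.array([self.table[s] for s in seqs])


class TestOneHot:
    def test_single_base(self):
        np.testing.assert_array_equal(one_hot_encode(["A"]), [[1, 0, 0, 0]])

    def test_acgt_identity_blocks(self):
        row = one_hot_encode(["ACGT"])[0]
        assert row.sum() == 4
        np.testing.assert_array_equal(row.reshape(4, 4), np.eye(4))

    def test_round_trip_random_sequences(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), size=12)) for _ in range(1000)]
        assert one_hot_decode(one_hot_encode(seqs)) == seqs

    def test_ambiguous_character_rejected(self):
        with pytest.raises(MLError):
            one_hot_encode(["ACGN"])


class TestSplits:
    @staticmethod
    def _dataset(n):
        rng = np.random.default_rng(1)
        out = {}
        while len(out) < n:
            out["".join(rng.choice(list("ACGT"), size=10))] = float(
                rng.lognormal(1, 2)
            )
        return out

    def test_random_split_sizes_and_disjointness(self):
        data = self._dataset(1000)
        train, test = random_split(data, 0.1, 0.1, seed=3)
        assert len(train) == 100 and len(test) == 100
        assert not set(train) & set(test)
        assert set(train) | set(test) <= set(data)

    def test_random_split_reproducible(self):
        data = self._dataset(500)
        assert random_split(data, seed=7) == random_split(data, seed=7)
        assert random_split(data, seed=7) != random_split(data, seed=8)

    def test_fitness_split_top_matches_sort_oracle(self):
        data = self._dataset(400)
        train, val, test = fitness_split(data, n_test=100, n_val=100,
                                         train_sample_frac=1.0, seed=0)
        ranked = sorted(data, key=lambda s: (-data[s], s))
        assert set(test) == set(ranked[:100])
        assert set(val) == set(ranked[100:200])
        assert len(train) == 200
        assert not (set(train) & set(val)) and not (set(train) & set(test))

    def test_fitness_split_train_fraction_floor(self):
        data = self._dataset(450)
        train, _, _ = fitness_split(data, train_sample_frac=0.1, seed=0)
        assert len(train) == 25  # floor(0.1 * 250)

    def test_fitness_split_too_small(self):
        with pytest.raises(MLError):
            fitness_split(self._dataset(150), n_test=100, n_val=100)


class TestTrainModel:
    def test_constant_labels_predict_constant(self):
        rng = np.random.default_rng(2)
        data = {"".join(rng.choice(list("ACGT"), size=6)): 42.0 for _ in range(200)}
        model = train_model(data, seed=0)
        pred = model.predict(sorted(data)[:50])
        assert np.all(np.abs(pred - 42.0) / 42.0 < 0.1)

    def test_same_seed_is_bitwise_identical(self):
        rng = np.random.default_rng(3)
        data = {
            "".join(rng.choice(list("ACGT"), size=6)): float(v)
            for v in rng.lognormal(1, 1, size=150)
        }
        a = train_model(data, seed=5).predict(sorted(data))
        b = train_model(data, seed=5).predict(sorted(data))
        np.testing.assert_array_equal(a, b)

    def test_nan_labels_rejected(self):
        with pytest.raises(MLError):
            train_model({"ACGT": float("nan")})

    def test_additive_landscape_is_learnable(self, toy_spec, toy_design, toy_sequences):
        """On a purely additive landscape the MLP reaches r >= 0.9 on held-out
        sequences (log CPM scale)."""
        landscape = make_toy_landscape(toy_spec, ruggedness=0.0, pair_penalty=0.0, seed=4)
        k = landscape.k_obs(toy_sequences, 100.0)
        data = {s: float(v * 1e4) for s, v in zip(toy_sequences, k)}
        train, test = random_split(data, 0.25, 0.25, seed=4)
        model = train_model(train, seed=4, log_labels=True)
        report = evaluate_regression(model, test)
        assert report["pearson_log10"] >= 0.9


class TestEvaluate:
    def test_perfect_predictions(self):
        data = {"AAAA": 1.0, "AACC": 5.0, "GGTT": 25.0, "TTTT": 125.0}
        report = evaluate_regression(_OracleModel(data), data)
        assert report["pearson"] == pytest.approx(1.0)
        assert report["spearman"] == pytest.approx(1.0)

    def test_shuffled_predictions_are_uncorrelated(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACGT"), size=8)) for _ in range(2000)]
        seqs = sorted(set(seqs))
        values = rng.lognormal(0, 1, size=len(seqs))
        shuffled = rng.permutation(values)
        model = _OracleModel(dict(zip(seqs, shuffled)))
        report = evaluate_regression(model, dict(zip(seqs, values)))
        assert abs(report["pearson"]) < 0.1 and abs(report["spearman"]) < 0.1

    def test_five_point_hand_table(self):
        seqs = ["AA", "AC", "AG", "AT", "CA"]
        obs = [1.0, 2.0, 3.0, 4.0, 5.0]
        pred = [2.0, 1.0, 4.0, 3.0, 5.0]
        model = _OracleModel(dict(zip(seqs, pred)))
        report = evaluate_regression(model, dict(zip(seqs, obs)))
        assert report["pearson"] == pytest.approx(0.8)  # hand-computed
        assert report["spearman"] == pytest.approx(0.8)


class TestPrecisionAndExploration:
    def test_precision_examples(self):
        assert precision(["A", "C"], ["A", "C"]) == 1.0
        assert precision(["A", "C"], ["G", "T"]) == 0.0
        found = [f"s{i}" for i in range(100)]
        true = found[:40] + [f"t{i}" for i in range(60)]
        assert precision(found, true) == pytest.approx(0.40)
        with pytest.raises(MLError):
            precision(["A"], ["A", "C"])

    def test_fraction_explored(self):
        tree = SearchTree({f"s{i}": SearchNode(f"s{i}", 0.0, 0, None) for i in range(1000)})
        assert fraction_explored(tree, 10**6) == pytest.approx(0.001)
        with pytest.raises(MLError):
            fraction_explored(tree, 0)


class TestBeamSearch:
    @pytest.fixture(scope="class")
    def small_landscape(self):
        """A 256-sequence exhaustively enumerable lookup landscape."""
        import itertools

        seqs = ["".join(p) for p in itertools.product("ACGT", repeat=4)]
        rng = np.random.default_rng(6)
        return dict(zip(seqs, rng.lognormal(0, 2, size=len(seqs))))

    @staticmethod
    def _alphabet(L):
        return [frozenset("ACGT")] * L

    def test_max_depth_zero_returns_ranked_seeds(self, small_landscape):
        model = _OracleModel(small_landscape)
        seeds = sorted(small_landscape)[:5]
        params = BeamSearchParams(topN_start=5, beam_width=3, max_depth=0, top_explored=5)
        result = beam_search(model, seeds, params, self._alphabet(4))
        assert result.top == sorted(seeds, key=lambda s: (-small_landscape[s], s))

    def test_saturating_beam_equals_exhaustive_top_k(self, small_landscape):
        model = _OracleModel(small_landscape)
        seeds = sorted(small_landscape, key=lambda s: (-small_landscape[s], s))[:5]
        params = BeamSearchParams(topN_start=5, beam_width=4096, max_depth=16,
                                  top_explored=50)
        result = beam_search(model, seeds, params, self._alphabet(4))
        exhaustive = sorted(small_landscape, key=lambda s: (-small_landscape[s], s))[:50]
        assert result.top == exhaustive

    def test_never_revisits_and_tree_bound(self, small_landscape):
        model = _OracleModel(small_landscape)
        seeds = sorted(small_landscape)[:5]
        params = BeamSearchParams(topN_start=5, beam_width=3, max_depth=4, top_explored=10)
        result = beam_search(model, seeds, params, self._alphabet(4))
        branching = 4 * 3  # L * (|alphabet| - 1)
        assert len(result.tree) <= 5 + params.max_depth * params.beam_width * branching
        assert len(set(result.tree.nodes)) == len(result.tree)

    def test_deeper_search_never_finds_worse_best(self, small_landscape):
        model = _OracleModel(small_landscape)
        seeds = sorted(small_landscape)[:3]
        best = []
        for depth in range(6):
            params = BeamSearchParams(topN_start=3, beam_width=3, max_depth=depth,
                                      top_explored=1)
            result = beam_search(model, seeds, params, self._alphabet(4))
            best.append(small_landscape[result.top[0]])
        assert all(b2 >= b1 for b1, b2 in zip(best, best[1:]))

    def test_random_mode_is_seeded_and_distinct(self, small_landscape):
        model = _OracleModel(small_landscape)
        seeds = sorted(small_landscape)[:5]
        params = BeamSearchParams(mode="random", top_explored=20, max_depth=3)
        a = beam_search(model, seeds, params, self._alphabet(4), rng_seed=1)
        b = beam_search(model, seeds, params, self._alphabet(4), rng_seed=1)
        c = beam_search(model, seeds, params, self._alphabet(4), rng_seed=2)
        assert a.top == b.top
        assert set(a.tree.nodes) != set(c.tree.nodes)

    def test_alphabet_restricts_neighbours(self, toy_design, toy_sequences):
        """Within-design search never leaves the encoded sequence space."""
        alphabet = allowed_bases_by_position(toy_design)
        table = {s: float(i) for i, s in enumerate(toy_sequences)}
        model = _OracleModel(table)
        params = BeamSearchParams(topN_start=3, beam_width=5, max_depth=3, top_explored=50)
        seeds = toy_sequences[:3]
        result = beam_search(model, seeds, params, alphabet)
        encoded = set(toy_sequences)
        assert set(result.tree.nodes) <= encoded


class TestGridSearch:
    def test_default_grid_has_36_combinations(self):
        n = 1
        for values in DEFAULT_GRID.values():
            n *= len(values)
        assert n == 36

    def test_single_cell_grid_returns_that_cell(self):
        rng = np.random.default_rng(9)
        data = {
            "".join(rng.choice(list("ACGT"), size=6)): float(v)
            for v in rng.lognormal(2, 1, size=400)
        }
        train, val, _ = fitness_split(data, n_test=30, n_val=30, seed=0)
        grid = {"hidden_layer_sizes": [(10,)], "learning_rate_init": [0.01],
                "batch_size": [50]}
        hp, table = grid_search(
            train, val, [frozenset("ACGT")] * 6, grid=grid,
            beam_params=BeamSearchParams(top_explored=30, max_depth=2), seed=0,
            max_iter=50,
        )
        assert hp == HyperParams((10,), 0.01, 50)
        assert len(table) == 1

    def test_dominant_hyperparameters_are_selected(self, toy_spec, toy_design, toy_sequences):
        """A grid cell whose model is far better trained wins in 5/5 seeds."""
        landscape = make_toy_landscape(toy_spec, ruggedness=0.0, seed=10)
        k = landscape.k_obs(toy_sequences, 100.0)
        data = {s: float(v * 1e4) for s, v in zip(toy_sequences, k)}
        alphabet = allowed_bases_by_position(toy_design)
        grid = {
            "hidden_layer_sizes": [(50, 50)],
            "learning_rate_init": [0.001, 1e-7],  # 1e-7 barely moves off init
            "batch_size": [100],
        }
        for seed in range(5):
            train, val, _ = fitness_split(data, seed=seed, train_sample_frac=0.25)
            hp, table = grid_search(
                train, val, alphabet, grid=grid,
                beam_params=BeamSearchParams(top_explored=100), seed=seed,
                max_iter=150,
            )
            assert hp.learning_rate_init == 0.001
            assert table["precision"].iloc[0] > table["precision"].iloc[1]
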