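"""Ranking, subset selection, restriction, evaluation and the sweep loop."""

import numpy as np
import pytest

from conftest import fast_hp, small_spec
from ecaselect.network import TrainedModel, _Runtime
from ecaselect.preprocess import SampleSet
from ecaselect.selection import (
    ChannelRanking,
    ChannelSelectionModel,
    ChannelSubset,
    channel_sweep,
    evaluate,
    extract_channel_weights,
    rank_channels,
    restrict_to_subset,
    select_subset,
    split_by_trial,
    train_model,
)


class TestRankChannels:
    def test_basic_ordering(self):
        rk = rank_channels(np.array([0.2, 0.9, 0.5]), ["ch1", "ch2", "ch3"])
        assert rk.names == ["ch2", "ch3", "ch1"]

    def test_ties_keep_original_order(self):
        rk = rank_channels(np.full(4, 0.5), ["a", "b", "c", "d"])
        assert rk.names == ["a", "b", "c", "d"]

    def test_permutation_of_input(self):
        rng = np.random.default_rng(0)
        names = [f"ch{i}" for i in range(10)]
        rk = rank_channels(rng.uniform(0.01, 0.99, 10), names)
        assert sorted(rk.names) == sorted(names)
        assert np.all(np.diff(rk.weights) <= 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rank_channels(np.ones(3), ["a", "b"])

    def test_increasing_weights_rejected_in_type(self):
        with pytest.raises(ValueError):
            ChannelRanking([("a", 0.1), ("b", 0.9)])


class TestSelectSubset:
    @pytest.fixture()
    def ranking(self):
        return rank_channels(
            np.linspace(0.9, 0.1, 22), [f"ch{i}" for i in range(22)]
        )

    def test_full_prefix(self, ranking):
        sub = select_subset(ranking, 22)
        assert sub.channels == ranking.names

    def test_single_top_channel(self, ranking):
        assert select_subset(ranking, 1).channels == [ranking.names[0]]

    def test_eight_of_twenty_two(self, ranking):
        sub = select_subset(ranking, 8)
        assert len(sub.channels) == 8

    def test_prefix_property(self, ranking):
        for a in (1, 4, 9):
            for b in range(a, 23, 5):
                sa = select_subset(ranking, a).channels
                sb = select_subset(ranking, b).channels
                assert sb[: len(sa)] == sa

    @pytest.mark.parametrize("n", [0, 23, -1])
    def test_out_of_range(self, ranking, n):
        with pytest.raises(ValueError):
            select_subset(ranking, n)


class TestRestrictToSubset:
    @pytest.fixture()
    def sampleset(self, rng):
        return SampleSet(
            rng.normal(size=(10, 5, 30)),
            rng.integers(0, 4, 10),
            np.arange(10),
            ["a", "b", "c", "d", "e"],
        )

    def test_identity_subset(self, sampleset):
        sub = ChannelSubset(5, ["a", "b", "c", "d", "e"])
        out = restrict_to_subset(sampleset, sub)
        assert np.array_equal(out.samples, sampleset.samples)

    def test_shape_and_order(self, sampleset):
        sub = ChannelSubset(2, ["d", "a"])
        out = restrict_to_subset(sampleset, sub)
        assert out.samples.shape == (10, 2, 30)
        assert np.array_equal(out.samples[:, 0], sampleset.samples[:, 3])
        assert out.channel_names == ["d", "a"]

    def test_labels_unchanged(self, sampleset):
        sub = ChannelSubset(3, ["b", "c", "e"])
        out = restrict_to_subset(sampleset, sub)
        assert np.array_equal(out.labels, sampleset.labels)
        assert np.array_equal(out.trial_ids, sampleset.trial_ids)

    def test_unknown_channel(self, sampleset):
        with pytest.raises(KeyError):
            restrict_to_subset(sampleset, ChannelSubset(1, ["zz"]))


class TestEvaluate:
    def test_perfect_predictions(self, small_trained, small_split):
        train_ss, _ = small_split
        preds = small_trained.predict(train_ss.samples)
        forced = SampleSet(
            train_ss.samples, preds, train_ss.trial_ids, train_ss.channel_names
        )
        assert evaluate(small_trained, forced) == 1.0

    def test_untrained_model_at_chance_on_random_labels(self):
        spec = small_spec(6, 250, 4)
        rt = _Runtime(spec, np.random.default_rng(0), 0.0)
        model = TrainedModel(spec, rt, [], fast_hp(), 0, np.arange(4))
        rng = np.random.default_rng(1)
        n = 800
        ss = SampleSet(
            rng.normal(size=(n, 6, 250)),
            rng.integers(0, 4, n),
            np.arange(n),
            [f"ch{i}" for i in range(6)],
        )
        assert evaluate(model, ss) == pytest.approx(0.25, abs=0.05)

    def test_accuracy_bounded(self, small_trained, small_split):
        _, eval_ss = small_split
        acc = evaluate(small_trained, eval_ss)
        assert 0.0 <= acc <= 1.0
        vote = evaluate(small_trained, eval_ss, vote_by_trial=True)
        assert 0.0 <= vote <= 1.0

    def test_empty_set_rejected(self, small_trained):
        empty = SampleSet(
            np.empty((0, 8, 250)), np.empty(0, int), np.empty(0, int),
            [f"ch{i}" for i in range(8)],
        )
        with pytest.raises(ValueError):
            evaluate(small_trained, empty)


class TestExtractWeights:
    def test_shape_and_range(self, small_trained, small_split):
        train_ss, _ = small_split
        w = extract_channel_weights(small_trained, train_ss)
        assert w.shape == (8,)
        assert np.all((w > 0) & (w < 1))

    def test_invariant_to_sample_order(self, small_trained, small_split):
        train_ss, _ = small_split
        w1 = extract_channel_weights(small_trained, train_ss)
        perm = np.random.default_rng(5).permutation(len(train_ss))
        shuffled = SampleSet(
            train_ss.samples[perm], train_ss.labels[perm], train_ss.trial_ids[perm],
            train_ss.channel_names,
        )
        w2 = extract_channel_weights(small_trained, shuffled)
        assert np.abs(w1 - w2).max() < 1e-6

    def test_weight_norm_diagnostic_mode(self, small_trained, small_split):
        train_ss, _ = small_split
        w = extract_channel_weights(small_trained, train_ss, method="weight_norm")
        assert w.shape == (8,) and np.all((w > 0) & (w < 1))

    def test_channel_mismatch_rejected(self, small_trained, small_split):
        train_ss, _ = small_split
        sub = SampleSet(
            train_ss.samples[:, :4], train_ss.labels, train_ss.trial_ids,
            train_ss.channel_names[:4],
        )
        with pytest.raises(ValueError):
            extract_channel_weights(small_trained, sub)


class TestSweepLoop:
    def test_full_subset_reproduces_direct_training(self, small_split):
        train_ss, eval_ss = small_split
        hp = fast_hp(epochs=3)
        spec = small_spec(train_ss.n_channels, train_ss.n_times, 4)
        direct = evaluate(train_model(train_ss, hp, spec=spec), eval_ss)
        table = channel_sweep(train_ss, hp, [8], eval_samples=eval_ss, spec=spec)
        assert table.loc[0, "accuracy"] == direct
        assert table.shape[0] == 1

    def test_planted_information_monotonicity(self, small_sampleset):
        # 4 of 8 channels carry all class information: using all four planted
        # channels should not classify worse than using only two, in a
        # majority of seeded runs
        ss, _ = small_sampleset
        spec = small_spec(ss.n_channels, ss.n_times, 4)
        wins = 0
        for seed in (2, 3, 4):
            train_ss, eval_ss = split_by_trial(ss, 0.25, seed=seed)
            hp = fast_hp(epochs=20, seed=seed)
            table = channel_sweep(
                train_ss, hp, [2, 4, 8], eval_samples=eval_ss, spec=spec
            )
            assert table.shape[0] == 3
            acc = dict(zip(table["n_c"], table["accuracy"]))
            wins += acc[4] >= acc[2]
        assert wins >= 2

    def test_invalid_sizes_rejected(self, small_split):
        train_ss, eval_ss = small_split
        with pytest.raises(ValueError):
            channel_sweep(train_ss, fast_hp(epochs=1), [0], eval_samples=eval_ss)


@pytest.fixture(scope="module")
def results(small_split):
    train_ss, _ = small_split
    spec = small_spec(train_ss.n_channels, train_ss.n_times, 4)
    return ChannelSelectionModel(train_ss, fast_hp(epochs=4), spec=spec).fit()


class TestModelResultsSurface:

    def test_ranking_is_channel_permutation(self, results):
        assert sorted(results.ranking.names) == sorted(results.channel_names)

    def test_select_records_provenance(self, results):
        sub = results.select(3)
        assert sub.n_c == 3
        assert sub.provenance["seed"] == 11

    def test_summary_mentions_every_channel(self, results):
        text = results.summary()
        for name in results.channel_names:
            assert name in text

    def test_ranking_csv_round_trip(self, results, tmp_path):
        import pandas as pd

        path = tmp_path / "ranking.csv"
        results.save_ranking_csv(path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["rank", "channel_name", "mean_weight"]
        assert df.shape[0] == 8
        assert np.all(np.diff(df["mean_weight"]) <= 0)

    def test_subset_file_round_trip(self, results, tmp_path):
        sub = results.select(4)
        path = tmp_path / "subset.txt"
        sub.save(path)
        assert path.read_text().splitlines() == sub.channels
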