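import numpy as np
import pandas as pd
import pytest

from distrank import metrics
from distrank.ranking import (
    ModelPool,
    Ranking,
    StackedQA,
    consensus_scores,
    filter_redundant,
    rank_average,
    select_top,
)


def pool_with_matrix(k, groups=None, seed=0):
    """Tiny pool whose structures are irrelevant: tests inject the pairwise
    GDT-TS matrix directly."""
    from conftest import random_structure

    return ModelPool(
        target_id="t",
        model_ids=[f"m{i}" for i in range(k)],
        models=[random_structure(12, seed + i) for i in range(k)],
        groups=groups,
    )


class TestFilterRedundant:
    def test_same_group_above_cutoff_drops_lower_ranked(self):
        pool = pool_with_matrix(2, groups=["gA", "gA"])
        pw = np.array([[1.0, 0.97], [0.97, 1.0]])
        out = filter_redundant(pool, pairwise=pw)
        assert out.model_ids == ["m0"]

    def test_cross_group_pair_never_filtered(self):
        pool = pool_with_matrix(2, groups=["gA", "gB"])
        pw = np.array([[1.0, 0.97], [0.97, 1.0]])
        out = filter_redundant(pool, pairwise=pw)
        assert out.model_ids == ["m0", "m1"]

    def test_below_cutoff_kept(self):
        pool = pool_with_matrix(2, groups=["gA", "gA"])
        pw = np.array([[1.0, 0.90], [0.90, 1.0]])
        out = filter_redundant(pool, pairwise=pw)
        assert out.model_ids == ["m0", "m1"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        pw = rng.uniform(0.5, 1.0, size=(6, 6))
        pw = (pw + pw.T) / 2
        np.fill_diagonal(pw, 1.0)
        pool = pool_with_matrix(6, groups=["gA", "gA", "gA", "gB", "gB", "gB"])
        once = filter_redundant(pool, pairwise=pw)
        keep = [pool.model_ids.index(m) for m in once.model_ids]
        twice = filter_redundant(once, pairwise=pw[np.ix_(keep, keep)])
        assert twice.model_ids == once.model_ids

    def test_real_pool_end_to_end(self, pool30):
        dup = pool30.models[0]
        pool = ModelPool(
            target_id="t",
            model_ids=["a", "a_copy", "b"],
            models=[dup, dup, pool30.models[-1]],
            groups=["gA", "gA", "gA"],
        )
        out = filter_redundant(pool)
        assert "a_copy" not in out.model_ids
        assert "a" in out.model_ids


class TestConsensusScores:
    def test_identical_models_all_one(self):
        pool = pool_with_matrix(4)
        pw = np.ones((4, 4))
        assert set(consensus_scores(pool, pairwise=pw).values()) == {1.0}

    def test_outlier_gets_lowest_score(self, native30, pool30):
        from distrank import synth

        near = synth.make_decoys(
            native30, synth.DecoySpec(n_decoys=5, noise_levels=(0.5,), seed=2))
        outlier = synth.make_decoys(
            native30, synth.DecoySpec(n_decoys=2, noise_levels=(9.0,), seed=4)
        ).models[0]
        pool = ModelPool(
            target_id="t",
            model_ids=near.model_ids + ["outlier"],
            models=near.models + [outlier],
        )
        scores = consensus_scores(pool)
        assert min(scores, key=scores.get) == "outlier"
        # verify one entry against a direct mean
        pw = metrics.pairwise_matrix(pool.models)
        assert scores["outlier"] == pytest.approx(np.mean(pw[-1, :-1]))

    def test_two_model_pool_symmetric(self):
        pool = pool_with_matrix(2)
        pw = np.array([[1.0, 0.63], [0.63, 1.0]])
        scores = consensus_scores(pool, pairwise=pw)
        assert scores["m0"] == scores["m1"] == pytest.approx(0.63)

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            consensus_scores(pool_with_matrix(1))

    def test_duplicating_a_model_inflates_its_consensus(self):
        """Adding identical copies of one model drags the consensus score
        toward it — the mechanism that misleads clustering QA on skewed
        pools."""
        base = np.array([
            [1.0, 0.5, 0.4],
            [0.5, 1.0, 0.45],
            [0.4, 0.45, 1.0]])
        pool3 = pool_with_matrix(3)
        before = consensus_scores(pool3, pairwise=base)["m0"]
        # add two exact copies of m0
        k = 5
        pw = np.ones((k, k))
        copies = [0, 1, 2, 0, 0]
        for i in range(k):
            for j in range(k):
                pw[i, j] = base[copies[i], copies[j]]
                if i != j and copies[i] == copies[j]:
                    pw[i, j] = 1.0
        pool5 = pool_with_matrix(5)
        after = consensus_scores(pool5, pairwise=pw)["m0"]
        assert after > before


class TestRankAverage:
    def r(self, pairs):
        return Ranking(entries=pairs)

    def test_identical_rankings_preserved(self):
        a = self.r([("x", 0.9), ("y", 0.5), ("z", 0.1)])
        out = rank_average([a, a, a])
        assert out.model_ids == ["x", "y", "z"]

    def test_symmetric_tie_broken_by_id(self):
        a = self.r([("x", 0.9), ("y", 0.5)])
        b = self.r([("y", 0.9), ("x", 0.5)])
        out = rank_average([a, b])
        assert out.model_ids == ["x", "y"]

    def test_mean_rank_hand_computed(self):
        r1 = self.r([("a", 4.0), ("b", 3.0), ("c", 2.0), ("d", 1.0)])
        r2 = self.r([("b", 4.0), ("a", 3.0), ("d", 2.0), ("c", 1.0)])
        r3 = self.r([("b", 4.0), ("c", 3.0), ("a", 2.0), ("d", 1.0)])
        # mean ranks: a = (1+2+3)/3 = 2, b = (2+1+1)/3 = 1.33,
        #             c = (3+4+2)/3 = 3, d = (4+3+4)/3 = 3.67
        out = rank_average([r1, r2, r3])
        assert out.model_ids == ["b", "a", "c", "d"]

    def test_mismatched_sets_rejected(self):
        a = self.r([("x", 1.0), ("y", 0.5)])
        b = self.r([("x", 1.0), ("z", 0.5)])
        with pytest.raises(ValueError):
            rank_average([a, b])


class TestSelectTop:
    def test_fewer_models_than_n(self):
        r = Ranking(entries=[("a", 0.9), ("b", 0.5), ("c", 0.1)])
        assert select_top(r, 5) == ["a", "b", "c"]

    def test_zero_n(self):
        r = Ranking(entries=[("a", 0.9)])
        assert select_top(r, 0) == []

    def test_first_five_by_score(self):
        rng = np.random.default_rng(1)
        scores = {f"m{i}": float(rng.random()) for i in range(10)}
        r = Ranking.from_scores(scores)
        expected = sorted(scores, key=lambda m: (-scores[m], m))[:5]
        assert select_top(r, 5) == expected


def informative_features(n_rows, seed, n_noise=3):
    """Synthetic regression set: label recoverable from two noisy views."""
    rng = np.random.default_rng(seed)
    y = rng.uniform(0, 1, size=n_rows)
    df = pd.DataFrame({
        "f1": y + rng.normal(scale=0.05, size=n_rows),
        "f2": y + rng.normal(scale=0.10, size=n_rows),
        **{f"n{k}": rng.normal(size=n_rows) for k in range(n_noise)},
    }, index=[f"m{i}" for i in range(n_rows)])
    return df, y


class TestStackedQA:
    def test_constant_labels_warn_and_predict_near_constant(self):
        df, _ = informative_features(60, 0)
        with pytest.warns(UserWarning, match="zero-variance"):
            qa = StackedQA(seed=1).fit(df, np.full(60, 0.5))
        pred = qa.predict(df)
        assert np.all((pred >= 0.45) & (pred <= 0.55))

    def test_determinism_bit_for_bit(self):
        df, y = informative_features(80, 2)
        p1 = StackedQA(seed=5).fit(df, y).predict(df)
        p2 = StackedQA(seed=5).fit(df, y).predict(df)
        assert np.array_equal(p1.to_numpy(), p2.to_numpy())

    def test_different_seed_changes_fit(self):
        df, y = informative_features(80, 2)
        p1 = StackedQA(seed=5).fit(df, y).predict(df)
        p2 = StackedQA(seed=6).fit(df, y).predict(df)
        assert not np.array_equal(p1.to_numpy(), p2.to_numpy())

    def test_missing_column_error_names_it(self):
        df, y = informative_features(60, 3)
        qa = StackedQA(seed=1).fit(df, y)
        renamed = df.rename(columns={"f2": "g2"})
        with pytest.raises(ValueError, match="f2"):
            qa.predict(renamed)

    def test_too_few_rows_rejected(self):
        df, y = informative_features(20, 4)
        with pytest.raises(ValueError):
            StackedQA().fit(df, y)

    def test_labels_outside_unit_interval_rejected(self):
        df, y = informative_features(60, 5)
        with pytest.raises(ValueError):
            StackedQA().fit(df, y + 2.0)

    def test_recovers_signal_on_held_out_rows(self):
        from scipy.stats import spearmanr

        df, y = informative_features(200, 6)
        qa = StackedQA(seed=3).fit(df.iloc[:150], y[:150])
        pred = qa.predict(df.iloc[150:])
        rho = spearmanr(pred.to_numpy(), y[150:])[0]
        assert rho > 0.9

    def test_predictions_clipped_to_unit_interval(self):
        df, y = informative_features(100, 7)
        qa = StackedQA(seed=2).fit(df, y)
        wild = df * 10  # far outside the training range
        pred = qa.predict(wild)
        assert pred.min() >= 0.0 and pred.max() <= 1.0

    def test_save_load_roundtrip(self, tmp_path):
        df, y = informative_features(60, 8)
        qa = StackedQA(seed=4).fit(df, y)
        path = tmp_path / "qa.joblib"
        qa.save(path)
        back = StackedQA.load(path)
        assert np.array_equal(back.predict(df).to_numpy(),
                              qa.predict(df).to_numpy())
        assert back.seed == 4 and back.feature_schema == list(df.columns)

    def test_ten_folds_partition_training_rows(self):
        df, y = informative_features(100, 9)
        qa = StackedQA(seed=0).fit(df, y)
        assert len(qa.level1) == 10
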