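import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctleeg import relieff_weights, top_features


def brute_force_relieff_k1(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent k=1, m=all ReliefF: explicit neighbour search per instance."""
    X = np.asarray(X, dtype=float)
    mn, mx = X.min(axis=0), X.max(axis=0)
    scale = np.where(mx - mn == 0, 1.0, mx - mn)
    Xs = (X - mn) / scale
    n, f = Xs.shape
    W = np.zeros(f)
    for i in range(n):
        best = {True: None, False: None}
        for j in range(n):
            if j == i:
                continue
            d = np.abs(Xs[i] - Xs[j]).sum()
            same = y[j] == y[i]
            if best[same] is None or d < best[same][0]:
                best[same] = (d, j)
        hit, miss = best[True][1], best[False][1]
        W += (np.abs(Xs[i] - Xs[miss]) - np.abs(Xs[i] - Xs[hit])) / n
    return W


TOY_X = np.array([[0.0, 0.5], [0.0, 0.5], [1.0, 0.5], [1.0, 0.5]])
TOY_Y = np.array([0, 0, 1, 1])


class TestWeights:
    def test_constant_feature_has_weight_zero(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=8), np.full(8, 3.0)])
        y = np.array([0, 1] * 4)
        rw = relieff_weights(X, y, k=1)
        assert rw.weights[1] == 0.0

    def test_four_instance_toy_set_hand_computed(self):
        # f1 equals the class label -> every miss diff 1, every hit diff 0
        rw = relieff_weights(TOY_X, TOY_Y, k=1)
        np.testing.assert_allclose(rw.weights, [1.0, 0.0])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_oracle_k1(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(10, 6))
        y = rng.integers(0, 2, size=10)
        y[:2], y[-2:] = 0, 1  # both classes guaranteed
        rw = relieff_weights(X, y, k=1)
        np.testing.assert_allclose(rw.weights, brute_force_relieff_k1(X, y), atol=1e-12)

    def test_weights_bounded_by_one(self):
        rng = np.random.default_rng(7)
        X = rng.uniform(-5, 5, size=(20, 8))
        y = np.array([0, 1] * 10)
        rw = relieff_weights(X, y)
        assert np.all(np.abs(rw.weights) <= 1 + 1e-12)

    def test_class_smaller_than_k_is_named_in_error(self):
        X = np.random.default_rng(1).normal(size=(5, 2))
        y = np.array([0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="class 1"):
            relieff_weights(X, y, k=2)

    def test_duplicating_instances_zeroes_hit_term_only(self):
        """Duplicates sit at distance zero, so each instance's nearest hit
        becomes its own copy (hit penalty 0) while the nearest miss is
        unchanged: duplicated weights equal the original miss term and can
        only rise."""
        rng = np.random.default_rng(5)
        X = rng.normal(size=(8, 4))
        y = np.array([0, 1] * 4)
        rw = relieff_weights(X, y, k=1)
        rw_dup = relieff_weights(np.vstack([X, X]), np.concatenate([y, y]), k=1)
        assert np.all(rw_dup.weights >= rw.weights - 1e-12)
        np.testing.assert_allclose(
            rw_dup.weights,
            brute_force_relieff_k1(np.vstack([X, X]), np.concatenate([y, y])),
            atol=1e-12,
        )

    @settings(max_examples=15, derandomize=True, deadline=None)
    @given(st.permutations(list(range(5))))
    def test_feature_permutation_permutes_weights(self, perm):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(12, 5))
        y = np.array([0, 1] * 6)
        base = relieff_weights(X, y, k=2).weights
        permuted = relieff_weights(X[:, perm], y, k=2).weights
        np.testing.assert_allclose(permuted, base[perm], atol=1e-12)

    def test_iid_noise_feature_has_near_zero_expected_weight(self):
        # expectation over many resamples of a label-independent feature
        means = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = np.column_stack([
                np.array([0, 1] * 5) + rng.normal(0, 0.2, 10),
                rng.normal(size=10),
            ])
            y = np.array([0, 1] * 5)
            means.append(relieff_weights(X, y, k=1).weights[1])
        assert abs(np.mean(means)) < 0.05


class TestTopFeatures:
    def test_full_ranking_returned_at_d_max(self):
        rw = relieff_weights(TOY_X, TOY_Y, k=1)
        assert list(top_features(rw, 2)) == list(rw.ranking)

    def test_ties_break_by_ascending_feature_index(self):
        rw = relieff_weights(TOY_X, TOY_Y, k=1)
        rw.weights[:] = [0.2, 0.9]
        from ctleeg.relieff import _rank_descending

        ranking = _rank_descending(np.array([0.2, 0.9, 0.9]))
        assert list(ranking[:2]) == [1, 2]

    def test_toy_set_top_one_is_the_label_feature(self):
        rw = relieff_weights(TOY_X, TOY_Y, k=1)
        assert list(top_features(rw, 1)) == [0]

    def test_weight_table_export(self, tmp_path):
        import pandas as pd

        rw = relieff_weights(TOY_X, TOY_Y, k=1)
        path = tmp_path / "weights.csv"
        rw.to_csv(path, feature_names=["label_like", "constant"])
        df = pd.read_csv(path)
        assert list(df.columns) == ["feature", "weight", "rank"]
        assert df.loc[df["feature"] == "label_like", "rank"].iloc[0] == 1

    def test_d_out_of_range_rejected(self):
        rw = relieff_weights(TOY_X, TOY_Y, k=1)
        with pytest.raises(ValueError, match="out of range"):
            top_features(rw, 3)
        with pytest.raises(ValueError, match="out of range"):
            top_features(rw, 0)
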