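import numpy as np
import pytest
from sklearn.base import clone
from sklearn.pipeline import Pipeline
from sklearn.linear_model import LogisticRegression

from enzyph import (MRMDSelector, max_distance, max_relevance, rank_features,
                    select_subset)

from _naive import naive_pearson


def planted_noise_matrix(seed, n=200, n_noise=19, sigma=0.667):
    """One informative column (labels + noise, point-biserial ~0.6) + noise."""
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    informative = y + rng.normal(0, sigma, n)
    X = np.column_stack([informative] + [rng.normal(size=n) for _ in range(n_noise)])
    return X, y


class TestMaxRelevance:
    def test_label_identical_column_scores_one(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        X = np.column_stack([y.astype(float), np.ones(6)])
        with pytest.warns(UserWarning, match="zero-variance"):
            mr = max_relevance(X, y)
        assert mr[0] == pytest.approx(1.0)
        assert mr[1] == 0.0

    def test_matches_naive_pearson(self):
        y = np.array([0] * 5 + [1] * 5)
        col = y.astype(float).copy()
        col[3] = 1.0  # one flipped entry
        mr = max_relevance(np.column_stack([col, -col]), y)
        expected = abs(naive_pearson(col.tolist(), y.tolist()))
        assert mr[0] == pytest.approx(expected, abs=1e-12)
        assert mr[1] == pytest.approx(expected, abs=1e-12)  # |r| symmetric

    def test_single_class_labels_raise(self):
        with pytest.raises(ValueError, match="both classes"):
            max_relevance(np.ones((4, 2)), np.zeros(4))


class TestMaxDistance:
    def test_identical_columns_have_zero_distance(self):
        col = np.array([0.1, 0.7, 0.3, 1.0])
        md = max_distance(np.column_stack([col, col]))
        assert np.allclose(md, 0, atol=1e-12)

    def test_orthogonal_columns_hand_computed(self):
        # Already min-max normalised; a.b = 0
        a = np.array([1.0, 0, 0, 1.0])
        b = np.array([0, 1.0, 1.0, 0])
        md = max_distance(np.column_stack([a, b]))
        ed = 2.0                 # sqrt(4 unit differences)
        cos = 1.0                # 1 - 0
        tc = 1.0                 # 1 - 0/(2+2-0)
        assert np.allclose(md, ed + cos + tc)

    def test_nonnegative(self, rng):
        X = rng.random((30, 8))
        assert np.all(max_distance(X) >= 0)

    def test_single_column_raises(self):
        with pytest.raises(ValueError):
            max_distance(np.ones((4, 1)))

    def test_zero_column_pairs_warn_and_contribute_zero_similarity_distance(self):
        X = np.column_stack([np.zeros(4), np.array([0, 1, 2, 3.0])])
        with pytest.warns(UserWarning, match="all-zero"):
            md = max_distance(X)
        # cosine is undefined for the zero column's pair -> contributes 0;
        # Tanimoto is defined (similarity 0) -> distance 1
        ed = np.linalg.norm(np.array([0, 1 / 3, 2 / 3, 1.0]))
        assert np.allclose(md, ed + 1.0)


class TestRankFeatures:
    def test_singleton_matrix(self):
        y = np.array([0, 1, 0, 1])
        scores = rank_features(np.array([[1.0], [2], [1], [2]]), y)
        assert len(scores) == 1
        assert scores[0].rank == 1 and scores[0].distance == 0.0

    def test_ranks_are_a_permutation(self, planted_matrix):
        fm = planted_matrix
        scores = rank_features(fm.X, fm.labels, fm.names)
        assert sorted(s.rank for s in scores) == list(range(1, fm.n_features + 1))

    def test_planted_column_ranks_first_in_most_replicates(self):
        wins = sum(
            rank_features(*planted_noise_matrix(seed))[0].index == 0
            for seed in range(100))
        assert wins >= 90

    def test_duplicate_top_column_lowers_its_distance(self):
        X, y = planted_noise_matrix(3)
        md_before = max_distance(X)
        X_dup = np.column_stack([X, X[:, 0]])
        md_after = max_distance(X_dup)
        assert md_after[0] < md_before[0]
        assert md_after[-1] < md_before[0]

    def test_row_permutation_invariance(self, rng):
        X, y = planted_noise_matrix(5, n=60, n_noise=5)
        perm = rng.permutation(60)
        before = rank_features(X, y)
        after = rank_features(X[perm], y[perm])
        assert [s.index for s in before] == [s.index for s in after]
        assert np.allclose([s.score for s in before], [s.score for s in after])

    def test_affine_rescaling_invariance(self):
        X, y = planted_noise_matrix(7, n=60, n_noise=5)
        X2 = X.copy()
        X2[:, 2] = 100.0 * X2[:, 2] - 17.0
        before = rank_features(X, y)
        after = rank_features(X2, y)
        assert [s.index for s in before] == [s.index for s in after]


class TestSelectSubset:
    def test_planted_column_selected(self):
        X, y = planted_noise_matrix(13)
        chosen, trace = select_subset(X, y, cv=5, seed=1)
        assert 0 in chosen

    def test_identical_columns_choose_k_one(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=40)
        X = np.column_stack([col] * 6)
        y = np.repeat([0, 1], 20)
        chosen, trace = select_subset(X, y, cv=5, seed=1)
        assert len(chosen) == 1

    def test_trace_covers_grid(self):
        X, y = planted_noise_matrix(17, n=60, n_noise=7)
        chosen, trace = select_subset(X, y, cv=5, seed=1)
        assert [t["k"] for t in trace] == list(range(1, 9))
        assert all(0 <= t["accuracy"] <= 1 for t in trace)


class TestSelectorAPI:
    def test_fixed_k_pipeline(self):
        X, y = planted_noise_matrix(19)
        sel = MRMDSelector(n_features=3)
        pipe = Pipeline([("select", sel),
                         ("clf", LogisticRegression(max_iter=200))])
        pipe.fit(X, y)
        assert pipe.named_steps["select"].support_.sum() == 3
        assert pipe.score(X, y) > 0.5

    def test_auto_mode_attributes(self):
        X, y = planted_noise_matrix(23, n=80, n_noise=5)
        sel = MRMDSelector(n_features="auto", cv=4, random_state=0).fit(X, y)
        assert sel.transform(X).shape[1] == len(sel.selected_indices_)
        assert len(sel.selection_trace_) >= 1
        assert len(sel.ranking_) == 6

    def test_clone_and_params(self):
        sel = MRMDSelector(n_features=5, cv=3, random_state=7)
        params = clone(sel).get_params()
        assert params["n_features"] == 5 and params["cv"] == 3
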