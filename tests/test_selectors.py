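"""The five base selectors: scoring oracles, ranking rules, support recovery."""

import numpy as np
import pytest
from scipy import stats

import voxelstab.selectors as sel_mod
from voxelstab.design import starplus_design
from voxelstab.errors import DegenerateLabelsError, ParameterError
from voxelstab.selectors import (
    RankedScores,
    SelectorConfig,
    lambda_max,
    rank_top_k,
    score_correlation,
    score_mutual_information,
    select_enet,
    select_lasso,
    svm_rfe,
    tune_subset_size,
)
from voxelstab.synthetic import SyntheticSpec, make_starplus_like


def planted_instance(seed, n=80, m=50, effect=4.0, n_informative=1):
    spec = SyntheticSpec(
        design=starplus_design(), grid_dims=(8, 8, 4), n_voxels=m,
        n_informative=n_informative, cluster_radius=0.0,
        effect_size=effect, noise_sd=1.0, seed=seed,
    )
    ds = make_starplus_like(spec)
    return ds.X[:n], ds.labels[:n], sorted(ds.ground_truth)


class TestCorrelation:
    def test_perfect_and_sign_symmetric(self):
        y = np.array([0, 1] * 10)
        coding = np.where(y == 1, 1.0, -1.0)
        X = np.column_stack([coding, -coding, np.ones(20)])
        scores = score_correlation(X, y).scores
        assert scores[0] == pytest.approx(1.0)
        assert scores[1] == pytest.approx(1.0)
        assert scores[2] == 0.0  # constant feature

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            X = rng.normal(size=(30, 4))
            y = rng.integers(0, 2, 30)
            if len(np.unique(y)) < 2:
                continue
            scores = score_correlation(X, y).scores
            coding = np.where(y == 1, 1.0, -1.0)
            for j in range(4):
                r = stats.pearsonr(X[:, j], coding).statistic
                assert scores[j] == pytest.approx(abs(r), abs=1e-12)

    def test_permutation_null_is_small(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=80)
        y = np.array([0, 1] * 40)
        acc = 0.0
        for _ in range(100):
            perm = rng.permutation(y)
            acc += score_correlation(x[:, None], perm).scores[0]
        assert acc / 100 < 0.15

    def test_single_class_raises(self):
        with pytest.raises(DegenerateLabelsError):
            score_correlation(np.ones((5, 2)), np.zeros(5))


class TestMutualInformation:
    def test_deterministic_feature_carries_full_label_entropy(self):
        y = np.array([0, 1] * 40)
        x = np.where(y == 1, 2.0, -1.0) + 0.0
        scores = score_mutual_information(x[:, None], y, mi_bins=8).scores
        assert scores[0] == pytest.approx(1.0, abs=1e-12)  # H(y) = 1 bit

    def test_matches_bruteforce_histogram_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(20, 60))
            X = rng.normal(size=(n, 3))
            y = rng.integers(0, 3, n)
            if len(np.unique(y)) < 2:
                continue
            bins = int(rng.integers(2, 6))
            scores = score_mutual_information(X, y, mi_bins=bins).scores
            for j in range(3):
                ranks = stats.rankdata(X[:, j], method="ordinal") - 1
                codes = (ranks * bins // n).astype(int)
                # brute force: sum over observed (code, label) cells
                mi = 0.0
                for a in np.unique(codes):
                    for b in np.unique(y):
                        p_ab = np.mean((codes == a) & (y == b))
                        if p_ab > 0:
                            p_a, p_b = np.mean(codes == a), np.mean(y == b)
                            mi += p_ab * np.log2(p_ab / (p_a * p_b))
                assert scores[j] == pytest.approx(mi, abs=1e-12)

    def test_duplicated_columns_and_independence(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=80)
        y = np.array([0, 1] * 40)
        scores = score_mutual_information(
            np.column_stack([x, x]), y
        ).scores
        assert scores[0] == scores[1]
        # independent feature: plug-in MI stays well below H(y) = 1 bit
        assert scores[0] < 0.3

    def test_bins_exceed_samples(self):
        with pytest.raises(ParameterError):
            score_mutual_information(np.zeros((5, 1)), np.array([0, 1] * 2 + [0]),
                                     mi_bins=6)


class TestRankTopK:
    def test_rules(self):
        scores = RankedScores.from_scores(np.array([0.9, 0.5, 0.5, 0.1]))
        assert rank_top_k(scores, 4).indices == frozenset({0, 1, 2, 3})
        assert rank_top_k(scores, 2).indices == frozenset({0, 1})  # tie-break
        assert rank_top_k(scores, 1).indices == frozenset({0})
        with pytest.raises(ParameterError):
            rank_top_k(scores, 5)
        with pytest.raises(ParameterError):
            rank_top_k(scores, 0)


class TestSvmRfe:
    def test_no_op_when_k_equals_m(self):
        X, y, _ = planted_instance(0, m=10)
        out = svm_rfe(X, y, k=10)
        assert out.indices == frozenset(range(10))
        assert out.elimination_order == ()

    def test_elimination_schedule_halving(self, monkeypatch):
        X, y, _ = planted_instance(1, m=8)
        calls = []
        orig = sel_mod._svm_weight_magnitudes

        def spy(Xs, ys, C):
            calls.append(Xs.shape[1])
            return orig(Xs, ys, C)

        monkeypatch.setattr(sel_mod, "_svm_weight_magnitudes", spy)
        out = svm_rfe(X, y, k=1, rfe_step_fraction=0.5)
        assert calls == [8, 4, 2]  # survivors per round: 8 -> 4 -> 2 -> 1
        assert len(out) == 1
        assert len(out.elimination_order) == 7

    def test_separating_feature_survives(self):
        wins = 0
        for seed in range(20):
            X, y, info = planted_instance(seed, m=21, effect=6.0)
            # sanity: the planted feature alone separates the classes
            j = info[0]
            thresh = X[:, j].mean()
            assert np.mean((X[:, j] > thresh) == y) > 0.9
            out = svm_rfe(X, y, k=1)
            wins += out.indices == frozenset(info)
        assert wins >= 18


class TestRegularizedSelectors:
    def test_empty_support_above_lambda_max(self, split_80):
        X, y, _ = planted_instance(4)
        tr, va, _ = split_80
        lm = lambda_max(X[tr], y[tr])
        out = select_lasso(X[tr], y[tr], (X[va], y[va]),
                           lambda_grid=[lm * 1.5])
        assert len(out) == 0

    def test_planted_feature_recovered(self, split_80):
        tr, va, _ = split_80
        hits = 0
        for seed in range(100):
            X, y, info = planted_instance(seed)
            out = select_lasso(X[tr], y[tr], (X[va], y[va]))
            hits += info[0] in out.indices
        assert hits >= 95

    def test_enet_grouping_vs_lasso_splitting(self, split_80):
        tr, va, _ = split_80
        rng_master = np.random.default_rng(10)
        enet_both = 0
        lasso_pairs = []
        enet_pairs = []
        for seed in rng_master.integers(0, 2**31, size=100):
            X, y, info = planted_instance(int(seed), m=11, effect=4.0)
            X = np.column_stack([X, X[:, info[0]]])  # duplicate the signal
            pair = {info[0], 11}
            l = select_lasso(X[tr], y[tr], (X[va], y[va]))
            e = select_enet(X[tr], y[tr], (X[va], y[va]), alpha=0.8)
            lasso_pairs.append(len(pair & l.indices))
            enet_pairs.append(len(pair & e.indices))
            enet_both += pair <= e.indices
        assert enet_both >= 90  # grouping effect
        assert np.mean(lasso_pairs) < np.mean(enet_pairs)

    def test_enet_alpha_zero_reduces_to_lasso(self, split_80):
        tr, va, _ = split_80
        X, y, _ = planted_instance(6, n_informative=3)
        grid = sel_mod.default_lambda_grid(X[tr], y[tr])
        l = select_lasso(X[tr], y[tr], (X[va], y[va]), lambda_grid=grid)
        e = select_enet(X[tr], y[tr], (X[va], y[va]), lambda_grid=grid,
                        alpha=0.0)
        assert l.indices == e.indices

    def test_empty_grid_rejected(self, split_80):
        tr, va, _ = split_80
        X, y, _ = planted_instance(7)
        with pytest.raises(ParameterError):
            select_lasso(X[tr], y[tr], (X[va], y[va]), lambda_grid=[])


class TestTuneSubsetSize:
    @staticmethod
    def _corr_selector(X, y, k):
        return rank_top_k(score_correlation(X, y), k)

    def test_singleton_grid(self, split_80):
        X, y, _ = planted_instance(8, m=20)
        tr, va, _ = split_80
        assert tune_subset_size(self._corr_selector, X[tr], y[tr],
                                X[va], y[va], [20]) == 20

    def test_tie_goes_to_smallest_k(self, split_80):
        X, y, info = planted_instance(9, m=20, effect=8.0)
        tr, va, _ = split_80
        # both sizes classify perfectly -> smallest wins
        assert tune_subset_size(self._corr_selector, X[tr], y[tr],
                                X[va], y[va], [1, 20]) == 1

    def test_modal_choice_matches_signal_size(self, split_80):
        tr, va, _ = split_80
        chosen = []
        for seed in range(20):
            X, y, info = planted_instance(seed, m=50, effect=2.0,
                                          n_informative=5)
            chosen.append(tune_subset_size(
                self._corr_selector, X[tr], y[tr], X[va], y[va], [1, 5, 50]
            ))
        values, counts = np.unique(chosen, return_counts=True)
        assert values[np.argmax(counts)] == 5


def test_selector_config_validation():
    with pytest.raises(ParameterError):
        SelectorConfig(method="PCA")
    with pytest.raises(ParameterError):
        SelectorConfig(method="RFE", rfe_step_fraction=1.0)
    with pytest.raises(ParameterError):
        SelectorConfig(method="ENet", alpha=1.5)
    with pytest.raises(ParameterError):
        SelectorConfig(method="LASSO", lambda_grid=())
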