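"""Outer CV schemes, final classifiers, and method-level reports."""

import numpy as np
import pytest

import voxelstab.evaluation as ev_mod
from voxelstab.design import haxby_design, starplus_design
from voxelstab.errors import ParameterError, SchemeError
from voxelstab.evaluation import (
    CVPlan,
    evaluate_method,
    finalize_and_test,
    make_cv_splits_haxby,
    make_cv_splits_starplus,
    theta_sweep,
    train_linear_svm,
    train_regularized_lr,
)
from voxelstab.selectors import SelectedSet, SelectorConfig, lambda_max
from voxelstab.stability import ResamplingPlan
from voxelstab.synthetic import SyntheticSpec, make_haxby_like, make_starplus_like


def small_dataset(seed=0, m=40, effect=4.0, n_informative=4):
    spec = SyntheticSpec(
        design=starplus_design(), grid_dims=(8, 8, 4), n_voxels=m,
        n_informative=n_informative, cluster_radius=0.0,
        effect_size=effect, noise_sd=1.0, seed=seed,
    )
    return make_starplus_like(spec)


class TestStarplusSplits:
    def test_default_scheme(self):
        ds = small_dataset()
        plans = make_cv_splits_starplus(ds, seed=3)
        assert len(plans) == 10
        for p in plans:
            assert p.train_idx.size == 60
            assert p.val_idx.size == 10
            assert p.test_idx.size == 10
            used = np.concatenate([p.train_idx, p.val_idx, p.test_idx])
            assert np.array_equal(np.sort(used), np.arange(80))
            # stratification: every block is class-balanced
            for block in (p.train_idx, p.val_idx, p.test_idx):
                counts = np.bincount(ds.labels[block])
                assert counts[0] == counts[1]

    def test_determinism_and_size_check(self):
        ds = small_dataset()
        a = make_cv_splits_starplus(ds, seed=5)
        b = make_cv_splits_starplus(ds, seed=5)
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.train_idx, pb.train_idx)
        with pytest.raises(SchemeError):
            make_cv_splits_starplus(ds, sizes=(70, 10, 10))


class TestHaxbySplits:
    def test_each_trial_tested_once(self):
        ds = make_haxby_like()
        plans = make_cv_splits_haxby(ds, seed=0)
        assert len(plans) == 12
        tested = sorted(
            int(np.unique(ds.trial_ids[p.test_idx])[0]) for p in plans
        )
        assert tested == list(range(12))
        for p in plans:
            assert p.sampling_unit == "trials"
            used = np.concatenate([p.train_idx, p.val_idx, p.test_idx])
            assert np.array_equal(np.sort(used), np.arange(96))

    def test_dropped_trial_gives_eleven_plans(self):
        spec = SyntheticSpec(
            design=haxby_design(), grid_dims=(15, 15, 3), n_voxels=50,
            n_informative=8, drop_trial=4,
        )
        ds = make_haxby_like(spec)
        assert len(make_cv_splits_haxby(ds, seed=0)) == 11


class TestLinearSvm:
    # separable toy: margin 2 about x=0 on the first coordinate
    X4 = np.array([[-2.0, 0.0], [-1.0, 1.0], [1.0, 0.0], [2.0, 1.0]])
    y4 = np.array([0, 0, 1, 1])

    def test_separable_toy_zero_slack(self):
        clf = train_linear_svm(self.X4, self.y4, C=1.0)
        assert np.all(clf.predict(self.X4) == self.y4)
        assert np.all(clf.slack < 1e-6)

    def test_label_flip_symmetry(self):
        a = train_linear_svm(self.X4, self.y4)
        b = train_linear_svm(self.X4, 1 - self.y4)
        np.testing.assert_allclose(a.weights, -b.weights, atol=1e-8)

    def test_duplicated_training_set_same_rule(self):
        a = train_linear_svm(self.X4, self.y4)
        b = train_linear_svm(np.vstack([self.X4, self.X4]),
                             np.concatenate([self.y4, self.y4]))
        grid = np.random.default_rng(0).normal(size=(50, 2))
        np.testing.assert_allclose(a.decision_function(grid),
                                   b.decision_function(grid), atol=1e-6)

    def test_single_class_rejected(self):
        with pytest.raises(ParameterError):
            train_linear_svm(self.X4, np.zeros(4))


class TestRegularizedLr:
    X4 = TestLinearSvm.X4
    y4 = TestLinearSvm.y4

    def test_weak_penalty_fits_separable_toy(self):
        clf = train_regularized_lr(self.X4, self.y4, lam=1e-6)
        assert np.all(clf.predict(self.X4) == self.y4)

    def test_full_shrinkage_predicts_majority(self):
        X = np.vstack([self.X4, [[3.0, 0.0]]])
        y = np.array([0, 0, 1, 1, 1])  # majority class 1
        lm = lambda_max(X, y)
        clf = train_regularized_lr(X, y, lam=lm * 10)
        assert np.allclose(clf.weights, 0.0, atol=1e-6)
        assert np.all(clf.predict(X) == 1)

    def test_support_matches_selector_at_same_lambda(self, split_80):
        ds = small_dataset(seed=2, m=30)
        tr, va, _ = split_80
        from voxelstab.selectors import select_lasso

        sel = select_lasso(ds.X[tr], ds.labels[tr],
                           (ds.X[va], ds.labels[va]))
        lam = sel.params["lambda"]
        clf = train_regularized_lr(ds.X[tr], ds.labels[tr], lam=lam)
        support = frozenset(np.flatnonzero(
            np.abs(clf.weights[0]) > 1e-8
        ).tolist())
        assert support == sel.indices


class TestFinalizeAndTest:
    def test_accuracy_granularity_and_strong_signal(self):
        ds = small_dataset(seed=1)
        plans = make_cv_splits_starplus(ds, seed=1)
        sel = SelectedSet(indices=frozenset(ds.ground_truth), method="gt")
        for p in plans[:3]:
            acc = finalize_and_test(ds, p, sel, family="svm")
            assert acc in {float(v) for v in range(0, 101, 10)}
            assert acc >= 90.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(0)
        accs = []
        for seed in range(10):
            ds = small_dataset(seed=seed)
            shuffled = ds.labels.copy()
            rng.shuffle(shuffled)
            ds.labels = shuffled
            plans = make_cv_splits_starplus(ds, n_replications=2, seed=seed)
            sel = SelectedSet(indices=frozenset(range(10)), method="rand")
            for p in plans:
                accs.append(finalize_and_test(ds, p, sel, family="svm"))
        mean = np.mean(accs)
        se = 100 * np.sqrt(0.25 / (len(accs) * 10))
        assert abs(mean - 50.0) < 3 * se + 5

    def test_empty_selection_rejected(self):
        ds = small_dataset()
        plans = make_cv_splits_starplus(ds, seed=0)
        with pytest.raises(ParameterError):
            finalize_and_test(ds, plans[0],
                              SelectedSet(indices=frozenset(), method="x"))


class TestEvaluateMethod:
    def test_dominant_feature_gives_full_stability(self):
        # one overwhelming voxel: Corr with k=1 picks it in every
        # replication, so the cross-replication Jaccard stability is 1
        ds = small_dataset(seed=3, m=20, effect=8.0, n_informative=1)
        plans = make_cv_splits_starplus(ds, n_replications=3, seed=2)
        rep = evaluate_method(
            ds, SelectorConfig(method="Corr", k=1), plans,
            resampling=ResamplingPlan(n_resamples=10, seed=1),
        )
        assert rep.stability == 1.0
        assert rep.avg_n_selected == 1.0
        assert rep.mean_accuracy > 90.0

    def test_mean_std_recomputable_from_detail(self):
        ds = small_dataset(seed=4, m=20, effect=2.0)
        plans = make_cv_splits_starplus(ds, n_replications=4, seed=3)
        rep = evaluate_method(
            ds, SelectorConfig(method="Corr", k=3), plans,
            resampling=ResamplingPlan(n_resamples=10, seed=2),
        )
        accs = np.array(rep.accuracies)
        assert rep.mean_accuracy == pytest.approx(accs.mean())
        assert rep.std_accuracy == pytest.approx(accs.std(ddof=1))
        assert rep.avg_n_selected == pytest.approx(
            np.mean(rep.subset_sizes)
        )

    def test_requires_two_plans(self):
        ds = small_dataset()
        plans = make_cv_splits_starplus(ds, n_replications=1, seed=0)
        with pytest.raises(SchemeError):
            evaluate_method(ds, SelectorConfig(method="Corr", k=2), plans)


class TestThetaSweep:
    def test_profiles_computed_once_and_subsets_nested(self, monkeypatch):
        ds = small_dataset(seed=5, m=25, effect=3.0)
        plans = make_cv_splits_starplus(ds, n_replications=3, seed=4)
        calls = []
        orig = ev_mod.run_stability_selection

        def spy(*args, **kw):
            calls.append(1)
            return orig(*args, **kw)

        monkeypatch.setattr(ev_mod, "run_stability_selection", spy)
        reports = theta_sweep(
            ds, SelectorConfig(method="LASSO"), plans,
            thetas=(0.6, 0.7, 0.8, 0.9),
            resampling=ResamplingPlan(n_resamples=10, seed=5),
        )
        assert len(reports) == 4
        assert len(calls) == len(plans)  # cached across thetas
        labels = [r.method for r in reports]
        assert labels == [f"LASSO (theta={t:g})" for t in
                          (0.6, 0.7, 0.8, 0.9)]
        # final subset size cannot grow as theta rises
        sizes = [r.avg_n_selected for r in reports]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_rejects_filter_methods(self):
        ds = small_dataset()
        plans = make_cv_splits_starplus(ds, n_replications=2, seed=0)
        with pytest.raises(ParameterError):
            theta_sweep(ds, SelectorConfig(method="MI", k=3), plans)


def test_ground_truth_recovery_beats_random_subsets():
    # strong-signal data: the stability-selected subset should resemble the
    # planted voxels far more than a random subset of the same size does
    from voxelstab.stability import jaccard_index

    ds = small_dataset(seed=6, m=60, effect=3.0, n_informative=6)
    plans = make_cv_splits_starplus(ds, n_replications=2, seed=6)
    rep = evaluate_method(
        ds, SelectorConfig(method="LASSO"), plans,
        resampling=ResamplingPlan(n_resamples=25, seed=7), theta=0.6,
    )
    gt = set(ds.ground_truth)
    rng = np.random.default_rng(8)
    for subset in rep.subsets:
        j_real = jaccard_index(set(subset), gt)
        rand = set(rng.choice(60, size=max(len(subset), 1), replace=False))
        assert j_real > jaccard_index(rand, gt) or j_real > 0.3
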