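"""Outer cross-validation, final classifiers, and method-level reporting.

Two outer schemes mirror the benchmark experiments:

* sample-level random splits — per replication, disjoint training /
  test / validation sets of fixed sizes (default 60/10/10 of 80 samples,
  10 replications), stratified by class;
* leave-one-trial-out — one replication per trial; the held-out trial is
  the test set and the remaining trials are divided into training and
  validation blocks (default 6/5 of 11), so every trial is tested exactly
  once.

Per replication the stability-selection loop produces a final voxel
subset; the track's classifier (linear SVM for the filter/wrapper
methods, regularized logistic regression for the embedded ones) is then
retrained on training+validation restricted to that subset and scored on
the held-out test set.  A :class:`MethodReport` aggregates mean/STD
accuracy, the average subset size, and the mean pairwise Jaccard
stability of the per-replication final subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.svm import SVC

from voxelstab.errors import ParameterError, SchemeError
from voxelstab.selectors import (
    SelectedSet,
    SelectorConfig,
    default_size_grid,
    make_selector,
    rank_top_k,
    score_correlation,
    score_mutual_information,
    svm_rfe,
    tune_penalty,
    tune_subset_size,
)
from voxelstab.stability import (
    FrequencyProfile,
    ResamplingPlan,
    mean_pairwise_jaccard,
    run_stability_selection,
    threshold_select,
    topk_by_frequency,
)
from voxelstab.synthetic import FeatureDataset

EMBEDDED = {"LASSO", "ENet"}


@dataclass(frozen=True)
class CVPlan:
    """One replication's partition into training/validation/test indices."""

    replication_index: int
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    sampling_unit: str = "samples"  # or "trials"

    def __post_init__(self):
        for name in ("train_idx", "val_idx", "test_idx"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=int)
            )
        t, v, g = set(self.train_idx), set(self.val_idx), set(self.test_idx)
        if t & v or t & g or v & g:
            raise SchemeError("train/validation/test sets must be disjoint")
        if not g:
            raise SchemeError("test set must be nonempty")


@dataclass
class LinearClassifier:
    """A fitted linear decision rule over the selected features.

    ``weights`` is (n_machines, m'); binary problems have one machine and
    predict ``classes[1]`` when ``w @ x + b > 0``.  Multiclass problems
    hold one one-vs-rest machine per class and predict the argmax of the
    decision values.  ``slack`` (SVM only) holds the training hinge slacks
    ``max(0, 1 - t_i f(x_i))``.
    """

    family: str  # "svm" | "lr"
    classes: np.ndarray
    weights: np.ndarray
    intercepts: np.ndarray
    params: dict = field(default_factory=dict)
    slack: np.ndarray | None = None

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights.T + self.intercepts

    def predict(self, X: np.ndarray) -> np.ndarray:
        scores = self.decision_function(X)
        if self.classes.size == 2:
            return np.where(scores[:, 0] > 0, self.classes[1], self.classes[0])
        return self.classes[np.argmax(scores, axis=1)]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


def _stratified_partition(labels, idx, sizes, rng):
    """Disjoint index blocks of the given sizes, class-proportional."""
    idx = np.asarray(idx)
    y = np.asarray(labels)[idx]
    classes = np.unique(y)
    blocks = [[] for _ in sizes]
    perm_by_class = {c: rng.permutation(idx[y == c]) for c in classes}
    offsets = {c: 0 for c in classes}
    for b, size in enumerate(sizes):
        quotas = np.array([
            np.sum(y == c) * size / idx.size for c in classes
        ])
        base = np.floor(quotas).astype(int)
        short = size - base.sum()
        if short > 0:
            order = np.argsort(-(quotas - base), kind="stable")
            base[order[:short]] += 1
        for c, n_c in zip(classes, base):
            start = offsets[c]
            take = perm_by_class[c][start:start + n_c]
            if take.size < n_c:
                raise SchemeError("partition sizes exceed the class counts")
            blocks[b].append(take)
            offsets[c] = start + n_c
    return [np.sort(np.concatenate(b)) for b in blocks]


def make_cv_splits_starplus(
    dataset: FeatureDataset,
    n_replications: int = 10,
    sizes: tuple = (60, 10, 10),
    seed: int = 0,
) -> list[CVPlan]:
    """Sample-level random splits: (|D^T|, |D^G|, |D^V|) = ``sizes``.

    Each replication draws fresh disjoint, class-stratified sets from its
    own seed substream; with the defaults on an 80-sample dataset every
    sample is used in each replication.
    """
    n = dataset.n_samples
    if sum(sizes) > n:
        raise SchemeError(f"split sizes {sizes} exceed {n} samples")
    plans = []
    all_idx = np.arange(n)
    for r in range(n_replications):
        rng = _rng(seed, r)
        train, test, val = _stratified_partition(
            dataset.labels, all_idx, sizes, rng
        )
        plans.append(CVPlan(replication_index=r, train_idx=train,
                            val_idx=val, test_idx=test,
                            sampling_unit="samples"))
    return plans


def make_cv_splits_haxby(
    dataset: FeatureDataset,
    n_train_trials: int = 6,
    n_val_trials: int = 5,
    seed: int = 0,
) -> list[CVPlan]:
    """Leave-one-trial-out: every trial is the test set exactly once.

    The remaining trials are shuffled (per-replication substream) and split
    into ``n_train_trials`` training and ``n_val_trials`` validation trials;
    if fewer trials remain than the configured counts, the validation block
    absorbs the shortfall.
    """
    trials = np.unique(dataset.trial_ids)
    if trials.size < 3:
        raise SchemeError("need at least 3 trials for trial-level CV")
    plans = []
    for r, test_trial in enumerate(trials):
        rng = _rng(seed, r)
        others = rng.permutation(trials[trials != test_trial])
        n_train = min(n_train_trials, others.size - 1)
        train_trials = set(others[:n_train].tolist())
        # the validation block takes every remaining trial so the three
        # blocks always partition the dataset
        val_trials = set(others[n_train:].tolist())
        t_idx = np.flatnonzero(np.isin(dataset.trial_ids,
                                       sorted(train_trials)))
        v_idx = np.flatnonzero(np.isin(dataset.trial_ids,
                                       sorted(val_trials)))
        g_idx = np.flatnonzero(dataset.trial_ids == test_trial)
        plans.append(CVPlan(replication_index=r, train_idx=t_idx,
                            val_idx=v_idx, test_idx=g_idx,
                            sampling_unit="trials"))
    return plans


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0
                     ) -> LinearClassifier:
    """Soft-margin linear SVM (one-vs-rest for multiclass) with slacks."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ParameterError("single-class training set")
    if X.shape[1] < 1:
        raise ParameterError("need at least one feature")
    if classes.size == 2:
        codings = [np.where(y == classes[1], 1.0, -1.0)]
    else:
        codings = [np.where(y == c, 1.0, -1.0) for c in classes]
    W, b, slacks = [], [], []
    for t in codings:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X, t)
        w = clf.coef_[0]
        bi = float(clf.intercept_[0])
        W.append(w)
        b.append(bi)
        slacks.append(np.maximum(0.0, 1.0 - t * (X @ w + bi)))
    return LinearClassifier(
        family="svm",
        classes=classes,
        weights=np.array(W),
        intercepts=np.array(b),
        params={"C": C},
        slack=np.array(slacks).max(axis=0) if classes.size == 2
        else np.array(slacks),
    )


def train_regularized_lr(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    alpha: float = 0.0,
) -> LinearClassifier:
    """Elastic-net-penalized logistic regression at a fixed penalty.

    ``alpha`` weights the ridge term (0 = pure LASSO), matching the selector
    convention.  Features are standardized internally and the coefficients
    are folded back to the original scale, so the returned rule is linear
    in the raw features.
    """
    from voxelstab.selectors import _binary_codings, _logreg_path, _standardize

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ParameterError("single-class training set")
    if lam <= 0:
        raise ParameterError("lambda must be positive")
    Xs, mu, sd = _standardize(X)
    W, b = [], []
    for t in _binary_codings(y):
        y01 = (t > 0).astype(float)
        coefs, intercepts = _logreg_path(Xs, y01, np.array([lam]),
                                         l1_ratio=1.0 - alpha)
        w_std, b_std = coefs[0], intercepts[0]
        w = w_std / sd
        W.append(w)
        b.append(b_std - float(w @ mu))
    return LinearClassifier(
        family="lr",
        classes=classes,
        weights=np.array(W),
        intercepts=np.array(b),
        params={"lambda": lam, "alpha": alpha},
    )


def finalize_and_test(
    dataset: FeatureDataset,
    plan: CVPlan,
    selected: SelectedSet,
    family: str = "svm",
    svm_C: float = 1.0,
    lam: float | None = None,
    alpha: float = 0.0,
) -> float:
    """Retrain on training+validation over the selected voxels; % correct
    on the held-out test set."""
    if len(selected) == 0:
        raise ParameterError("selected feature set is empty")
    if plan.test_idx.size == 0:
        raise SchemeError("empty test set")
    cols = selected.as_array()
    fit_idx = np.sort(np.concatenate([plan.train_idx, plan.val_idx]))
    X_fit = dataset.X[np.ix_(fit_idx, cols)]
    y_fit = dataset.labels[fit_idx]
    if family == "svm":
        clf = train_linear_svm(X_fit, y_fit, C=svm_C)
    elif family == "lr":
        if lam is None:
            raise ParameterError("embedded track needs a tuned lambda")
        clf = train_regularized_lr(X_fit, y_fit, lam, alpha)
    else:
        raise ParameterError(f"unknown classifier family {family!r}")
    X_test = dataset.X[np.ix_(plan.test_idx, cols)]
    y_test = dataset.labels[plan.test_idx]
    return 100.0 * float(np.mean(clf.predict(X_test) == y_test))


@dataclass
class MethodReport:
    """One summary row: accuracy, spread, subset size and stability."""

    method: str
    mean_accuracy: float
    std_accuracy: float
    avg_n_selected: float
    stability: float
    n_replications: int
    accuracies: tuple = ()
    subset_sizes: tuple = ()
    subsets: tuple = ()
    fallback_count: int = 0

    @property
    def label(self) -> str:
        return self.method


def _sized_selector(config: SelectorConfig):
    """selector(X, y, k) for the filter/wrapper k-tuning step."""
    def run(X, y, k):
        if config.method == "MI":
            return rank_top_k(score_mutual_information(X, y, config.mi_bins),
                              k, method="MI")
        if config.method == "Corr":
            return rank_top_k(score_correlation(X, y), k, method="Corr")
        return svm_rfe(X, y, k, config.rfe_step_fraction, config.svm_C)
    return run


def _replication_outcome(dataset, plan, config, resampling, theta):
    """(profile, final SelectedSet, accuracy, tuned params) for one plan."""
    X, y = dataset.X, dataset.labels
    rep_plan = replace(
        resampling,
        seed=int(np.random.SeedSequence(
            [resampling.seed, plan.replication_index]
        ).generate_state(1)[0] % (2**31)),
    )
    if config.method in EMBEDDED:
        alpha = config.alpha if config.method == "ENet" else 0.0
        selector = make_selector(config)
        profile = run_stability_selection(
            X, y, plan.train_idx, plan.val_idx, selector, rep_plan
        )
        final = threshold_select(profile, theta, method=config.method)
        lam = tune_penalty(
            X[plan.train_idx], y[plan.train_idx],
            (X[plan.val_idx], y[plan.val_idx]),
            config.lambda_grid, alpha=alpha,
        )
        acc = finalize_and_test(dataset, plan, final, family="lr",
                                lam=lam, alpha=alpha)
        return profile, final, acc
    # filter/wrapper track: k tuned once per replication on (D^T, D^V)
    k = config.k
    if k is None:
        grid = config.size_grid or default_size_grid(X.shape[1])
        k = tune_subset_size(
            _sized_selector(config),
            X[plan.train_idx], y[plan.train_idx],
            X[plan.val_idx], y[plan.val_idx],
            grid, svm_C=config.svm_C,
        )
    fixed = replace(config, k=int(k))
    selector = make_selector(fixed)
    profile = run_stability_selection(
        X, y, plan.train_idx, plan.val_idx, selector, rep_plan
    )
    final = topk_by_frequency(profile, int(k), method=config.method)
    acc = finalize_and_test(dataset, plan, final, family="svm",
                            svm_C=config.svm_C)
    return profile, final, acc


def _aggregate(method_label, outcomes, n_plans) -> MethodReport:
    accs = np.array([acc for _, _, acc in outcomes])
    subsets = [final for _, final, _ in outcomes]
    sizes = np.array([len(s) for s in subsets], dtype=float)
    stability = mean_pairwise_jaccard(subsets).value
    return MethodReport(
        method=method_label,
        mean_accuracy=float(accs.mean()),
        std_accuracy=float(accs.std(ddof=1)) if accs.size > 1 else 0.0,
        avg_n_selected=float(sizes.mean()),
        stability=float(stability),
        n_replications=n_plans,
        accuracies=tuple(float(a) for a in accs),
        subset_sizes=tuple(int(s) for s in sizes),
        subsets=tuple(tuple(sorted(s.indices)) for s in subsets),
        fallback_count=sum(1 for s in subsets if s.fallback),
    )


def evaluate_method(
    dataset: FeatureDataset,
    config: SelectorConfig,
    plans: list[CVPlan],
    resampling: ResamplingPlan | None = None,
    theta: float = 0.6,
) -> MethodReport:
    """Full stability-selection benchmark of one method over all plans.

    Embedded methods threshold the frequency profile at ``theta``;
    filter/wrapper methods keep the k most frequent voxels with k tuned
    per replication on the validation set.
    """
    if len(plans) < 2:
        raise SchemeError("need >= 2 replications to measure stability")
    resampling = resampling or ResamplingPlan()
    outcomes = [
        _replication_outcome(dataset, plan, config, resampling, theta)
        for plan in plans
    ]
    label = config.method
    if config.method in EMBEDDED:
        label = f"{config.method} (theta={theta:g})"
    else:
        label = f"SVM-{config.method}"
    return _aggregate(label, outcomes, len(plans))


def theta_sweep(
    dataset: FeatureDataset,
    config: SelectorConfig,
    plans: list[CVPlan],
    thetas=(0.6, 0.7, 0.8, 0.9),
    resampling: ResamplingPlan | None = None,
) -> list[MethodReport]:
    """One report per threshold, reusing the frequency profiles.

    The resampling loop runs once per replication; each theta only
    re-thresholds the cached profiles, so the selector is invoked exactly
    ``len(plans) * n_resamples`` times regardless of how many thresholds
    are examined.
    """
    if config.method not in EMBEDDED:
        raise ParameterError("theta_sweep applies to embedded methods only")
    if len(plans) < 2:
        raise SchemeError("need >= 2 replications to measure stability")
    resampling = resampling or ResamplingPlan()
    X, y = dataset.X, dataset.labels
    alpha = config.alpha if config.method == "ENet" else 0.0
    cached = []
    for plan in plans:
        rep_plan = replace(
            resampling,
            seed=int(np.random.SeedSequence(
                [resampling.seed, plan.replication_index]
            ).generate_state(1)[0] % (2**31)),
        )
        selector = make_selector(config)
        profile = run_stability_selection(
            X, y, plan.train_idx, plan.val_idx, selector, rep_plan
        )
        lam = tune_penalty(
            X[plan.train_idx], y[plan.train_idx],
            (X[plan.val_idx], y[plan.val_idx]),
            config.lambda_grid, alpha=alpha,
        )
        cached.append((plan, profile, lam))
    reports = []
    for theta in thetas:
        outcomes = []
        for plan, profile, lam in cached:
            final = threshold_select(profile, theta, method=config.method)
            acc = finalize_and_test(dataset, plan, final, family="lr",
                                    lam=lam, alpha=alpha)
            outcomes.append((profile, final, acc))
        reports.append(_aggregate(
            f"{config.method} (theta={theta:g})", outcomes, len(plans)
        ))
    return reports
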