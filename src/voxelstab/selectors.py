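"""Base feature-selection methods under one selector contract.

Five methods, three families:

* filter   — rank voxels by |Pearson r| against the label coding
             (``score_correlation``) or by plug-in mutual information with
             equal-frequency binning (``score_mutual_information``), then
             keep the top k (``rank_top_k``);
* wrapper  — SVM recursive feature elimination (``svm_rfe``): repeatedly
             train a linear SVM and discard the fraction of surviving
             features with the smallest weight magnitudes;
* embedded — L1 (``select_lasso``) or elastic-net (``select_enet``)
             regularized logistic regression, where the selected set is the
             support of the fitted coefficients at a penalty strength tuned
             on a validation set.

Elastic-net convention
----------------------
The mixing weight ``alpha`` multiplies the *ridge* term:

    penalty = (1 - alpha) * sum|w| + alpha * sum w^2

so ``alpha = 0`` reduces exactly to the LASSO.  This is the opposite of the
scikit-learn/glmnet ``l1_ratio`` convention (``l1_ratio = 1 - alpha``); the
mapping is applied internally, but beware when porting hyperparameters.

Every selector is a pure function of (data, hyperparameters, seed); ties in
rankings are always broken toward the smallest feature index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from voxelstab.errors import DegenerateLabelsError, ParameterError

#: coefficients with absolute value below this are treated as zero
NONZERO_TOL = 1e-8

#: default number of points in an automatically built lambda grid
N_LAMBDA = 30

#: smallest grid lambda as a fraction of the data-dependent maximum
LAMBDA_MIN_RATIO = 1e-3


@dataclass(frozen=True)
class SelectorConfig:
    """Method identity plus hyperparameters.

    ``k`` is the target subset size for the filter/wrapper methods; ``None``
    means "tune on the validation set".  ``alpha`` follows the ridge-weight
    convention documented in the module docstring.
    """

    method: str  # one of MI, Corr, RFE, LASSO, ENet
    k: int | None = None
    mi_bins: int = 8
    rfe_step_fraction: float = 0.1
    lambda_grid: tuple | None = None
    alpha: float = 0.8
    svm_C: float = 1.0
    size_grid: tuple | None = None

    def __post_init__(self):
        if self.method not in {"MI", "Corr", "RFE", "LASSO", "ENet"}:
            raise ParameterError(f"unknown method {self.method!r}")
        if not (0 < self.rfe_step_fraction < 1):
            raise ParameterError("rfe_step_fraction must be in (0,1)")
        if self.lambda_grid is not None and len(self.lambda_grid) == 0:
            raise ParameterError("lambda_grid must be nonempty")
        if not (0 <= self.alpha <= 1):
            raise ParameterError("alpha must be in [0,1]")
        if self.svm_C <= 0:
            raise ParameterError("svm_C must be positive")
        if self.mi_bins < 2:
            raise ParameterError("mi_bins must be >= 2")


@dataclass(frozen=True)
class RankedScores:
    """Per-feature relevance scores with a deterministic ordering."""

    scores: np.ndarray
    ordering: np.ndarray  # feature indices, descending score, ties -> smaller index

    @classmethod
    def from_scores(cls, scores: np.ndarray) -> "RankedScores":
        scores = np.asarray(scores, dtype=float)
        # stable sort of -scores keeps the smallest index first among ties
        ordering = np.argsort(-scores, kind="stable")
        return cls(scores=scores, ordering=ordering)


@dataclass(frozen=True)
class SelectedSet:
    """A selected feature-index set with provenance."""

    indices: frozenset
    method: str
    params: dict = field(default_factory=dict)
    elimination_order: tuple | None = None  # RFE: first-removed first
    fallback: bool = False

    def __post_init__(self):
        object.__setattr__(
            self, "indices", frozenset(int(j) for j in self.indices)
        )

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.fromiter(sorted(self.indices), dtype=int)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise DegenerateLabelsError("labels contain a single class")
    return y


def _binary_codings(y: np.ndarray) -> list[np.ndarray]:
    """{-1,+1} codings: one for binary labels, one-vs-rest otherwise."""
    classes = np.unique(y)
    if classes.size == 2:
        return [np.where(y == classes[1], 1.0, -1.0)]
    return [np.where(y == c, 1.0, -1.0) for c in classes]


def score_correlation(X: np.ndarray, y: np.ndarray) -> RankedScores:
    """|Pearson r| of each feature against the class coding.

    Binary labels are coded {-1,+1}; for multiclass the score is the
    maximum over one-vs-rest codings.  Constant features score 0.
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    n = X.shape[0]
    Xc = X - X.mean(axis=0)
    sx = np.sqrt(np.sum(Xc**2, axis=0))
    best = np.zeros(X.shape[1])
    for t in _binary_codings(y):
        tc = t - t.mean()
        st = np.sqrt(np.sum(tc**2))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Xc.T @ tc) / (sx * st)
        r[~np.isfinite(r)] = 0.0
        best = np.maximum(best, np.abs(r))
    return RankedScores.from_scores(np.minimum(best, 1.0))


def _equal_frequency_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Rank-based equal-frequency discretisation into ``bins`` codes."""
    n = x.size
    ranks = rankdata(x, method="ordinal") - 1  # deterministic on ties
    return (ranks * bins // n).astype(int)


def _plugin_mi_bits(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information (bits) from the joint contingency table."""
    ai = np.unique(a, return_inverse=True)[1]
    bi = np.unique(b, return_inverse=True)[1]
    table = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(table, (ai, bi), 1.0)
    p = table / table.sum()
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (pi @ pj)[nz])))


def score_mutual_information(
    X: np.ndarray, y: np.ndarray, mi_bins: int = 8
) -> RankedScores:
    """Plug-in MI (bits) between each equal-frequency-binned feature and y."""
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    if mi_bins < 2:
        raise ParameterError("mi_bins must be >= 2")
    if mi_bins > X.shape[0]:
        raise ParameterError(
            f"mi_bins ({mi_bins}) exceeds the sample count ({X.shape[0]})"
        )
    scores = np.array(
        [_plugin_mi_bits(_equal_frequency_bins(X[:, j], mi_bins), y)
         for j in range(X.shape[1])]
    )
    return RankedScores.from_scores(np.maximum(scores, 0.0))


def rank_top_k(scores: RankedScores, k: int, method: str = "rank") -> SelectedSet:
    """The k highest-scoring features; ties broken toward smaller indices."""
    m = scores.scores.size
    if not (1 <= k <= m):
        raise ParameterError(f"k={k} outside 1..{m}")
    return SelectedSet(
        indices=frozenset(int(j) for j in scores.ordering[:k]),
        method=method,
        params={"k": int(k)},
    )


def _svm_weight_magnitudes(X, y, C):
    """Sum of |w_j| over the (one-vs-rest) linear SVM machines."""
    classes = np.unique(y)
    total = np.zeros(X.shape[1])
    if classes.size == 2:
        machines = [np.where(y == classes[1], 1, -1)]
    else:
        machines = [np.where(y == c, 1, -1) for c in classes]
    for t in machines:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X, t)
        total += np.abs(clf.coef_[0])
    return total


def svm_rfe(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    rfe_step_fraction: float = 0.1,
    svm_C: float = 1.0,
) -> SelectedSet:
    """Backward elimination by linear-SVM weight magnitude.

    Each round trains a linear SVM on the surviving features, ranks them by
    |w_j| (summed over one-vs-rest machines for multiclass) and removes
    ``max(1, floor(fraction * surviving))`` of the lowest-ranked, never
    overshooting below ``k``.  Removal ties go to the larger feature index
    (so the smaller index survives).
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    m = X.shape[1]
    if not (1 <= k <= m):
        raise ParameterError(f"k={k} outside 1..{m}")
    if not (0 < rfe_step_fraction < 1):
        raise ParameterError("rfe_step_fraction must be in (0,1)")
    surviving = np.arange(m)
    eliminated: list[int] = []
    while surviving.size > k:
        w = _svm_weight_magnitudes(X[:, surviving], y, svm_C)
        n_remove = min(
            max(1, int(rfe_step_fraction * surviving.size)), surviving.size - k
        )
        # stable sort ascending |w|: among ties the smaller index comes
        # first in `order`, so remove from the *end* of the tie run last;
        # we drop the first n_remove, i.e. smallest weights, ties -> the
        # smaller index is removed first among exactly equal weights.
        order = np.argsort(w, kind="stable")
        drop_local = order[:n_remove]
        eliminated.extend(int(surviving[j]) for j in sorted(drop_local,
                          key=lambda j: (w[j], surviving[j])))
        keep = np.ones(surviving.size, dtype=bool)
        keep[drop_local] = False
        surviving = surviving[keep]
    return SelectedSet(
        indices=frozenset(int(j) for j in surviving),
        method="RFE",
        params={"k": int(k), "rfe_step_fraction": rfe_step_fraction,
                "svm_C": svm_C},
        elimination_order=tuple(eliminated),
    )


# ---------------------------------------------------------------------------
# embedded methods: regularized logistic regression paths


def _standardize(X, eps=1e-12):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd < eps, 1.0, sd)
    return (X - mu) / sd, mu, sd


def lambda_max(X: np.ndarray, y: np.ndarray, l1_ratio: float = 1.0) -> float:
    """Smallest penalty strength at which every coefficient is zero.

    Uses the logistic-regression KKT bound ``max_j |x_j^T (y - mean(y))| / n``
    on standardized features (one-vs-rest maximum for multiclass), divided
    by the L1 fraction for elastic-net penalties.
    """
    Xs, _, _ = _standardize(np.asarray(X, dtype=float))
    n = Xs.shape[0]
    lam = 0.0
    for t in _binary_codings(np.asarray(y)):
        y01 = (t > 0).astype(float)
        resid = y01 - y01.mean()
        lam = max(lam, float(np.max(np.abs(Xs.T @ resid))) / n)
    if l1_ratio <= 0:
        return lam
    return lam / l1_ratio


def default_lambda_grid(
    X, y, l1_ratio: float = 1.0, n_lambda: int = N_LAMBDA,
    min_ratio: float = LAMBDA_MIN_RATIO,
) -> np.ndarray:
    """Decreasing log-spaced grid from the maximal penalty down to
    ``min_ratio`` times it."""
    lmax = lambda_max(X, y, l1_ratio)
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def _logreg_path(Xs, y01, lambdas, l1_ratio):
    """Regularization path over a decreasing lambda grid.

    Returns (coefs, intercepts): len(lambdas) x p and len(lambdas),
    for one binary problem with {0,1} labels on standardized features.
    The solver objective is matched to ``(1/n) loss + lambda * penalty``
    via ``C = 1 / (n * lambda)``.  Pure-L1 paths (``l1_ratio == 1``) use
    the exact coordinate-descent liblinear solver; mixed penalties use
    warm-started saga, whose proximal step still yields exact zeros.
    """
    n = Xs.shape[0]
    if l1_ratio == 1.0:
        # large intercept_scaling leaves the intercept effectively
        # unpenalized, matching the usual convention where only the
        # feature weights are shrunk
        est = LogisticRegression(solver="liblinear", l1_ratio=1.0,
                                 intercept_scaling=100.0,
                                 max_iter=1000, tol=1e-6, C=1.0)
        warm = False
    else:
        est = LogisticRegression(solver="saga", l1_ratio=l1_ratio,
                                 warm_start=True, max_iter=1000, tol=1e-4,
                                 C=1.0)
        warm = True
    coefs, intercepts = [], []
    with warnings.catch_warnings():
        if warm:
            # warm-started path fits: the few non-converged iterations at
            # the dense end of the grid only perturb coefficients far above
            # the support-detection threshold
            warnings.simplefilter("ignore", ConvergenceWarning)
        for lam in lambdas:
            est.set_params(C=1.0 / (n * lam))
            est.fit(Xs, y01)
            coefs.append(est.coef_[0].copy())
            intercepts.append(float(est.intercept_[0]))
    return np.array(coefs), np.array(intercepts)


def _regularized_path_select(X, y, lambda_grid, l1_ratio, validation, method):
    """Shared LASSO/elastic-net selection with validation-tuned lambda.

    ``validation`` is an (X_val, y_val) pair.  The grid is traversed in
    decreasing order; ties in validation accuracy keep the larger lambda
    (the sparser model).  Returns (SelectedSet, tuned_lambda).
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    if lambda_grid is None:
        lambda_grid = default_lambda_grid(X, y, l1_ratio=l1_ratio)
    lambdas = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
    if lambdas.size == 0:
        raise ParameterError("lambda_grid must be nonempty")
    X_val, y_val = validation
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val)
    Xs, mu, sd = _standardize(X)
    Xvs = (X_val - mu) / sd
    classes = np.unique(y)
    codings = _binary_codings(y)
    # per-lambda decision values on the validation set, per machine
    decisions = np.zeros((lambdas.size, X_val.shape[0], len(codings)))
    supports = [np.zeros(X.shape[1], dtype=bool) for _ in lambdas]
    for c, t in enumerate(codings):
        y01 = (t > 0).astype(float)
        coefs, intercepts = _logreg_path(Xs, y01, lambdas, l1_ratio)
        decisions[:, :, c] = (Xvs @ coefs.T).T + intercepts[:, None]
        for i in range(lambdas.size):
            supports[i] |= np.abs(coefs[i]) > NONZERO_TOL
    if classes.size == 2:
        preds = np.where(decisions[:, :, 0] > 0, classes[1], classes[0])
    else:
        preds = classes[np.argmax(decisions, axis=2)]
    accs = (preds == y_val[None, :]).mean(axis=1)
    best = 0
    for i in range(1, lambdas.size):
        if accs[i] > accs[best]:
            best = i
    sel = SelectedSet(
        indices=frozenset(int(j) for j in np.flatnonzero(supports[best])),
        method=method,
        params={"lambda": float(lambdas[best]), "l1_ratio": float(l1_ratio),
                "validation_accuracy": float(accs[best])},
    )
    return sel, float(lambdas[best])


def select_lasso(
    X: np.ndarray,
    y: np.ndarray,
    validation: tuple,
    lambda_grid=None,
) -> SelectedSet:
    """Support of L1-regularized logistic regression at a tuned penalty.

    The penalty strength is chosen from ``lambda_grid`` (default: 30
    log-spaced values from the data-dependent maximum down to 1e-3 of it)
    by accuracy on the validation pair; accuracy ties keep the larger
    lambda, i.e. the sparser model.  Multiclass problems are handled
    one-vs-rest and the supports are unioned.
    """
    sel, _ = _regularized_path_select(
        X, y, lambda_grid, l1_ratio=1.0, validation=validation, method="LASSO"
    )
    return sel


def select_enet(
    X: np.ndarray,
    y: np.ndarray,
    validation: tuple,
    lambda_grid=None,
    alpha: float = 0.8,
) -> SelectedSet:
    """Elastic-net analogue of :func:`select_lasso`.

    ``alpha`` weights the ridge term (``alpha = 0`` is exactly the LASSO);
    internally this maps to ``l1_ratio = 1 - alpha``.
    """
    if not (0 <= alpha <= 1):
        raise ParameterError("alpha must be in [0,1]")
    sel, _ = _regularized_path_select(
        X, y, lambda_grid, l1_ratio=1.0 - alpha, validation=validation,
        method="ENet",
    )
    return sel


def tune_penalty(
    X: np.ndarray,
    y: np.ndarray,
    validation: tuple,
    lambda_grid=None,
    alpha: float = 0.0,
) -> float:
    """Validation-tuned penalty strength for the regularized-LR family.

    Same grid search as :func:`select_lasso` / :func:`select_enet` but
    returning the chosen lambda instead of the support; used to refit the
    final embedded-track classifier.
    """
    _, lam = _regularized_path_select(
        X, y, lambda_grid, l1_ratio=1.0 - alpha, validation=validation,
        method="tune",
    )
    return lam


def tune_subset_size(
    selector,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    size_grid,
    svm_C: float = 1.0,
) -> int:
    """Validation-tuned subset size for a sized selector.

    ``selector(X, y, k)`` must return a :class:`SelectedSet`.  For each k in
    the grid the selection is made on the training pair, a linear SVM is
    trained on the selected columns and scored on the validation pair; the
    accuracy-maximising k wins, ties going to the smallest k.
    """
    sizes = sorted(int(k) for k in size_grid)
    if not sizes:
        raise ParameterError("size_grid must be nonempty")
    if X_val.shape[0] == 0:
        raise ParameterError("validation set is empty")
    best_k, best_acc = None, -1.0
    for k in sizes:
        sel = selector(X_train, y_train, k)
        cols = sel.as_array()
        clf = _fit_ovr_svm(X_train[:, cols], y_train, svm_C)
        acc = float(np.mean(_predict_ovr_svm(clf, X_val[:, cols]) == y_val))
        if acc > best_acc:
            best_k, best_acc = k, acc
    return best_k


def _fit_ovr_svm(X, y, C):
    classes = np.unique(y)
    if classes.size == 2:
        clf = SVC(kernel="linear", C=C)
        clf.fit(X, y)
        return ("binary", classes, clf)
    machines = []
    for c in classes:
        m = SVC(kernel="linear", C=C)
        m.fit(X, np.where(y == c, 1, -1))
        machines.append(m)
    return ("ovr", classes, machines)


def _predict_ovr_svm(model, X):
    kind, classes, inner = model
    if kind == "binary":
        return inner.predict(X)
    scores = np.column_stack([m.decision_function(X) for m in inner])
    return classes[np.argmax(scores, axis=1)]


def default_size_grid(m: int) -> tuple:
    """Candidate subset sizes for filter/wrapper tuning: a rounded
    log-spaced ladder capped at the feature count."""
    ladder = [1, 2, 5, 10, 20, 50, 100, 200, 500, 1000, 2000]
    sizes = [k for k in ladder if k < m]
    sizes.append(m)
    return tuple(sizes)


def make_selector(config: SelectorConfig):
    """Wrap a :class:`SelectorConfig` as the stability-loop contract.

    Returns ``selector(X_sub, y_sub, X_val, y_val) -> SelectedSet``.  Filter
    and wrapper methods need a fixed ``config.k`` (tuned beforehand via
    :func:`tune_subset_size`); embedded methods tune their penalty on the
    validation pair at every call.
    """
    method = config.method
    if method in {"MI", "Corr", "RFE"}:
        if config.k is None:
            raise ParameterError(
                f"{method} requires a fixed k inside the stability loop; "
                "tune it first with tune_subset_size"
            )

    def selector(X, y, X_val, y_val):
        if method == "MI":
            scores = score_mutual_information(X, y, config.mi_bins)
            return rank_top_k(scores, config.k, method="MI")
        if method == "Corr":
            scores = score_correlation(X, y)
            return rank_top_k(scores, config.k, method="Corr")
        if method == "RFE":
            return svm_rfe(X, y, config.k, config.rfe_step_fraction,
                           config.svm_C)
        if method == "LASSO":
            return select_lasso(X, y, (X_val, y_val), config.lambda_grid)
        return select_enet(X, y, (X_val, y_val), config.lambda_grid,
                           config.alpha)

    return selector
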