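"""Resampling stability selection and Jaccard stability metrics.

The stability-selection loop repeatedly draws half-sized subsamples of the
training set, runs a base selector on each (tuning its hyperparameters on a
held-out validation set), and accumulates per-voxel selection frequencies.
The final subset is either every voxel whose frequency reaches a threshold
theta (embedded methods) or the k most frequent voxels (filter/wrapper
methods, k tuned beforehand).

Stability between selected subsets is quantified by the Jaccard index
``J(A,B) = |A n B| / |A u B|`` and, for k subsets, by the mean over all
k(k-1)/2 unordered pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from voxelstab.errors import (
    ParameterError,
    SchemeError,
    StabilityIterationError,
)
from voxelstab.selectors import SelectedSet


@dataclass(frozen=True)
class ResamplingPlan:
    """How to resample the training set.

    Defaults follow the standard stability-selection recipe: 50 resamples
    of half the training samples, drawn without replacement, stratified by
    class so small classes cannot vanish from a subsample.
    """

    n_resamples: int = 50
    subsample_fraction: float = 0.5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_resamples < 1:
            raise ParameterError("n_resamples must be >= 1")
        if not (0 < self.subsample_fraction < 1):
            raise ParameterError("subsample_fraction must be in (0,1)")


@dataclass(frozen=True)
class FrequencyProfile:
    """Per-voxel selection counts over the resampling iterations."""

    counts: np.ndarray
    n_resamples: int

    def __post_init__(self):
        object.__setattr__(
            self, "counts", np.asarray(self.counts, dtype=int)
        )
        if np.any(self.counts < 0) or np.any(self.counts > self.n_resamples):
            raise ParameterError("counts must lie in 0..n_resamples")

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_resamples

    @property
    def n_features(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class StabilityScore:
    """Mean pairwise Jaccard similarity over k subsets."""

    value: float
    k: int

    def __post_init__(self):
        if self.k < 2:
            raise ParameterError("stability is defined for k >= 2 subsets")
        if not (0.0 <= self.value <= 1.0 + 1e-12):
            raise ParameterError("stability value outside [0,1]")


def _iteration_rng(seed: int, iteration: int) -> np.random.Generator:
    # substream per iteration: reproducible and order-independent
    return np.random.default_rng(np.random.SeedSequence([seed, iteration]))


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation preserving sum = total; ties by smaller index."""
    base = np.floor(quotas).astype(int)
    short = total - base.sum()
    if short > 0:
        remainders = quotas - base
        order = np.argsort(-remainders, kind="stable")
        base[order[:short]] += 1
    return base


def subsample(
    train_idx: np.ndarray,
    labels: np.ndarray,
    plan: ResamplingPlan,
    iteration: int,
) -> np.ndarray:
    """One subsample D^S of the training indices, deterministic per iteration.

    Draws ``floor(fraction * |D^T|)`` samples without replacement.  Under
    stratification the per-class counts follow largest-remainder rounding of
    the proportional quotas.
    """
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0:
        raise SchemeError("empty training set")
    rng = _iteration_rng(plan.seed, iteration)
    total = int(plan.subsample_fraction * train_idx.size)
    if total < 1:
        raise SchemeError("subsample would be empty")
    if not plan.stratified:
        pick = rng.choice(train_idx.size, size=total, replace=False)
        return np.sort(train_idx[pick])
    y = np.asarray(labels)[train_idx]
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts == 0):
        raise SchemeError("a class is absent from the training set")
    quotas = counts * (total / train_idx.size)
    alloc = _largest_remainder(quotas, total)
    if np.any(alloc > counts):
        raise SchemeError("stratified quota exceeds class size")
    out = []
    for c, n_c in zip(classes, alloc):
        members = train_idx[y == c]
        if n_c > 0:
            pick = rng.choice(members.size, size=int(n_c), replace=False)
            out.append(members[pick])
    return np.sort(np.concatenate(out))


def run_stability_selection(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    selector,
    plan: ResamplingPlan,
) -> FrequencyProfile:
    """Selection frequencies of every voxel over the resampling loop.

    ``selector(X_sub, y_sub, X_val, y_val)`` must return a
    :class:`~voxelstab.selectors.SelectedSet`; a failure in any iteration
    aborts with the iteration index rather than skipping silently.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    val_idx = np.asarray(val_idx)
    if val_idx.size == 0:
        raise SchemeError("validation set is empty")
    counts = np.zeros(X.shape[1], dtype=int)
    X_val, y_val = X[val_idx], y[val_idx]
    for it in range(plan.n_resamples):
        sub = subsample(train_idx, y, plan, it)
        try:
            selected = selector(X[sub], y[sub], X_val, y_val)
        except Exception as exc:  # noqa: BLE001 - re-raised with context
            raise StabilityIterationError(it, exc) from exc
        idx = selected.as_array()
        if idx.size and (idx.min() < 0 or idx.max() >= X.shape[1]):
            raise StabilityIterationError(
                it, ParameterError("selected index out of range")
            )
        counts[idx] += 1
    return FrequencyProfile(counts=counts, n_resamples=plan.n_resamples)


def threshold_select(
    profile: FrequencyProfile, theta: float, method: str = "threshold"
) -> SelectedSet:
    """Voxels whose selection frequency reaches theta.

    The comparison is ``>=`` so theta = 1.0 remains attainable.  If no voxel
    reaches the threshold the single most frequent voxel (smallest index on
    ties) is returned with ``fallback=True`` — a downstream classifier needs
    at least one feature.
    """
    if not (0 < theta <= 1):
        raise ParameterError("theta must be in (0,1]")
    freq = profile.frequencies
    hits = np.flatnonzero(freq >= theta)
    if hits.size:
        return SelectedSet(indices=frozenset(int(j) for j in hits),
                           method=method, params={"theta": theta})
    top = int(np.argmax(freq))  # argmax takes the smallest index on ties
    return SelectedSet(indices=frozenset({top}), method=method,
                       params={"theta": theta}, fallback=True)


def topk_by_frequency(
    profile: FrequencyProfile, k: int, method: str = "topk"
) -> SelectedSet:
    """The k most frequently selected voxels; ties to the smaller index."""
    m = profile.n_features
    if not (1 <= k <= m):
        raise ParameterError(f"k={k} outside 1..{m}")
    order = np.argsort(-profile.frequencies, kind="stable")
    return SelectedSet(indices=frozenset(int(j) for j in order[:k]),
                       method=method, params={"k": int(k)})


def jaccard_index(set_a, set_b) -> float:
    """|A n B| / |A u B|; undefined (raises) when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        raise ParameterError("Jaccard index undefined for two empty sets")
    return len(a & b) / len(union)


def mean_pairwise_jaccard(subsets) -> StabilityScore:
    """Average Jaccard index over all k(k-1)/2 unordered pairs of subsets."""
    sets = [set(s.indices) if isinstance(s, SelectedSet) else set(s)
            for s in subsets]
    k = len(sets)
    if k < 2:
        raise ParameterError("need at least two subsets")
    total = 0.0
    n_pairs = 0
    for a, b in combinations(sets, 2):
        total += jaccard_index(a, b)
        n_pairs += 1
    assert n_pairs == k * (k - 1) // 2
    return StabilityScore(value=total / n_pairs, k=k)
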