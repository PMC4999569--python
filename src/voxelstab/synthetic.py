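"""Synthetic event-related fMRI-like data with planted informative voxels.

Two generators emulate the structure of the classic benchmark experiments
used for MVPA decoding studies:

* ``make_starplus_like`` — 40 trials x 2 samples (one sentence, one picture
  per trial), binary labels, ~2000 candidate voxels;
* ``make_haxby_like``   — 12 trials x 8 object categories = 96 samples, up
  to 675 voxels, with an optional dropped (corrupted) trial.

The signal model is a class-conditional mean shift on the beta values of
the informative voxels; noise is i.i.d. Gaussian.  Informative voxels are
spatially clustered in spheres of a configurable radius to mimic the
clustered activations real decoding studies recover.  ``simulate_bold``
additionally provides a raw-signal stage: per-event amplitudes convolved
with the canonical HRF plus Gaussian scanner noise, which the GLM module
can invert back to betas.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from voxelstab.design import ExperimentDesign, haxby_design, starplus_design
from voxelstab.errors import DesignError, InvalidSpecError


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset.

    ``effect_size`` is the between-class difference in mean beta value of an
    informative voxel, in the same units as ``noise_sd`` (so effect_size =
    2 * noise_sd plants a 2-sigma contrast).  ``cluster_radius`` is in voxel
    grid units; radius 0 disables spatial clustering.  ``drop_trial``
    removes one whole trial's samples (as happens with a corrupted run).
    """

    design: ExperimentDesign
    grid_dims: tuple = (16, 16, 8)
    n_voxels: int = 2000
    n_informative: int = 20
    cluster_radius: float = 2.0
    effect_size: float = 1.0
    noise_sd: float = 1.0
    drop_trial: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_informative > self.n_voxels:
            raise InvalidSpecError(
                f"n_informative ({self.n_informative}) exceeds n_voxels "
                f"({self.n_voxels})"
            )
        if self.n_informative < 0 or self.n_voxels <= 0:
            raise InvalidSpecError("voxel counts must be non-negative")
        if self.effect_size < 0:
            raise InvalidSpecError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise InvalidSpecError("noise_sd must be > 0")
        if int(np.prod(self.grid_dims)) < self.n_voxels:
            raise InvalidSpecError(
                f"grid {self.grid_dims} holds fewer than {self.n_voxels} sites"
            )
        if self.drop_trial is not None and not (
            0 <= self.drop_trial < self.design.n_trials
        ):
            raise InvalidSpecError(
                f"drop_trial {self.drop_trial} outside "
                f"0..{self.design.n_trials - 1}"
            )


@dataclass
class FeatureDataset:
    """Samples x voxels beta matrix with labels, trials and voxel geometry.

    ``ground_truth`` is the set of planted informative voxel indices when
    the dataset is synthetic, else ``None``.
    """

    X: np.ndarray
    labels: np.ndarray
    trial_ids: np.ndarray
    voxel_coords: np.ndarray
    ground_truth: frozenset | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.trial_ids = np.asarray(self.trial_ids, dtype=int)
        self.voxel_coords = np.asarray(self.voxel_coords, dtype=int)
        n, m = self.X.shape
        if not np.all(np.isfinite(self.X)):
            raise InvalidSpecError("feature matrix contains non-finite values")
        if self.labels.size != n or self.trial_ids.size != n:
            raise InvalidSpecError("labels/trial_ids must have one entry per sample")
        if self.voxel_coords.shape != (m, 3):
            raise InvalidSpecError("voxel_coords must be m x 3")
        if self.ground_truth is not None:
            self.ground_truth = frozenset(int(j) for j in self.ground_truth)
            if self.ground_truth and (
                min(self.ground_truth) < 0 or max(self.ground_truth) >= m
            ):
                raise InvalidSpecError("ground_truth indices outside 0..m-1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def _place_voxels(spec: SyntheticSpec, rng: np.random.Generator):
    """Choose voxel grid sites and a (clustered) informative subset."""
    dims = spec.grid_dims
    sites = np.indices(dims).reshape(3, -1).T
    chosen = rng.choice(sites.shape[0], size=spec.n_voxels, replace=False)
    coords = sites[np.sort(chosen)]
    if spec.n_informative == 0:
        return coords, frozenset()
    if spec.cluster_radius <= 0:
        idx = rng.choice(spec.n_voxels, size=spec.n_informative, replace=False)
        return coords, frozenset(int(j) for j in idx)
    informative: list[int] = []
    taken = np.zeros(spec.n_voxels, dtype=bool)
    while len(informative) < spec.n_informative:
        center = int(rng.integers(spec.n_voxels))
        d2 = np.sum((coords - coords[center]) ** 2, axis=1)
        ball = np.flatnonzero((d2 <= spec.cluster_radius**2) & ~taken)
        for j in ball:
            if len(informative) >= spec.n_informative:
                break
            informative.append(int(j))
            taken[j] = True
    return coords, frozenset(informative)


def make_starplus_like(spec: SyntheticSpec | None = None) -> FeatureDataset:
    """Binary sentence/picture-style dataset: 40 trials x 2 samples.

    Each trial contributes one sample of each class, so labels are exactly
    balanced.  Informative voxels carry a mean shift of ``-effect_size/2``
    for class 0 and ``+effect_size/2`` for class 1 on top of
    ``Normal(0, noise_sd)`` noise.  Deterministic under a fixed seed.
    """
    if spec is None:
        spec = SyntheticSpec(design=starplus_design())
    design = spec.design
    if spec.drop_trial is not None:
        design = design.drop_trial(spec.drop_trial)
    rng = np.random.default_rng(spec.seed)
    coords, informative = _place_voxels(spec, rng)
    n = design.n_events
    labels = design.event_labels
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_voxels))
    if informative:
        idx = np.fromiter(sorted(informative), dtype=int)
        shift = np.where(labels == 0, -0.5, 0.5) * spec.effect_size
        X[:, idx] += shift[:, None]
    return FeatureDataset(
        X=X,
        labels=labels.copy(),
        trial_ids=design.trial_ids.copy(),
        voxel_coords=coords,
        ground_truth=informative,
    )


def make_haxby_like(spec: SyntheticSpec | None = None) -> FeatureDataset:
    """8-category object-vision-style dataset: 12 trials x 8 samples = 96.

    The informative voxels are partitioned into one cluster per category;
    a sample of category ``c`` has its category's voxels shifted by
    ``+effect_size`` (category-selective tuning).  ``drop_trial`` removes
    one trial, giving (12-1) x 8 = 88 samples.
    """
    if spec is None:
        spec = SyntheticSpec(
            design=haxby_design(),
            grid_dims=(15, 15, 3),
            n_voxels=675,
            n_informative=40,
            cluster_radius=1.0,
        )
    design = spec.design
    if spec.drop_trial is not None:
        design = design.drop_trial(spec.drop_trial)
    rng = np.random.default_rng(spec.seed)
    coords, informative = _place_voxels(spec, rng)
    n = design.n_events
    labels = design.event_labels
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_voxels))
    if informative:
        idx = np.fromiter(sorted(informative), dtype=int)
        # round-robin assignment of informative voxels to categories keeps
        # per-category cluster sizes within one of each other
        owner = np.arange(idx.size) % design.n_classes
        for c in range(design.n_classes):
            vox = idx[owner == c]
            if vox.size:
                X[np.ix_(labels == c, vox)] += spec.effect_size
    return FeatureDataset(
        X=X,
        labels=labels.copy(),
        trial_ids=design.trial_ids.copy(),
        voxel_coords=coords,
        ground_truth=informative,
    )


def simulate_bold(
    design: ExperimentDesign,
    voxel_betas: np.ndarray,
    noise_sd: float,
    seed: int = 0,
    oversampling: int | None = None,
) -> np.ndarray:
    """Raw BOLD series (n_scans x m) from per-event response amplitudes.

    Each voxel's series is the sum over events of ``amplitude x (boxcar of
    the stimulus duration convolved with the canonical double-gamma HRF,
    sampled at TR)`` plus ``Normal(0, noise_sd)`` scanner noise.

    ``voxel_betas`` is n_events x m.
    """
    from voxelstab import glm  # local import: glm depends only on design

    voxel_betas = np.atleast_2d(np.asarray(voxel_betas, dtype=float))
    if voxel_betas.shape[0] != design.n_events:
        raise DesignError(
            f"voxel_betas has {voxel_betas.shape[0]} rows, design has "
            f"{design.n_events} events"
        )
    if noise_sd < 0:
        raise DesignError("noise_sd must be >= 0")
    kwargs = {} if oversampling is None else {"oversampling": oversampling}
    dm = glm.build_design_matrix(design, drift=False, check_rank=False, **kwargs)
    regressors = dm.matrix[:, dm.event_columns]  # n_scans x n_events
    signal = regressors @ voxel_betas
    if noise_sd == 0:
        return signal
    rng = np.random.default_rng(seed)
    return signal + rng.normal(0.0, noise_sd, size=signal.shape)
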