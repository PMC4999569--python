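"""Beta-series GLM feature extraction from BOLD time series.

The BOLD series of every voxel is modelled as ``Y = X b + e`` where the
design matrix ``X`` holds one haemodynamic regressor *per stimulus event*
(the "beta-series" or least-squares-all parameterisation), an intercept,
and optionally a linear drift.  Each event's fitted coefficient per voxel
is one entry of the feature matrix handed to the decoding pipeline: rows
are events in presentation order, columns are voxels.

The haemodynamic response function (HRF) is the canonical double-gamma
(response peak 6 s, undershoot peak 16 s, undershoot ratio 1/6), built from
``scipy.stats.gamma`` densities and normalised to unit peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.stats import gamma as gamma_dist

from voxelstab.design import ExperimentDesign
from voxelstab.errors import DesignError, RankDeficiencyError

#: temporal oversampling factor used when building regressors
OVERSAMPLING = 16

#: canonical double-gamma HRF parameters (seconds / ratio)
HRF_PEAK = 6.0
HRF_UNDERSHOOT = 16.0
HRF_RATIO = 6.0
HRF_LENGTH = 32.0


def double_gamma_hrf(dt: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled every ``dt`` seconds, unit peak."""
    if dt <= 0:
        raise DesignError("HRF sampling interval must be positive")
    t = np.arange(0, HRF_LENGTH, dt)
    # gamma densities with shape = peak time + 1 and unit scale peak at t=peak
    peak = gamma_dist.pdf(t, HRF_PEAK + 1.0)
    undershoot = gamma_dist.pdf(t, HRF_UNDERSHOOT + 1.0)
    h = peak - undershoot / HRF_RATIO
    return h / h.max()


def event_regressor(
    onset: float,
    duration: float,
    tr: float,
    n_scans: int,
    oversampling: int = OVERSAMPLING,
) -> np.ndarray:
    """HRF-convolved boxcar for one event, sampled at scan times.

    A zero-duration event is treated as a unit impulse, so the regressor is
    the HRF impulse response shifted to the onset.
    """
    dt = tr / oversampling
    n_fine = n_scans * oversampling
    stim = np.zeros(n_fine)
    start = int(round(onset / dt))
    if start >= n_fine:
        raise DesignError(f"event onset {onset}s falls outside the scan window")
    if duration <= 0:
        stim[start] = 1.0 / dt
    else:
        stop = min(int(round((onset + duration) / dt)), n_fine)
        stim[start:stop] = 1.0
    hrf = double_gamma_hrf(dt)
    conv = np.convolve(stim, hrf)[:n_fine] * dt
    return conv[::oversampling]


@dataclass(frozen=True)
class DesignMatrix:
    """GLM design matrix with per-column roles.

    ``column_roles[j]`` is ``("event", i)`` for the regressor of event ``i``,
    ``("intercept",)`` or ``("drift",)``.
    """

    matrix: np.ndarray
    column_roles: tuple

    def __post_init__(self):
        if self.matrix.ndim != 2:
            raise DesignError("design matrix must be 2-D")
        if len(self.column_roles) != self.matrix.shape[1]:
            raise DesignError("one role per design-matrix column required")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def event_columns(self) -> np.ndarray:
        """Column indices that carry event regressors, in event order."""
        cols = [(role[1], j) for j, role in enumerate(self.column_roles)
                if role[0] == "event"]
        cols.sort()
        return np.array([j for _, j in cols], dtype=int)


@dataclass(frozen=True)
class BetaEstimates:
    """Per-voxel OLS coefficients (p x m) and residual variances (m,)."""

    beta_hat: np.ndarray
    residual_variance: np.ndarray
    column_roles: tuple

    def __post_init__(self):
        if not np.all(np.isfinite(self.beta_hat)):
            raise DesignError("non-finite beta estimates")


def _rank_check(X: np.ndarray, roles: tuple) -> None:
    """Raise RankDeficiencyError naming near-dependent columns."""
    p = X.shape[1]
    if X.shape[0] < p:
        raise RankDeficiencyError(
            f"{X.shape[0]} scans cannot identify {p} regressors",
            columns=range(p),
        )
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = piv[diag <= tol]
    if bad.size:
        names = ", ".join(str(roles[j]) for j in sorted(bad))
        raise RankDeficiencyError(
            f"design matrix is rank deficient; offending columns: {names}",
            columns=sorted(bad),
        )


def build_design_matrix(
    design: ExperimentDesign,
    drift: bool = False,
    oversampling: int = OVERSAMPLING,
    check_rank: bool = True,
) -> DesignMatrix:
    """One HRF-convolved regressor per event, plus intercept (plus drift).

    Raises :class:`RankDeficiencyError` (naming the offending columns) when
    events overlap so heavily that their regressors are linearly dependent.
    """
    last = design.onsets[-1] if design.n_events else 0.0
    if last >= design.scan_duration:
        raise DesignError(
            f"last onset {last}s is outside the {design.scan_duration}s scan window"
        )
    cols = [
        event_regressor(on, design.stimulus_duration, design.tr,
                        design.n_scans, oversampling)
        for on in design.onsets
    ]
    roles = [("event", i) for i in range(design.n_events)]
    cols.append(np.ones(design.n_scans))
    roles.append(("intercept",))
    if drift:
        t = np.linspace(-1.0, 1.0, design.n_scans)
        cols.append(t)
        roles.append(("drift",))
    X = np.column_stack(cols)
    dm = DesignMatrix(matrix=X, column_roles=tuple(roles))
    if check_rank:
        _rank_check(X, dm.column_roles)
    return dm


def fit_betas(Y: np.ndarray, design_matrix: DesignMatrix) -> BetaEstimates:
    """Ordinary least squares per voxel; no silent regularisation.

    ``Y`` is n_scans x m.  Returns the p x m coefficient matrix solving the
    normal equations (identical to the Moore-Penrose solution for a
    full-rank design) and the per-voxel residual variance RSS/(n-p).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    X = design_matrix.matrix
    if Y.shape[0] != X.shape[0]:
        raise DesignError(
            f"series has {Y.shape[0]} scans, design matrix {X.shape[0]}"
        )
    if not np.all(np.isfinite(Y)):
        raise DesignError("non-finite values in BOLD series")
    _rank_check(X, design_matrix.column_roles)
    beta, _, _, _ = linalg.lstsq(X, Y)
    resid = Y - X @ beta
    dof = X.shape[0] - X.shape[1]
    rss = np.sum(resid**2, axis=0)
    var = rss / dof if dof > 0 else np.full(Y.shape[1], np.nan)
    return BetaEstimates(
        beta_hat=beta,
        residual_variance=var,
        column_roles=design_matrix.column_roles,
    )


def assemble_feature_matrix(
    betas: BetaEstimates,
    design: ExperimentDesign,
    voxel_coords: np.ndarray | None = None,
):
    """Event-ordered beta feature matrix as a :class:`FeatureDataset`.

    Rows are events in presentation order; intercept/drift coefficients are
    excluded.  Labels and trial ids are attached from the design.  When no
    voxel coordinates are supplied, placeholder coordinates ``(j, 0, 0)``
    are generated.
    """
    from voxelstab.synthetic import FeatureDataset  # deferred: avoids cycle

    event_rows = [i for i, role in enumerate(betas.column_roles)
                  if role[0] == "event"]
    order = np.argsort([betas.column_roles[i][1] for i in event_rows])
    event_rows = np.array(event_rows)[order]
    if event_rows.size != design.n_events:
        raise DesignError(
            f"{event_rows.size} event betas but design has {design.n_events} events"
        )
    X = betas.beta_hat[event_rows, :]
    m = X.shape[1]
    if voxel_coords is None:
        voxel_coords = np.column_stack(
            [np.arange(m), np.zeros(m, int), np.zeros(m, int)]
        )
    return FeatureDataset(
        X=X,
        labels=design.event_labels.copy(),
        trial_ids=design.trial_ids.copy(),
        voxel_coords=np.asarray(voxel_coords, dtype=int),
        ground_truth=None,
    )
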