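"""Readers and writers for every external format the pipeline touches.

Canonical tabular format is TSV with ``#``-prefixed comment header lines
carrying the config hash and master seed, so every output file is traceable
to the run that produced it.  Decimal values are written at 10 significant
digits, which makes fixed-seed runs byte-identical across platforms.

Datasets round-trip through four files in one directory::

    features.tsv      samples x voxels beta matrix (header = voxel ids)
    labels.tsv        per-sample class label and trial id
    voxels.tsv        0-based x, y, z grid coordinates per voxel
    ground_truth.tsv  planted informative voxel indices (synthetic only)

Raw-signal exports use a 4D NIfTI volume plus a BIDS-style events table
(columns ``onset``, ``duration``, ``trial_type``).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from voxelstab.design import ExperimentDesign
from voxelstab.errors import VoxelStabError
from voxelstab.evaluation import MethodReport
from voxelstab.stability import FrequencyProfile
from voxelstab.synthetic import FeatureDataset

FLOAT_FMT = "%.10g"


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def _write_tsv(path: Path, df: pd.DataFrame, meta: dict | None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def _read_tsv(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_dataset(dataset: FeatureDataset, out_dir, meta: dict | None = None
                  ) -> dict:
    """Write the four-file tabular representation; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    m = dataset.n_voxels
    feat = pd.DataFrame(dataset.X, columns=[f"v{j}" for j in range(m)])
    lab = pd.DataFrame({"label": dataset.labels,
                        "trial_id": dataset.trial_ids})
    vox = pd.DataFrame(dataset.voxel_coords, columns=["x", "y", "z"])
    paths = {
        "features": out_dir / "features.tsv",
        "labels": out_dir / "labels.tsv",
        "voxels": out_dir / "voxels.tsv",
    }
    _write_tsv(paths["features"], feat, meta)
    _write_tsv(paths["labels"], lab, meta)
    _write_tsv(paths["voxels"], vox, meta)
    if dataset.ground_truth is not None:
        gt = pd.DataFrame({"voxel": sorted(dataset.ground_truth)})
        paths["ground_truth"] = out_dir / "ground_truth.tsv"
        _write_tsv(paths["ground_truth"], gt, meta)
    return paths


def read_dataset(in_dir) -> FeatureDataset:
    """Read a dataset written by :func:`write_dataset`."""
    in_dir = Path(in_dir)
    feat = _read_tsv(in_dir / "features.tsv")
    lab = _read_tsv(in_dir / "labels.tsv")
    vox = _read_tsv(in_dir / "voxels.tsv")
    gt_path = in_dir / "ground_truth.tsv"
    gt = None
    if gt_path.exists():
        gt = frozenset(int(v) for v in _read_tsv(gt_path)["voxel"])
    return FeatureDataset(
        X=feat.to_numpy(dtype=float),
        labels=lab["label"].to_numpy(),
        trial_ids=lab["trial_id"].to_numpy(),
        voxel_coords=vox[["x", "y", "z"]].to_numpy(dtype=int),
        ground_truth=gt,
    )


def write_profile(profile: FrequencyProfile, path, meta: dict | None = None
                  ) -> None:
    df = pd.DataFrame({
        "voxel": np.arange(profile.n_features),
        "count": profile.counts,
        "frequency": profile.frequencies,
    })
    _write_tsv(Path(path), df, meta)


def write_report(reports: list[MethodReport], path, meta: dict | None = None
                 ) -> None:
    """Summary TSV, one row per method: accuracy, STD, size, stability.

    The average-subset-size column is rounded to the nearest integer as in
    printed summaries; full precision lives in the detail file.
    """
    df = pd.DataFrame({
        "Method": [r.method for r in reports],
        "MeanAccuracy(%)": [round(r.mean_accuracy, 2) for r in reports],
        "STD(%)": [round(r.std_accuracy, 2) for r in reports],
        "AvgNumSelectedFeatures": [int(round(r.avg_n_selected))
                                   for r in reports],
        "Stability": [round(r.stability, 2) for r in reports],
    })
    _write_tsv(Path(path), df, meta)


def write_report_detail(reports: list[MethodReport], path,
                        meta: dict | None = None) -> None:
    rows = []
    for r in reports:
        for i, (acc, size, subset) in enumerate(
            zip(r.accuracies, r.subset_sizes, r.subsets)
        ):
            rows.append({
                "Method": r.method,
                "replication": i,
                "accuracy": acc,
                "subset_size": size,
                "subset": ",".join(str(j) for j in subset),
            })
    _write_tsv(Path(path), pd.DataFrame(rows), meta)


def write_selected(selected, path, meta: dict | None = None) -> None:
    df = pd.DataFrame({"voxel": selected.as_array()})
    all_meta = dict(meta or {})
    all_meta.update({"method": selected.method,
                     "params": json.dumps(selected.params),
                     "fallback": selected.fallback})
    _write_tsv(Path(path), df, all_meta)


# --------------------------------------------------------------------------
# raw-signal formats: 4D NIfTI + BIDS-style events


def write_bold_nifti(series: np.ndarray, coords: np.ndarray, grid_dims,
                     tr: float, path) -> None:
    """Pack an (n_scans x m) series into a 4D NIfTI volume.

    Voxels outside ``coords`` are zero.  The affine is diagonal with the TR
    on the time axis; no reorientation is applied.
    """
    n_scans, m = series.shape
    vol = np.zeros((*grid_dims, n_scans), dtype=np.float32)
    for j in range(m):
        x, y, z = coords[j]
        vol[x, y, z, :] = series[:, j]
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header["pixdim"][4] = tr
    nib.save(img, str(path))


def read_bold_nifti(path, coords: np.ndarray | None = None):
    """Unpack a 4D NIfTI into (n_scans x m) series.

    With ``coords`` given, exactly those voxels are extracted in order;
    otherwise every voxel with nonzero temporal variance is taken (in
    C-order) and its grid coordinates returned alongside.
    """
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4:
        raise VoxelStabError(f"{path} is not a 4D volume")
    if coords is None:
        mask = vol.std(axis=3) > 0
        coords = np.argwhere(mask)
    series = np.stack([vol[x, y, z, :] for x, y, z in coords], axis=1)
    tr = float(img.header["pixdim"][4])
    return series, np.asarray(coords, dtype=int), tr


def write_events(design: ExperimentDesign, path,
                 class_names: list | None = None) -> None:
    """BIDS-style events table: onset, duration, trial_type (+ trial id)."""
    names = class_names or [str(c) for c in range(design.n_classes)]
    df = pd.DataFrame({
        "onset": design.onsets,
        "duration": np.full(design.n_events, design.stimulus_duration),
        "trial_type": [names[c] for c in design.event_labels],
        "trial_id": design.trial_ids,
    })
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_events(path, tr: float, n_scans: int) -> ExperimentDesign:
    """Build an :class:`ExperimentDesign` from a BIDS-style events table.

    Columns are keyed by header name (order-independent); ``onset``,
    ``duration`` and ``trial_type`` are required, ``trial_id`` optional
    (defaulting to one trial per event).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"onset", "duration", "trial_type"}
    missing = required - set(df.columns)
    if missing:
        raise VoxelStabError(
            f"events table missing columns: {sorted(missing)}"
        )
    onsets = df["onset"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise VoxelStabError("event onsets must be strictly increasing")
    types = df["trial_type"].astype(str)
    classes = sorted(types.unique())
    labels = types.map({c: i for i, c in enumerate(classes)}).to_numpy()
    if "trial_id" in df.columns:
        trials = df["trial_id"].to_numpy(dtype=int)
    else:
        trials = np.arange(len(df))
    n_trials = np.unique(trials).size
    per_trial = len(df) // n_trials
    if n_trials * per_trial != len(df):
        # uneven trials: treat every event as its own trial
        trials = np.arange(len(df))
        n_trials, per_trial = len(df), 1
    durations = df["duration"].to_numpy(dtype=float)
    return ExperimentDesign(
        n_trials=n_trials,
        samples_per_trial=per_trial,
        n_classes=len(classes),
        onsets=onsets,
        event_labels=labels,
        trial_ids=trials,
        stimulus_duration=float(durations[0]),
        tr=tr,
        n_scans=n_scans,
    )


# --------------------------------------------------------------------------
# run configuration

KNOWN_CONFIG_KEYS = {
    "design", "n_trials", "n_voxels", "n_informative", "cluster_radius",
    "effect_size", "noise_sd", "drop_trial", "grid_dims", "seed",
    "methods", "thetas", "n_resamples", "subsample_fraction",
    "n_replications", "split_sizes", "n_train_trials", "n_val_trials",
    "alpha", "mi_bins", "rfe_step_fraction", "svm_C", "k", "out_dir",
}


def load_config(path) -> dict:
    """Flat key-value YAML config; unknown keys are rejected."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise VoxelStabError("config must be a mapping")
    unknown = set(cfg) - KNOWN_CONFIG_KEYS
    if unknown:
        raise VoxelStabError(f"unknown config keys: {sorted(unknown)}")
    return cfg
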