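"""From 4-D data to normalized trial-pattern matrices.

The pre-decoding chain is: per-run linear detrending of every voxel time
series, per-voxel z-scoring within run, extraction of one post-stimulus
volume per event, and per-trial pattern standardization.  The last step
removes the mean and scale of each trial's spatial pattern, so any
classification downstream must rest on the fine-grained spatial
distribution of the signal, never on bulk amplitude differences between
conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import detrend as _linear_detrend

from .simulate import AcquisitionParams, FunctionalDataset, validate_events

logger = logging.getLogger(__name__)

#: normalization modes: both steps, only one, or none
NORMALIZATION_MODES = ("both", "voxel", "pattern", "none")
#: onset-to-grid conventions for the k >= 1 volumes
ONSET_CONVENTIONS = ("containment", "ceil")


@dataclass
class TrialPatternSet:
    """Trials x voxels matrix with condition and run labels for one ROI."""

    X: np.ndarray
    labels: np.ndarray
    runs: np.ndarray
    roi: str
    volume_offset: int
    voxel_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.runs = np.asarray(self.runs)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D (trials x voxels)")
        if len(self.labels) != self.X.shape[0] or len(self.runs) != self.X.shape[0]:
            raise ValueError("labels and runs must have one entry per trial")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("trial patterns contain non-finite values")

    @property
    def n_trials(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.labels))

    def subset(self, mask: np.ndarray) -> "TrialPatternSet":
        return TrialPatternSet(
            X=self.X[mask], labels=self.labels[mask], runs=self.runs[mask],
            roi=self.roi, volume_offset=self.volume_offset,
            voxel_indices=self.voxel_indices,
        )

    def with_labels(self, labels: np.ndarray) -> "TrialPatternSet":
        return TrialPatternSet(
            X=self.X, labels=np.asarray(labels), runs=self.runs, roi=self.roi,
            volume_offset=self.volume_offset, voxel_indices=self.voxel_indices,
        )


def detrend_run(series: np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend (slope and intercept).

    ``series`` is 1-D (time) or 2-D (voxels x time); detrending acts along
    the last axis.  Runs shorter than 3 volumes are rejected: a line fits
    two points exactly, leaving nothing.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 3:
        raise ValueError(
            f"run has {series.shape[-1]} volumes; >= 3 required to detrend"
        )
    return _linear_detrend(series, axis=-1, type="linear")


def select_trial_volume(onset: float, acq: AcquisitionParams, k: int,
                        convention: str = "containment") -> int:
    """Map an event onset to the run-volume index of its k-th volume.

    ``k = 0`` returns the volume whose acquisition window contains the
    onset (the pre/at-onset volume).  ``k >= 1`` returns the k-th complete
    volume beginning after the onset: with the default ``containment``
    convention the first volume starting strictly after the onset is k=1.
    With ``ceil``, an onset falling exactly on the grid counts its own
    volume as k=1.

    Raises ``IndexError`` when the requested volume lies beyond the run;
    callers drop such trials.
    """
    if convention not in ONSET_CONVENTIONS:
        raise ValueError(f"unknown onset convention {convention!r}")
    if k < 0 or k > 6:
        raise ValueError(f"k must be in 0..6, got {k}")
    if onset < 0:
        raise ValueError("onset must be non-negative")
    if k == 0:
        idx = int(np.floor(onset / acq.tr))
    else:
        if convention == "containment":
            first_after = int(np.floor(onset / acq.tr)) + 1
        else:  # ceil: an on-grid onset counts its own volume as k=1
            first_after = int(np.ceil(onset / acq.tr))
        idx = first_after + (k - 1)
    if idx >= acq.n_volumes_per_run:
        raise IndexError(
            f"volume {idx} for onset {onset:.1f}s (k={k}) is beyond the run "
            f"({acq.n_volumes_per_run} volumes)"
        )
    return idx


def _normalize_rows(X: np.ndarray, trial_ids) -> np.ndarray:
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    bad = np.flatnonzero(sd.ravel() == 0)
    if bad.size:
        raise ValueError(
            "zero-variance pattern rows for trials "
            f"{[trial_ids[i] for i in bad]}; cannot standardize"
        )
    return (X - mean) / sd


def extract_patterns(data: FunctionalDataset,
                     events: pd.DataFrame,
                     roi: np.ndarray,
                     k: int = 2,
                     normalization: str = "both",
                     roi_name: str = "roi",
                     detrend: bool = True,
                     convention: str = "containment") -> TrialPatternSet:
    """Extract one normalized spatial pattern per event from an ROI.

    Per run, ROI voxel time series are linearly detrended and (modes
    ``both``/``voxel``) z-scored across the run's volumes; the volume
    selected by :func:`select_trial_volume` then yields one trials x voxels
    row per event.  Modes ``both``/``pattern`` standardize each row to
    mean 0 / sd 1 across voxels.  Events whose extraction volume falls
    outside the run are dropped with a logged warning, never imputed.
    """
    if normalization not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {normalization!r}")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != data.shape:
        raise ValueError("ROI mask shape does not match the data grid")
    n_vox = int(np.count_nonzero(roi))
    if n_vox < 2:
        raise ValueError(f"ROI has {n_vox} voxels; at least 2 required")
    validate_events(events)

    vox = np.flatnonzero(roi.reshape(-1))
    flat = data.data.reshape(-1, data.data.shape[3])
    acq = data.acquisition

    rows, labels, runs, trial_ids = [], [], [], []
    n_dropped = 0
    for run in sorted(events["run"].unique()):
        sl = data.run_slice(int(run))
        block = flat[vox, sl].astype(float)
        if detrend:
            block = detrend_run(block)
        if normalization in ("both", "voxel"):
            sd = block.std(axis=1, keepdims=True)
            sd[sd == 0] = 1.0  # dead voxels stay zero
            block = (block - block.mean(axis=1, keepdims=True)) / sd
        ev_run = events[events["run"] == run]
        for trial_id, row in ev_run.iterrows():
            try:
                idx = select_trial_volume(float(row["onset"]), acq, k,
                                          convention=convention)
            except IndexError as exc:
                n_dropped += 1
                logger.warning("dropping trial %s: %s", trial_id, exc)
                continue
            rows.append(block[:, idx])
            labels.append(row["condition"])
            runs.append(int(run))
            trial_ids.append(trial_id)
    if not rows:
        raise ValueError("no events survived volume extraction")
    if n_dropped:
        logger.warning("dropped %d/%d trials with out-of-run volumes",
                       n_dropped, len(events))
    X = np.vstack(rows)
    if normalization in ("both", "pattern"):
        X = _normalize_rows(X, trial_ids)
    return TrialPatternSet(
        X=X, labels=np.asarray(labels), runs=np.asarray(runs),
        roi=roi_name, volume_offset=k, voxel_indices=vox,
    )


def motion_by_condition(motion: pd.DataFrame,
                        events: pd.DataFrame,
                        acq: AcquisitionParams,
                        k: int = 2) -> pd.DataFrame:
    """Per-condition summary of realignment parameters at trial volumes.

    ``motion`` has one row per acquired volume (all runs concatenated) and
    one column per realignment parameter (conventionally 6: three
    translations, three rotations).  For each event the parameters of its
    extraction volume are collected; the result is the per-condition mean
    of each parameter, ready for a between-condition comparison.  No
    motion correction is performed here.
    """
    if len(motion) != acq.n_volumes_total:
        raise ValueError(
            f"motion table has {len(motion)} rows; expected one per volume "
            f"({acq.n_volumes_total})"
        )
    validate_events(events)
    rows = []
    for _, ev in events.iterrows():
        try:
            idx = select_trial_volume(float(ev["onset"]), acq, k)
        except IndexError:
            continue
        rows.append((ev["condition"],
                     *motion.iloc[int(ev["run"]) * acq.n_volumes_per_run
                                  + idx]))
    table = pd.DataFrame(rows, columns=["condition", *motion.columns])
    return table.groupby("condition").mean()


def pool_labels(patterns: TrialPatternSet,
                mapping: dict[str, str]) -> TrialPatternSet:
    """Relabel trials by pooling sub-conditions (e.g. two touch locations
    into one 'touch' class).  Unmapped labels are kept unchanged."""
    pooled = np.asarray([mapping.get(lab, lab) for lab in patterns.labels])
    return patterns.with_labels(pooled)
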