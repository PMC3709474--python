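"""Reading and writing the pipeline's file formats.

Functional data, masks, parcellations and maps travel as NIfTI-1; event
tables and result tables as tab-separated text; generation parameters as
JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .simulate import AcquisitionParams, EVENT_COLUMNS, FunctionalDataset


def save_dataset(dataset: FunctionalDataset, path) -> None:
    img = nib.Nifti1Image(dataset.data.astype(np.float32), dataset.affine)
    img.header.set_zooms((*img.header.get_zooms()[:3],
                          dataset.acquisition.tr))
    nib.save(img, str(path))


def load_dataset(path, acquisition: AcquisitionParams,
                 run_index: np.ndarray | None = None) -> FunctionalDataset:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if run_index is None:
        nv = acquisition.n_volumes_per_run
        run_index = np.repeat(np.arange(acquisition.n_runs), nv)
    return FunctionalDataset(data=data, run_index=np.asarray(run_index),
                             acquisition=acquisition,
                             affine=np.asarray(img.affine))


def save_mask(mask: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(mask).astype(np.uint8),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def load_labelled_volume(path) -> np.ndarray:
    return np.rint(np.asarray(nib.load(str(path)).dataobj)).astype(int)


def save_map(values: np.ndarray, voxel_indices: np.ndarray,
             shape: tuple[int, int, int], path,
             affine: np.ndarray | None = None) -> None:
    """Scatter a per-ROI-voxel vector back onto the grid and save it."""
    vol = np.full(int(np.prod(shape)), np.nan, dtype=np.float32)
    vol[np.asarray(voxel_indices)] = values
    img = nib.Nifti1Image(vol.reshape(shape),
                          np.eye(4) if affine is None else affine)
    nib.save(img, str(path))


def save_events(events: pd.DataFrame, path) -> None:
    events.loc[:, list(EVENT_COLUMNS)].to_csv(str(path), sep="\t", index=False)


def load_events(path) -> pd.DataFrame:
    events = pd.read_csv(str(path), sep="\t")
    missing = set(EVENT_COLUMNS) - set(events.columns)
    if missing:
        raise ValueError(f"event file missing columns: {sorted(missing)}")
    return events


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_sidecar(params, path) -> None:
    """Echo generation/analysis parameters to a JSON sidecar."""
    Path(path).write_text(json.dumps(_jsonable(params), indent=2,
                                     sort_keys=True) + "\n")
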