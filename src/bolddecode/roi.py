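"""ROI bookkeeping: erosion, parcellation extraction, hemisphere splits.

All operations are pure — input masks and volumes are never mutated.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

_STRUCT = {
    6: ndimage.generate_binary_structure(3, 1),
    26: ndimage.generate_binary_structure(3, 3),
}


def erode_mask(mask: np.ndarray, connectivity: int = 6) -> np.ndarray:
    """Peel the outer voxel layer off a binary mask.

    A voxel survives iff all of its face neighbours (6-connectivity, the
    default) lie inside the mask; voxels on the grid boundary are treated
    as having outside neighbours and are removed.  ``connectivity=26``
    peels using the full cube neighbourhood instead.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3-D volume")
    if not mask.any():
        raise ValueError("mask is empty")
    if connectivity not in _STRUCT:
        raise ValueError("connectivity must be 6 or 26")
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT[connectivity],
                                    border_value=0)
    if not eroded.any():
        raise ValueError(
            "erosion removed every voxel; use a larger ROI or skip erosion"
        )
    return eroded


def parcellation_rois(parcellation: np.ndarray,
                      min_voxels: int = 1,
                      names: dict[int, str] | None = None
                      ) -> dict[str, np.ndarray]:
    """Split an integer-labelled volume into one binary mask per label.

    Label 0 is background.  Labels with fewer than ``min_voxels`` voxels
    are reported and skipped; mask names come from ``names`` when given,
    else ``"label_<k>"``.
    """
    parcellation = np.asarray(parcellation)
    if parcellation.ndim != 3:
        raise ValueError("parcellation must be a 3-D labelled volume")
    if not np.issubdtype(parcellation.dtype, np.integer):
        if not np.allclose(parcellation, np.round(parcellation)):
            raise ValueError("parcellation labels must be integers")
        parcellation = np.round(parcellation).astype(int)
    labels, counts = np.unique(parcellation[parcellation > 0],
                               return_counts=True)
    rois: dict[str, np.ndarray] = {}
    skipped = []
    for lab, cnt in zip(labels, counts):
        if cnt < min_voxels:
            skipped.append((int(lab), int(cnt)))
            continue
        name = names.get(int(lab), f"label_{lab}") if names else f"label_{lab}"
        rois[name] = parcellation == lab
    if skipped:
        logger.warning("skipped %d labels below min_voxels=%d: %s",
                       len(skipped), min_voxels, skipped)
    if not rois:
        raise ValueError(
            f"no parcellation label has >= {min_voxels} voxels"
        )
    return rois


def split_hemispheres(mask: np.ndarray,
                      plane: int | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Split a mask into (left, right) halves along the x axis.

    ``plane`` is the first x index assigned to the right half; by default
    the grid midline ``nx // 2``.  With an odd grid the extra slice goes to
    the left half.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be a 3-D volume")
    nx = mask.shape[0]
    if plane is None:
        plane = (nx + 1) // 2
    if not 0 < plane < nx:
        raise ValueError(f"plane must lie strictly inside 0..{nx}")
    left = mask.copy()
    left[plane:] = False
    right = mask.copy()
    right[:plane] = False
    return left, right
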