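"""ROI erosion, hippocampal measurement extraction, asymmetry indices.

The asymmetry index (AI) of a modality is the left-minus-right
hippocampal z-score; raw left-minus-right differences (Delta_L-R) and
their ipsilateral-minus-contralateral orientation (Delta_I-C, negated for
right-sided epilepsy) quantify the same asymmetry on the measurement
scale.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure

from .types import ScalarMap

__all__ = [
    "erode_mask",
    "extract_roi_mean",
    "asymmetry_index",
    "pooled_ic_delta",
    "control_reference_interval",
]

logger = logging.getLogger(__name__)

# 6-connected 3-D cross: erodes one voxel shell per iteration.
_CROSS = generate_binary_structure(3, 1)


def erode_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Binary erosion with a 6-connected cross, repeated ``iterations`` times.

    Erosion trims the partial-volume shell of a segmentation. If erosion
    would empty the mask (tiny ROI), a warning is logged and the original
    mask is returned unchanged.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot erode an empty mask")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return mask.copy()
    eroded = binary_erosion(mask, _CROSS, iterations=iterations, border_value=0)
    if not eroded.any():
        logger.warning(
            "erosion (%d iter) emptied a %d-voxel mask; falling back to "
            "the un-eroded mask", iterations, int(mask.sum()),
        )
        return mask.copy()
    return eroded


def extract_roi_mean(
    scalar_map: ScalarMap, roi_mask: np.ndarray, roi_name: str = "ROI"
) -> float:
    """Arithmetic mean of valid voxels inside an ROI.

    Invalid voxels (e.g. CSF-excluded T2) drop out of the average. Raises
    if no valid voxel remains, naming the ROI.
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != scalar_map.shape:
        raise ValueError(f"{roi_name}: mask shape does not match map")
    sel = roi_mask & scalar_map.valid_mask
    if not sel.any():
        raise ValueError(f"{roi_name}: no valid voxels in ROI")
    return float(scalar_map.data[sel].mean())


def asymmetry_index(left: float, right: float) -> float:
    """Left-minus-right asymmetry."""
    if not (np.isfinite(left) and np.isfinite(right)):
        raise ValueError("asymmetry index requires finite left/right values")
    return float(left) - float(right)


def pooled_ic_delta(subgroup_deltas: Sequence[tuple[float, int, str]]) -> float:
    """Pool subgroup left-minus-right means into one I-C oriented mean.

    Each entry is (mean L-R delta, n, laterality "L"/"R"). Right-sided
    subgroups are negated (ipsilateral is the right side there), then a
    sample-size-weighted mean is returned.
    """
    if not subgroup_deltas:
        raise ValueError("no subgroups to pool")
    num = 0.0
    den = 0
    for mean, n, lat in subgroup_deltas:
        if n <= 0:
            raise ValueError("subgroup size must be positive")
        if lat not in ("L", "R"):
            raise ValueError(f"laterality must be 'L' or 'R', got {lat!r}")
        num += (mean if lat == "L" else -mean) * n
        den += n
    return num / den


def control_reference_interval(
    control_ais: Sequence[float], level: float = 0.95
) -> tuple[float, float]:
    """Central ``level`` empirical percentile interval of control AIs.

    A patient AI strictly inside the interval is "within normal range".
    ``level=1.0`` returns the control (min, max).
    """
    ais = np.asarray(control_ais, dtype=float)
    if ais.size < 3:
        raise ValueError("need at least 3 controls for a reference interval")
    if not (0 < level <= 1):
        raise ValueError("level must be in (0, 1]")
    if level == 1.0:
        return float(ais.min()), float(ais.max())
    alpha = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(ais, [alpha, 100.0 - alpha])
    return float(lo), float(hi)
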