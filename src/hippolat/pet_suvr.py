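"""PET intensity normalization to SUVR by global mean scaling.

Dividing each voxel by the mean uptake over a reference region (here the
whole brain mask by default) cancels injected dose and body-weight
factors, yielding a dimensionless standardized uptake value ratio whose
in-mask mean is exactly 1.
"""

from __future__ import annotations

import numpy as np

from .types import ScalarMap

__all__ = ["compute_suvr"]


def compute_suvr(pet: ScalarMap, brain_mask: np.ndarray) -> ScalarMap:
    """Scale a PET uptake map by its mean over ``brain_mask``.

    Out-of-mask voxels are invalid in the output. Raises on an empty mask,
    negative uptake, or zero mean (nothing to normalize by).
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != pet.shape:
        raise ValueError("mask shape does not match PET volume")
    region = brain_mask & pet.valid_mask
    if not region.any():
        raise ValueError("empty normalization region")
    vals = pet.data[region]
    if np.any(vals < 0):
        raise ValueError("PET uptake must be non-negative")
    mean = vals.mean()
    if mean <= 0:
        raise ValueError("mean uptake over the mask is zero; cannot scale")
    out = np.full(pet.shape, np.nan)
    out[region] = pet.data[region] / mean
    return ScalarMap(out, pet.voxel_size, units="suvr")
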