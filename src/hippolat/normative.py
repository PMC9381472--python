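"""Normative (control-referenced) voxel-wise z-score mapping.

Each control map is smoothed with an isotropic Gaussian specified by its
FWHM in mm (SD = FWHM / (2*sqrt(2*ln 2))), then per-voxel mean and sample
SD over controls define the normative model. A patient map smoothed at
the same FWHM is standardized voxel-by-voxel: z = (x - mu) / sigma.

Smoothing is mask-normalized: invalid voxels contribute no mass and never
become valid, so CSF-excluded or failed-fit voxels do not leak into their
neighbours.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

from .types import NormativeModel, ScalarMap

__all__ = [
    "fwhm_to_sigma",
    "smooth_gaussian",
    "build_normative_model",
    "zscore_map",
    "SD_FLOOR",
]

#: Control SDs below this (in modality units) mark a voxel invalid for
#: z-scoring: degenerate control variance would produce meaningless z.
SD_FLOOR = 1e-6


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian SD corresponding to a full width at half maximum."""
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_gaussian(scalar_map: ScalarMap, fwhm: float) -> ScalarMap:
    """Smooth a map with an isotropic Gaussian of the given FWHM (mm).

    The kernel SD is converted to voxel units per axis using the map's
    voxel size. fwhm = 0 returns an identical copy. Invalid voxels are
    excluded via normalized convolution (smooth(data*m)/smooth(m)) and
    stay invalid in the output.
    """
    if fwhm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm == 0:
        return scalar_map.copy()
    sigma_mm = fwhm_to_sigma(fwhm)
    sigma_vox = [sigma_mm / v for v in scalar_map.voxel_size]
    mask = scalar_map.valid_mask
    filled = np.where(mask, scalar_map.data, 0.0)
    num = gaussian_filter(filled, sigma_vox, mode="constant")
    den = gaussian_filter(mask.astype(float), sigma_vox, mode="constant")
    out = np.full(scalar_map.shape, np.nan)
    ok = mask & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return ScalarMap(out, scalar_map.voxel_size, scalar_map.units)


def build_normative_model(
    control_maps: list[ScalarMap],
    modality: str,
    fwhm: float,
    presmoothed: bool = False,
) -> NormativeModel:
    """Voxel-wise control mean and sample SD (n-1 denominator).

    Each control is smoothed at ``fwhm`` first (skip with
    ``presmoothed=True`` if the caller already did). A voxel is valid only
    where every control is valid.
    """
    if len(control_maps) < 2:
        raise ValueError("need at least 2 controls for a normative model")
    shape = control_maps[0].shape
    vox = control_maps[0].voxel_size
    for m in control_maps[1:]:
        if m.shape != shape or m.voxel_size != vox:
            raise ValueError("control maps must share one grid")
    if not presmoothed:
        control_maps = [smooth_gaussian(m, fwhm) for m in control_maps]
    stack = np.stack([m.data for m in control_maps])
    valid = np.all(np.isfinite(stack), axis=0)
    mean = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    mean[valid] = stack[:, valid].mean(axis=0)
    sd[valid] = stack[:, valid].std(axis=0, ddof=1)
    units = control_maps[0].units
    return NormativeModel(
        mean_map=ScalarMap(mean, vox, units),
        sd_map=ScalarMap(sd, vox, units),
        n_controls=len(control_maps),
        modality=modality,
        smoothing_fwhm=float(fwhm),
    )


def zscore_map(
    patient_map: ScalarMap,
    model: NormativeModel,
    sd_floor: float = SD_FLOOR,
) -> ScalarMap:
    """Standardize a (pre-smoothed) patient map against a normative model.

    z = (x - mu_HC) / sigma_HC per voxel. Voxels invalid in the patient or
    model, or with control SD below ``sd_floor``, are invalid.
    """
    if patient_map.shape != model.mean_map.shape:
        raise ValueError("patient map grid does not match normative model")
    mu = model.mean_map.data
    sigma = model.sd_map.data
    with np.errstate(invalid="ignore"):
        ok = (
            patient_map.valid_mask
            & np.isfinite(mu)
            & np.isfinite(sigma)
            & (sigma >= sd_floor)
        )
    out = np.full(patient_map.shape, np.nan)
    out[ok] = (patient_map.data[ok] - mu[ok]) / sigma[ok]
    return ScalarMap(out, patient_map.voxel_size, units="z")
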