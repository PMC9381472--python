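"""Voxel-wise T2 estimation from multi-echo spin-echo series.

The signal model is a monoexponential decay S(TE) = S0 * exp(-TE / T2).
The default estimator is weighted log-linear least squares with weights
proportional to the squared signal — the usual near-ML weighting for
log-transformed data at moderate SNR — followed by one reweighting pass
using the squared *predicted* signal, which removes most of the bias
that noisy weights induce. An optional bounded nonlinear refinement is
available. Voxels with any non-positive echo signal or a non-decaying
slope are marked invalid rather than partially fit.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import curve_fit

from .types import MultiEchoVolume, ScalarMap

__all__ = [
    "fit_monoexponential",
    "fit_t2_volume",
    "apply_csf_threshold",
    "CSF_T2_THRESHOLD_MS",
    "T2_UPPER_BOUND_MS",
]

#: T2 above which a voxel is treated as CSF-contaminated and excluded.
CSF_T2_THRESHOLD_MS = 170.0

#: Clip for near-flat decays; keeps the estimator finite without
#: affecting tissue-range values.
T2_UPPER_BOUND_MS = 5000.0


def _wls_pass(w: np.ndarray, y: np.ndarray, te: np.ndarray):
    """One weighted LS pass of y = intercept + slope*te (vectorized on
    leading axes)."""
    sw = w.sum(axis=-1)
    mx = (w * te).sum(axis=-1) / sw
    my = (w * y).sum(axis=-1) / sw
    dx = te - mx[..., None]
    slope = (w * dx * (y - my[..., None])).sum(axis=-1) / (w * dx * dx).sum(axis=-1)
    return my - slope * mx, slope


def _weighted_loglinear(signals: np.ndarray, te: np.ndarray):
    """Signal-weighted log-linear fit with one prediction-reweighting
    pass; returns (s0, slope)."""
    y = np.log(signals)
    intercept, slope = _wls_pass(signals**2, y, te)
    pred = np.exp(intercept[..., None] + slope[..., None] * te)
    intercept, slope = _wls_pass(pred**2, y, te)
    return np.exp(intercept), slope


def fit_monoexponential(
    signals,
    echo_times,
    refine: bool = False,
    t2_max: float = T2_UPPER_BOUND_MS,
) -> tuple[float, float, bool]:
    """Fit S(TE) = S0 * exp(-TE/T2) to one voxel's echo series.

    Parameters
    ----------
    signals, echo_times : sequences of equal length (>= 2), TE in ms.
    refine : bool
        If True, polish the log-linear solution with bounded
        Levenberg–Marquardt minimization of the untransformed residuals.
    t2_max : float
        Upper clip for T2 (ms); near-flat decays hit this bound.

    Returns
    -------
    (s0, t2, fit_ok) — fit_ok is False when any signal is non-positive or
    the fitted decay rate is non-negative (no decay); s0/t2 are NaN then
    except that a flat positive series still reports its mean-level S0.
    """
    signals = np.asarray(signals, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    if signals.ndim != 1 or te.ndim != 1 or signals.size != te.size:
        raise ValueError("signals and echo_times must be 1-D and equal length")
    if te.size < 2:
        raise ValueError("at least two echoes are required")
    if np.any(np.diff(te) <= 0):
        raise ValueError("echo times must be strictly increasing")

    if np.any(signals <= 0) or not np.all(np.isfinite(signals)):
        return np.nan, np.nan, False

    s0_arr, slope_arr = _weighted_loglinear(signals, te)
    s0, slope = float(s0_arr), float(slope_arr)
    if slope >= 0:
        return s0, np.nan, False
    t2 = min(-1.0 / slope, t2_max)

    if refine:
        def model(t, s0_, t2_):
            return s0_ * np.exp(-t / t2_)
        try:
            popt, _ = curve_fit(
                model, te, signals, p0=(s0, t2),
                bounds=([0.0, 1e-3], [np.inf, t2_max]), maxfev=200,
            )
            s0, t2 = float(popt[0]), float(popt[1])
        except RuntimeError:
            pass  # keep the log-linear solution
    return s0, t2, True


def fit_t2_volume(
    volume: MultiEchoVolume,
    brain_mask: np.ndarray,
    t2_max: float = T2_UPPER_BOUND_MS,
    drop_first_echo: bool = False,
) -> ScalarMap:
    """Voxel-wise T2 map over a brain mask (vectorized log-linear WLS).

    Voxels outside the mask, with any non-positive echo signal, or with a
    non-decaying fit are invalid (NaN) in the output.

    ``drop_first_echo`` discards TE_1 before fitting — a common guard
    against stimulated-echo bias in the first echo of CPMG-style trains.
    """
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if brain_mask.shape != volume.spatial_shape:
        raise ValueError(
            f"mask shape {brain_mask.shape} != volume spatial shape "
            f"{volume.spatial_shape}"
        )
    data = volume.data
    te = volume.echo_times
    if drop_first_echo:
        if te.size < 3:
            raise ValueError("cannot drop the first echo of a 2-echo series")
        data = data[..., 1:]
        te = te[1:]

    out = np.full(volume.spatial_shape, np.nan)
    sig = data[brain_mask]  # (n_voxels, n_echoes)
    if sig.size == 0:
        return ScalarMap(out, volume.voxel_size, units="ms")

    ok = np.all(sig > 0, axis=1) & np.all(np.isfinite(sig), axis=1)
    s = sig[ok]
    t2 = np.full(sig.shape[0], np.nan)
    if s.shape[0]:
        _, slope = _weighted_loglinear(s, te)
        dec = slope < 0
        vals = np.full(s.shape[0], np.nan)
        vals[dec] = np.minimum(-1.0 / slope[dec], t2_max)
        t2[ok] = vals
    out[brain_mask] = t2
    return ScalarMap(out, volume.voxel_size, units="ms")


def apply_csf_threshold(
    t2_map: ScalarMap, threshold: float = CSF_T2_THRESHOLD_MS
) -> ScalarMap:
    """Invalidate voxels with T2 strictly greater than ``threshold`` ms.

    Long-T2 voxels are dominated by cerebrospinal fluid; excluding them
    keeps ROI statistics tissue-specific. A value exactly at the threshold
    is retained. Idempotent.
    """
    if threshold <= 0:
        raise ValueError("CSF threshold must be positive (ms)")
    out = t2_map.data.copy()
    with np.errstate(invalid="ignore"):
        out[out > threshold] = np.nan
    return ScalarMap(out, t2_map.voxel_size, t2_map.units)
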