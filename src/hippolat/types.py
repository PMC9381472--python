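"""Core in-memory containers for the quantitative lateralization pipeline.

Volumes live on a shared voxel grid. Invalid voxels (outside the brain,
failed fits, CSF-excluded) carry NaN in ``data``; ``valid_mask`` is always
derived from finiteness so data and mask cannot disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScalarMap",
    "MultiEchoVolume",
    "NormativeModel",
    "SubjectMeasures",
    "LateralizationResult",
]


@dataclass
class ScalarMap:
    """A 3-D voxel grid of one quantitative value (T2 in ms, SUVR, or z).

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values; NaN marks invalid voxels.
    voxel_size : 3-tuple of float
        Voxel edge lengths in mm.
    units : str
        Free-text unit label ("ms", "suvr", "z").
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    units: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"ScalarMap data must be 3-D, got {self.data.ndim}-D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three positive lengths (mm)")

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean grid of voxels that carry a usable value."""
        return np.isfinite(self.data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def copy(self) -> "ScalarMap":
        return ScalarMap(self.data.copy(), self.voxel_size, self.units)


@dataclass
class MultiEchoVolume:
    """A 4-D multi-echo spin-echo series: one 3-D image per echo time.

    ``data[x, y, z, k]`` is the signal at echo time ``echo_times[k]`` (ms).
    """

    data: np.ndarray
    echo_times: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.echo_times = np.asarray(self.echo_times, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("multi-echo data must be 4-D (x, y, z, echo)")
        if self.echo_times.ndim != 1 or self.echo_times.size < 2:
            raise ValueError("need at least two echo times")
        if self.data.shape[3] != self.echo_times.size:
            raise ValueError(
                f"{self.data.shape[3]} echo images but "
                f"{self.echo_times.size} echo times"
            )
        if np.any(np.diff(self.echo_times) <= 0) or self.echo_times[0] <= 0:
            raise ValueError("echo times must be positive and strictly increasing")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_echoes(self) -> int:
        return self.echo_times.size


@dataclass
class NormativeModel:
    """Voxel-wise control-cohort statistics used for z-scoring.

    ``mean_map`` and ``sd_map`` are computed over controls after Gaussian
    smoothing at ``smoothing_fwhm`` mm; a voxel is valid only where every
    control contributed a valid value.
    """

    mean_map: ScalarMap
    sd_map: ScalarMap
    n_controls: int
    modality: str  # "T2" or "SUVR"
    smoothing_fwhm: float

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("a normative model needs at least 2 controls")
        if self.mean_map.shape != self.sd_map.shape:
            raise ValueError("mean and SD maps must share a grid")
        with np.errstate(invalid="ignore"):
            if np.any(self.sd_map.data[self.sd_map.valid_mask] < 0):
                raise ValueError("negative SD in normative model")


@dataclass
class SubjectMeasures:
    """Per-subject hippocampal measurements and derived asymmetry indices.

    Asymmetry indices (AI) are left-minus-right hippocampal z-scores; the
    L-R deltas are raw left-minus-right values. Ipsilateral-minus-
    contralateral (I-C) deltas are populated only when laterality is known:
    for left-sided epilepsy I-C equals L-R, for right-sided it is negated.
    """

    subject_id: str
    group: str
    t2_left: float
    t2_right: float
    suvr_left: float
    suvr_right: float
    z_t2_left: float = np.nan
    z_t2_right: float = np.nan
    z_suvr_left: float = np.nan
    z_suvr_right: float = np.nan
    laterality: str = ""  # "L", "R", or "" for controls
    ai_t2: float = field(init=False)
    ai_suvr: float = field(init=False)
    delta_t2_lr: float = field(init=False)
    delta_suvr_lr: float = field(init=False)
    delta_t2_ic: float = field(init=False)
    delta_suvr_ic: float = field(init=False)

    def __post_init__(self) -> None:
        self.ai_t2 = self.z_t2_left - self.z_t2_right
        self.ai_suvr = self.z_suvr_left - self.z_suvr_right
        self.delta_t2_lr = self.t2_left - self.t2_right
        self.delta_suvr_lr = self.suvr_left - self.suvr_right
        if self.laterality == "L":
            sign = 1.0
        elif self.laterality == "R":
            sign = -1.0
        else:
            sign = np.nan
        self.delta_t2_ic = sign * self.delta_t2_lr
        self.delta_suvr_ic = sign * self.delta_suvr_lr


@dataclass
class LateralizationResult:
    """Leave-one-out lateralization output for one feature set.

    Left-sided epilepsy (LTLE) is the positive class (label 1), right-sided
    (RTLE) the negative class (label 0). ``probabilities`` are held-out
    LOOCV probabilities of the positive class; ``calls`` are hard calls at
    the 0.5 threshold ("L", "R", or "U" for an exact tie, counted wrong).
    """

    model_name: str
    labels: np.ndarray
    probabilities: np.ndarray
    calls: list[str]
    auc: float
    mse: float
    roc_points: list[tuple[float, float]]
    n_correct: int
    n_total: int
    confusion: dict[str, int]  # keys tp, fp, tn, fn

    @property
    def accuracy_percent(self) -> float:
        return round(100.0 * self.n_correct / self.n_total, 2)
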