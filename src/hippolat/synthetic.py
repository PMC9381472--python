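"""Synthetic cohorts and imaging phantoms for the lateralization pipeline.

Clinical images in this problem are not shareable, so the package ships a
generator that reproduces the statistical structure the analysis assumes:

* **Feature level** — per-group hippocampal T2 (ms) and SUVR left/right
  means and SDs, and left-minus-right z-score asymmetry indices (AI),
  taken from the published group distributions (healthy controls plus
  four patient subgroups: MR-positive/negative, left/right-sided).
* **Image level** — a desk-scale digital phantom: a brain ellipsoid with
  background tissue (T2 90 ms), two disjoint hippocampal ellipsoids
  carrying subject-specific T2 and relative uptake, and a CSF
  compartment at 2000 ms (far above the 170 ms exclusion threshold).
  Multi-echo signals follow S0*exp(-TE/T2) with additive Gaussian noise.

Everything is seeded; identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .types import MultiEchoVolume, ScalarMap

__all__ = [
    "GroupParams",
    "PhantomConfig",
    "PhantomSubject",
    "GROUP_TABLE",
    "LABEL_OUTSIDE",
    "LABEL_LEFT_HIPP",
    "LABEL_RIGHT_HIPP",
    "LABEL_CSF",
    "LABEL_BRAIN",
    "generate_cohort_features",
    "generate_phantom_subject",
    "generate_control_cohort",
    "draw_bilateral_values",
]

# Label-mask codes shared with file I/O.
LABEL_OUTSIDE = 0
LABEL_LEFT_HIPP = 1
LABEL_RIGHT_HIPP = 2
LABEL_CSF = 3
LABEL_BRAIN = 4

#: Multi-echo spin-echo TEs (ms) of the emulated T2-mapping protocol.
DEFAULT_ECHO_TIMES = (10.5, 21.0, 31.5, 42.0, 52.5, 63.0)


@dataclass(frozen=True)
class GroupParams:
    """Generative moments for one subject group.

    Raw hippocampal values are in ms (T2) and dimensionless units (SUVR);
    ``ai_*`` are the left-minus-right z-score asymmetry indices (z-units)
    the lateralization models consume.
    """

    group_label: str
    t2_left_mean: float
    t2_left_sd: float
    t2_right_mean: float
    t2_right_sd: float
    suvr_left_mean: float
    suvr_left_sd: float
    suvr_right_mean: float
    suvr_right_sd: float
    ai_t2_mean: float
    ai_t2_sd: float
    ai_suvr_mean: float
    ai_suvr_sd: float
    n_subjects: int

    def __post_init__(self) -> None:
        for name in (
            "t2_left_sd", "t2_right_sd", "suvr_left_sd", "suvr_right_sd",
            "ai_t2_sd", "ai_suvr_sd",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{self.group_label}: {name} must be > 0")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def laterality(self) -> str:
        if "LTLE" in self.group_label:
            return "L"
        if "RTLE" in self.group_label:
            return "R"
        return ""


#: Published group distributions (hippocampal means +/- SD) used as the
#: generator defaults: HC = healthy controls; MRHS/MRneg = with/without a
#: visible hippocampal-sclerosis lesion on structural MRI; L/R TLE = side
#: of the temporal-lobe epilepsy.
GROUP_TABLE: dict[str, GroupParams] = {
    "HC": GroupParams("HC", 110.40, 3.11, 109.23, 2.98,
                      0.93, 0.06, 0.91, 0.07,
                      0.0, 0.78, 0.0, 0.54, 24),
    "MRHS_LTLE": GroupParams("MRHS_LTLE", 121.81, 8.00, 111.93, 4.50,
                             0.79, 0.07, 0.95, 0.05,
                             2.45, 2.08, -2.97, 1.32, 12),
    "MRneg_LTLE": GroupParams("MRneg_LTLE", 110.86, 4.66, 108.51, 5.01,
                              0.92, 0.07, 0.94, 0.07,
                              0.38, 0.81, -0.61, 0.65, 14),
    "MRHS_RTLE": GroupParams("MRHS_RTLE", 113.89, 4.12, 117.85, 7.48,
                             0.94, 0.02, 0.81, 0.09,
                             -1.78, 2.25, 1.69, 1.45, 10),
    "MRneg_RTLE": GroupParams("MRneg_RTLE", 112.93, 4.03, 114.94, 4.96,
                              0.95, 0.04, 0.91, 0.05,
                              -1.11, 1.28, 0.34, 0.33, 10),
}


def _default_geometry(shape: tuple[int, int, int]) -> dict:
    """Ellipsoid centers/radii (voxel units) scaled to a grid shape."""
    nx, ny, nz = shape
    return {
        "brain_center": (nx / 2, ny / 2, nz / 2),
        "brain_radii": (0.45 * nx, 0.45 * ny, 0.45 * nz),
        "left_center": (0.30 * nx, 0.50 * ny, 0.50 * nz),
        "left_radii": (max(2.0, 0.07 * nx), max(2.0, 0.10 * ny), max(2.0, 0.11 * nz)),
        "right_center": (0.70 * nx, 0.50 * ny, 0.50 * nz),
        "right_radii": (max(2.0, 0.07 * nx), max(2.0, 0.10 * ny), max(2.0, 0.11 * nz)),
        "csf_center": (0.50 * nx, 0.28 * ny, 0.50 * nz),
        "csf_radii": (max(2.0, 0.08 * nx), max(2.0, 0.08 * ny), max(2.0, 0.10 * nz)),
    }


@dataclass
class PhantomConfig:
    """Geometry and acquisition settings of the digital phantom.

    The grid defaults to 64x64x32 voxels at 2 mm isotropic — small enough
    to simulate and fit a subject in well under a second. S0 is 1000
    everywhere inside the brain; per-echo noise is additive Gaussian with
    SD ``noise_sd_relative * S0``.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_size: tuple[float, float, float] = (2.0, 2.0, 2.0)
    echo_times: tuple[float, ...] = DEFAULT_ECHO_TIMES
    csf_t2: float = 2000.0
    background_t2: float = 90.0
    background_suvr: float = 1.0
    csf_suvr: float = 0.3
    s0: float = 1000.0
    noise_sd_relative: float = 0.02
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        te = np.asarray(self.echo_times, dtype=float)
        if te.size < 2 or te[0] <= 0 or np.any(np.diff(te) <= 0):
            raise ValueError("echo_times must be positive, strictly increasing")
        if self.csf_t2 <= 170.0:
            raise ValueError("csf_t2 must exceed the 170 ms exclusion threshold")
        if self.background_t2 <= 0 or self.s0 <= 0:
            raise ValueError("background_t2 and s0 must be positive")
        if self.noise_sd_relative < 0:
            raise ValueError("noise_sd_relative must be >= 0")
        geo = _default_geometry(tuple(self.grid_shape))
        geo.update(self.geometry)
        self.geometry = geo
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        shape = tuple(self.grid_shape)
        rois = {
            name: self._ellipsoid(self.geometry[f"{name}_center"],
                                  self.geometry[f"{name}_radii"])
            for name in ("left", "right", "csf")
        }
        for name, m in rois.items():
            if not m.any():
                raise ValueError(f"{name} ellipsoid contains no voxels")
        if (rois["left"] & rois["right"]).any() or \
           (rois["left"] & rois["csf"]).any() or \
           (rois["right"] & rois["csf"]).any():
            raise ValueError("phantom ROIs overlap")
        brain = self._ellipsoid(self.geometry["brain_center"],
                                self.geometry["brain_radii"])
        for name, m in rois.items():
            if (m & ~brain).any():
                raise ValueError(f"{name} ellipsoid extends outside the brain")

    def _ellipsoid(self, center, radii) -> np.ndarray:
        idx = np.indices(tuple(self.grid_shape), dtype=float)
        r2 = sum(((idx[a] - center[a]) / radii[a]) ** 2 for a in range(3))
        return r2 <= 1.0

    def label_volume(self) -> np.ndarray:
        """Integer label mask: 0 outside, 1 left hipp, 2 right hipp, 3 CSF,
        4 remaining brain tissue."""
        labels = np.full(tuple(self.grid_shape), LABEL_OUTSIDE, dtype=np.int16)
        brain = self._ellipsoid(self.geometry["brain_center"],
                                self.geometry["brain_radii"])
        labels[brain] = LABEL_BRAIN
        labels[self._ellipsoid(self.geometry["csf_center"],
                               self.geometry["csf_radii"])] = LABEL_CSF
        labels[self._ellipsoid(self.geometry["left_center"],
                               self.geometry["left_radii"])] = LABEL_LEFT_HIPP
        labels[self._ellipsoid(self.geometry["right_center"],
                               self.geometry["right_radii"])] = LABEL_RIGHT_HIPP
        return labels

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["voxel_size"] = list(self.voxel_size)
        d["echo_times"] = list(self.echo_times)
        d["geometry"] = {k: list(v) for k, v in self.geometry.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        d = dict(d)
        for key in ("grid_shape", "voxel_size", "echo_times"):
            if key in d:
                d[key] = tuple(d[key])
        if "geometry" in d:
            d["geometry"] = {k: tuple(v) for k, v in d["geometry"].items()}
        return cls(**d)


@dataclass
class PhantomSubject:
    """One rendered phantom subject with its generating ground truth."""

    subject_id: str
    group: str
    laterality: str
    t2_left: float
    t2_right: float
    suvr_left: float
    suvr_right: float
    multi_echo: MultiEchoVolume | None = None
    pet: ScalarMap | None = None
    labels: np.ndarray | None = None
    truth_t2: ScalarMap | None = None


def generate_cohort_features(
    params_per_group: Sequence[GroupParams],
    seed: int,
    ai_correlation: float = 0.0,
) -> pd.DataFrame:
    """Draw per-subject AI features for each group.

    AI_T2 and AI_SUVR are Normal with the group's (mean, SD); by default
    they are drawn independently (``ai_correlation`` exposes the
    unreported cross-modality correlation). Returns one row per subject
    with columns subject_id, group, ai_t2, ai_suvr, laterality.
    """
    if not -1.0 < ai_correlation < 1.0:
        raise ValueError("ai_correlation must be in (-1, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for params in params_per_group:
        n = params.n_subjects
        cov = np.array([
            [params.ai_t2_sd**2,
             ai_correlation * params.ai_t2_sd * params.ai_suvr_sd],
            [ai_correlation * params.ai_t2_sd * params.ai_suvr_sd,
             params.ai_suvr_sd**2],
        ])
        draws = rng.multivariate_normal(
            [params.ai_t2_mean, params.ai_suvr_mean], cov, size=n,
            method="cholesky",
        )
        for j in range(n):
            rows.append({
                "subject_id": f"{params.group_label}_{j:05d}",
                "group": params.group_label,
                "ai_t2": draws[j, 0],
                "ai_suvr": draws[j, 1],
                "laterality": params.laterality,
            })
    return pd.DataFrame(rows)


def draw_bilateral_values(
    params: GroupParams,
    n: int,
    rng: np.random.Generator,
    lr_correlation: float = 0.5,
) -> pd.DataFrame:
    """Draw per-subject left/right hippocampal T2 and SUVR values.

    Left and right are bivariate normal with the group's marginal moments
    and within-subject correlation ``lr_correlation`` (0.5 by default —
    the within-subject dependence is not reported, and 0.5 keeps
    left-minus-right spreads in a physiologic range; raise it toward
    ~0.7-0.9 to match the narrower published difference SDs).
    """
    if not -1.0 < lr_correlation < 1.0:
        raise ValueError("lr_correlation must be in (-1, 1)")

    def bivariate(ml, sl, mr, sr):
        cov = np.array([
            [sl**2, lr_correlation * sl * sr],
            [lr_correlation * sl * sr, sr**2],
        ])
        return rng.multivariate_normal([ml, mr], cov, size=n, method="cholesky")

    t2 = bivariate(params.t2_left_mean, params.t2_left_sd,
                   params.t2_right_mean, params.t2_right_sd)
    suvr = bivariate(params.suvr_left_mean, params.suvr_left_sd,
                     params.suvr_right_mean, params.suvr_right_sd)
    return pd.DataFrame({
        "t2_left": t2[:, 0], "t2_right": t2[:, 1],
        "suvr_left": np.clip(suvr[:, 0], 1e-3, None),
        "suvr_right": np.clip(suvr[:, 1], 1e-3, None),
    })


def generate_phantom_subject(
    config: PhantomConfig,
    left_t2: float,
    right_t2: float,
    left_suvr: float,
    right_suvr: float,
    seed: int,
    dose_scale: float = 1.0,
) -> tuple[MultiEchoVolume, ScalarMap, np.ndarray, ScalarMap]:
    """Render one subject: multi-echo series, PET volume, labels, true T2.

    Voxel signal at echo k is S0*exp(-TE_k/T2(voxel)) plus Gaussian noise
    of SD ``noise_sd_relative*S0``. PET uptake is the relative tissue
    uptake times ``dose_scale`` (an arbitrary global intensity the SUVR
    normalization must cancel) plus matched relative noise.
    """
    if left_t2 <= 0 or right_t2 <= 0:
        raise ValueError("hippocampal T2 values must be positive")
    if left_suvr <= 0 or right_suvr <= 0:
        raise ValueError("hippocampal uptake values must be positive")
    rng = np.random.default_rng(seed)
    labels = config.label_volume()
    brain = labels != LABEL_OUTSIDE

    t2 = np.full(labels.shape, np.nan)
    t2[labels == LABEL_BRAIN] = config.background_t2
    t2[labels == LABEL_CSF] = config.csf_t2
    t2[labels == LABEL_LEFT_HIPP] = left_t2
    t2[labels == LABEL_RIGHT_HIPP] = right_t2

    te = np.asarray(config.echo_times, dtype=float)
    decay = np.exp(
        -te[None, None, None, :] / np.where(brain, t2, np.inf)[..., None]
    )
    echoes = np.where(brain[..., None], config.s0 * decay, 0.0)
    if config.noise_sd_relative > 0:
        echoes = echoes + rng.normal(
            0.0, config.noise_sd_relative * config.s0, size=echoes.shape
        ) * brain[..., None]
    multi_echo = MultiEchoVolume(echoes, te, config.voxel_size)

    # Requested hippocampal/CSF values are ratios to the global brain
    # mean; the background tissue level is solved so that the brain-mean
    # uptake is exactly 1, making SUVR recover the requested ratios.
    uptake = np.full(labels.shape, np.nan)
    uptake[labels == LABEL_CSF] = config.csf_suvr
    uptake[labels == LABEL_LEFT_HIPP] = left_suvr
    uptake[labels == LABEL_RIGHT_HIPP] = right_suvr
    n_brain = int(brain.sum())
    n_bg = int((labels == LABEL_BRAIN).sum())
    fixed_sum = np.nansum(uptake[brain])
    bg_level = (n_brain - fixed_sum) / n_bg
    if bg_level <= 0:
        raise ValueError("ROI uptake too high for a positive background level")
    uptake[labels == LABEL_BRAIN] = bg_level
    pet = np.where(brain, uptake * dose_scale, np.nan)
    if config.noise_sd_relative > 0:
        pet = pet + rng.normal(
            0.0,
            config.noise_sd_relative * config.background_suvr * dose_scale,
            size=pet.shape,
        ) * brain
        pet = np.where(brain, np.clip(pet, 0.0, None), np.nan)
    pet_map = ScalarMap(pet, config.voxel_size, units="uptake")

    truth = ScalarMap(np.where(brain, t2, np.nan), config.voxel_size, "ms")
    return multi_echo, pet_map, labels, truth


def generate_control_cohort(
    config: PhantomConfig,
    hc_params: GroupParams,
    n: int,
    seed: int,
    render: bool = True,
    lr_correlation: float = 0.5,
) -> list[PhantomSubject]:
    """Simulate ``n`` healthy-control subjects.

    Per-subject left/right hippocampal T2 and SUVR are drawn from the
    control group distribution, then (optionally) rendered as image
    phantoms. n must be at least 2 — a single control gives no normative
    SD.
    """
    if n < 2:
        raise ValueError("need n >= 2 controls (normative SD undefined)")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    values = draw_bilateral_values(hc_params, n, rng, lr_correlation)
    render_seeds = ss.spawn(n)
    subjects = []
    for i in range(n):
        row = values.iloc[i]
        subj = PhantomSubject(
            subject_id=f"{hc_params.group_label}_{i:05d}",
            group=hc_params.group_label,
            laterality=hc_params.laterality,
            t2_left=float(row.t2_left), t2_right=float(row.t2_right),
            suvr_left=float(row.suvr_left), suvr_right=float(row.suvr_right),
        )
        if render:
            me, pet, labels, truth = generate_phantom_subject(
                config, subj.t2_left, subj.t2_right,
                subj.suvr_left, subj.suvr_right,
                seed=int(render_seeds[i].generate_state(1)[0] % (2**31)),
            )
            subj.multi_echo, subj.pet = me, pet
            subj.labels, subj.truth_t2 = labels, truth
        subjects.append(subj)
    return subjects
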