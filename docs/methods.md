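# Methods

## T2 relaxometry

Each voxel's multi-echo spin-echo series is modeled as a monoexponential
decay S(TE) = S0 · exp(−TE/T2) over six echo times (10.5–63.0 ms in
10.5 ms steps by default). The estimator is weighted least squares in the
log domain — ln S regressed on TE — with weights proportional to the
squared signal, which is the near-maximum-likelihood weighting for
log-transformed data at moderate SNR. A second pass re-weights by the
squared *predicted* signal: using the noisy signal itself as a weight
correlates weight and residual and inflates T2 by ~0.7 ms at 2% noise;
one prediction-based reweighting (standard IRLS practice) cuts that to
~0.4 ms and is a no-op on noiseless data. A bounded Levenberg–Marquardt
refinement of the untransformed residuals is available (`refine=True`)
but changes noiseless results by < 0.1 ms.

Failure handling is conservative: a voxel with any non-positive echo
signal, or a non-decaying fitted slope, is invalid rather than partially
fit. Fitted T2 is clipped at 5000 ms so near-flat decays stay finite.
All six echoes are used by default; `drop_first_echo=True` discards TE₁,
a common guard against stimulated-echo bias in the first echo.

Intrinsic precision at the simulated SNR: the Cramér–Rao bound for
(S0, T2) at S0 = 1000, noise SD 20, these six TEs gives SD(T2) ≈ 7.7 ms
per voxel. Per-voxel error is therefore judged against that bound
(median absolute error ≈ 5.2 ms for an efficient estimator), while
accuracy claims are made at the ROI-average level, where a ~400-voxel
hippocampal ROI brings the standard error below 0.4 ms.

**CSF exclusion.** Voxels with T2 strictly above 170 ms are invalidated
before any ROI statistic: CSF T2 is an order of magnitude above tissue,
and partial-volume CSF otherwise inflates hippocampal means. The rule is
strict-greater (a voxel at exactly 170 ms is kept) and idempotent.

## PET SUVR

SUVR is uptake divided by the mean uptake over the whole-brain mask.
Injected dose and body weight cancel in the ratio, so they are not
modeled. The reference region is the whole brain (exposed as the mask
argument) rather than gray matter only — the simplest reading, and on
the synthetic phantoms the distinction does not exist. The output's
in-mask mean is exactly 1, and the map is invariant to any positive
rescaling of the input.

## Normative z-score maps

Controls and patients are smoothed with an isotropic Gaussian specified
by FWHM (SD = FWHM/(2√(2 ln 2))), 4 mm for T2 and 8 mm for SUVR by
default, converted to voxel units per axis. Smoothing is mask-normalized
(smooth(data·m)/smooth(m)): invalid voxels contribute nothing and stay
invalid, so CSF-excluded voxels neither leak values into neighbours nor
resurrect themselves. Smoothing always precedes z-scoring, for controls
and patients alike.

The normative model is the per-voxel sample mean and SD (n−1) over ≥ 2
smoothed controls; a voxel is valid only where every control is valid.
z = (x − μ_HC)/σ_HC; voxels with σ_HC < 1e−6 (modality units) are marked
invalid rather than producing enormous z from degenerate control
variance. Spatial normalization to a template is replaced by the shared
synthetic grid, so the map-back-to-native step of a clinical workflow is
a no-op here.

## ROI measures and asymmetry

Hippocampal label masks are eroded with a 6-connected 3-D cross (one
iteration by default) to trim the partial-volume shell; if erosion would
empty a tiny mask the un-eroded mask is used and a warning is logged.
The hippocampal value of a map is the arithmetic mean over valid eroded
ROI voxels (invalid voxels simply drop out). The per-subject z value of
a hippocampus is the mean of voxel-wise z within the eroded ROI (not the
z of the ROI mean — both readings are defensible; the voxel-mean reading
matches atlas-based extraction of z maps and is the default).

Asymmetry measures: AI = z_left − z_right per modality;
Δ_L−R = left − right on the raw scale; Δ_I−C = Δ_L−R for left-sided and
−Δ_L−R for right-sided patients. Subgroup Δ_L−R means are pooled into an
I−C mean by sign-flipping right-sided subgroups and weighting by n. The
"normal range" of an AI is the central 95% empirical percentile interval
of the control AIs (normal-theory μ ± 1.96σ is available as an option).

## Lateralization

Left-sided epilepsy is the positive class. The classifier is logistic
regression with an intercept and an L2 (ridge) penalty at C = 1: at
n = 24 with nearly separable asymmetry features, unpenalized maximum
likelihood diverges; ridge at the conventional default keeps the fit
proper while barely shrinking well-determined coefficients. An
unpenalized option (`penalty=None`) exists. Features are not
standardized before fitting — the AIs are already z-derived.

LOOCV refits the model n times and pools the n held-out probabilities
into one ROC; AUC is computed by the rank-sum (Mann–Whitney) formula
with ties counted one half, MSE is the mean squared difference between
label and probability, and hard calls threshold at 0.5 (an exact 0.5 is
"undetermined" and counted incorrect).

**Pooled-LOOCV pessimism.** Pooling held-out probabilities across folds
mixes scores from n slightly different models; leaving out a positive
subject lowers the training prevalence and intercept, so that subject is
scored by a slightly pessimistic model. At n = 24 this depresses the
expected pooled AUC by roughly 0.05 relative to the analytic
separability of the generating distributions (for the univariate T2
asymmetry moments used here, Φ(d′) ≈ 0.84 analytically vs ≈ 0.78 pooled
LOOCV on average). Single real cohorts evaluated this way scatter around
that mean with SD ≈ 0.09, so an individual cohort can easily print a
higher value than the replicate average. This is a property of the
evaluation protocol, not a defect of the fit, and is kept as-is because
pooled LOOCV is the protocol being emulated.

## Group statistics

Left-vs-right comparisons use the Wilcoxon signed-rank test (zero
differences dropped, the classical convention; Pratt's method available)
and between-group comparisons use the Mann–Whitney U test. Both report
two-sided p values: the exact null for n ≤ 12 (all 2ⁿ sign assignments /
all group assignments), the normal approximation with continuity and tie
corrections above that. α = 0.05 with no multiple-testing correction, by
convention of the emulated analysis. The identity U/(n_a·n_b) = AUC of
group membership against value links the two modules and is tested.

## Synthetic data

**Feature level.** Each group (healthy controls; MR-positive/negative ×
left/right-sided patients) is parameterized by hippocampal left/right T2
and SUVR means ± SDs and by AI means ± SDs taken from the published
group table; these defaults define the simulated study conditions
(cohort sizes 24/15 controls, 12/14/10/10 patients). AI_T2 and AI_SUVR
are drawn independently by default — their cross-modality correlation is
unreported — with the correlation exposed as a parameter. Raw left and
right values are drawn bivariate-normal with within-subject correlation
0.5 (also unreported; 0.5 keeps difference spreads physiologic, and
matching the reported difference SDs exactly would need ρ ≈ 0.7–0.9 —
the parameter is exposed for that purpose).

**Image level.** A 64×64×32 grid at 2 mm isotropic holds a brain
ellipsoid (tissue T2 90 ms, S0 = 1000), two disjoint hippocampal
ellipsoids carrying the subject's T2 and relative uptake, and a CSF
compartment at 2000 ms — values chosen to straddle the 170 ms rule.
Echo signals follow the forward model with additive Gaussian noise of SD
= 2% of S0 per echo. PET renders relative uptake (hippocampi at their
target SUVR, CSF at 0.3) with the background level solved so the brain
mean is exactly 1 before an arbitrary dose scale; SUVR normalization
must cancel that scale. Geometry scales proportionally with the grid, so
tests run the identical pipeline on smaller grids.

**What the phantom does not emulate** — and what passing tests therefore
do not show about clinical data: Rician noise (Gaussian is adequate at
SNR ≥ 20 but wrong near the noise floor), multi-exponential tissue
decay, stimulated echoes and TR effects, partial-volume mixing at tissue
interfaces, motion, registration error, segmentation error, and PET
attenuation-correction artifacts. Absolute T2 values in the literature
vary with acquisition protocol; the pipeline's comparisons are all
control-referenced, which is precisely why the z-score design matters.

## Problem sizes

The replicate lateralization study uses 200 cohorts of 24 subjects
(seconds per 100 replicates on one core). Image-level integration tests
run the full 85-subject cohort on a 32×32×16 grid (~15 s) and
single-subject checks on the default 64×64×32 grid (~0.15 s per subject
for rendering plus fitting). These sizes give standard errors comfortably
inside every tolerance asserted.
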