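# Methods

This note documents the models, the numerical choices, and what the
synthetic phantoms do and do not establish.

## Preprocessing

**Reference selection and the outlier rule.** The motion-correction
reference is the timepoint with the fewest outlier voxels. A sample is an
outlier when its deviation from a robust linear trend exceeds κ(n)·MAD,
with κ(n) = Φ⁻¹(1 − 0.001/n)·√(π/2): a two-sided Gaussian tail of 0.001/n
converted from standard deviations to MAD units. For 50–500 timepoints κ is
≈5.5. The trend is a least-absolute-deviations straight line fit by IRLS
(the quoted rule only fixes the ≈5.5 outcome; the LAD trend makes the rule
insensitive to the spikes it is hunting). Ties go to the earliest index.

**Slice timing** resamples each slice's series to the start of its TR by
Fourier phase shift (exact for band-limited signals; the Nyquist bin is
kept real). The target (start of TR) and the interpolation method are
package choices; the per-slice offsets must be supplied.

**Rigid registration** (motion correction, and intensity-based EPI→T1w
alignment) minimizes voxelwise squared error (motion) or maximizes
normalized mutual information over a 32×32 joint histogram (IBR) with
derivative-free Powell search. Two numerical details matter:

* rotations are rescaled by a 50-mm lever arm so a unit optimizer step
  displaces the head surface comparably for rotations and translations;
* the search is two-stage — a capture stage on 1-voxel-Gaussian-smoothed
  images with trilinear interpolation, then refinement on the original
  images with a cubic-spline interpolant (the moving image is
  spline-prefiltered once per volume). Hitting the iteration cap with an
  improved cost is treated as convergence; the identity fallback fires only
  when the optimizer returns a non-finite or non-improving result.

On smooth 24×24×12 phantoms this recovers injected motion of up to
5 mm / 3° to better than 0.3 mm / 0.3° (tested). IBR is multi-started at
±5 mm along each axis to escape histogram-induced local optima.

**Single-shot interpolation.** Motion and anatomical alignment transforms
are composed per timepoint and applied in one resampling pass with a
5-lobe Hann-windowed sinc kernel (weights normalized to unit sum so
constants are exact). Trilinear interpolation is used only inside
optimization loops. Composing a +2 mm and −2 mm shift through one resample
reproduces the input to machine precision, strictly better than two
sequential resamples (tested).

**Coordinate-based alignment (CBR)** trusts the scanner affines: the
functional data are resampled onto the T1w grid, previously resampled to a
2- or 3-mm isotropic axis-aligned RAS grid covering its field of view.
Boundary-based registration is out of scope; CBR is the default, IBR the
estimated alternative.

**Despiking.** A robust trend (LAD fit by 30 fixed IRLS iterations to a
quartic Legendre basis plus max(3, n/30) Fourier harmonic pairs) defines
residuals; σ is MAD/0.6745. Residuals beyond c₁ = 2.5σ are compressed to
c₁ + (c₂−c₁)·tanh((s−c₁)/(c₂−c₁)) with c₂ = 4, so no output sample sits
more than 4σ off the trend and sub-threshold samples pass through
bit-identically. Two guards: the IRLS iteration count is fixed so batched
and per-series calls agree, and a series whose σ is below 10⁻⁴ of its range
is treated as spike-free (such residuals are fit error, not physiology).
The constants c₁, c₂ and the basis are package choices.

**Nuisance removal and band-pass are one orthogonal projection.** Legendre
drift columns (default order 2), the nuisance regressors (six motion
parameters, mean WM and CSF signals from 99.9%-thresholded, one-voxel
6-connected-eroded, lesion-excluded masks; optional global signal from the
30% whole-brain mask), and cosine/sine pairs for every DFT bin outside the
pass band (default 0.01–0.08 Hz) are assembled into one basis and removed
in a single projection. This makes the operation idempotent and prevents
the regression from reintroducing filtered frequencies. Rank-deficient
bases collapse via SVD with a warning. Exact-bin sinusoids in the pass band
are fully retained; off-bin signal leaks slightly into neighbouring bins
(≥95% retention at 0.05 Hz on a 180×2 s run, ≤1% at 0.2 Hz; tested).

**Mask pipeline order** is fixed: threshold → erode → lesion-exclude →
nearest-neighbour resample to the functional grid. Eroding before
resampling keeps the partial-volume guard at anatomical resolution; lesion
exclusion after erosion means a lesion voxel always wins. "Eroded by one
voxel along each of the three axes" is implemented as one pass with the
6-connected cross element.

**Segmentation** is an intensity-only 3-class Gaussian mixture (EM, means
initialized evenly over the 1–99 percentile range so class proportions
cannot collapse two components into one mode; classes ordered CSF < GM < WM
by mean for T1w contrast). It stands in for a full registration+bias-field
unified segmentation, which is out of scope; externally computed
probability maps are accepted anywhere a `TissueProbMaps` is.

## GLM engine

The canonical HRF is the standard double-gamma (peak 6 s, undershoot 16 s,
unit dispersions, 6:1 ratio), normalized to unit peak. The RRF is the
two-gamma-term respiration response formula with its published constants;
it is not renormalized, so r(3 s) ≈ 0.869. Designs are built on a 0.1-s
grid, convolved, and sampled at k·TR; nuisance columns are demeaned and
degenerate (zero-variation) columns dropped with a warning — motion tables
from motion-free data would otherwise make the design singular.

ARMA(1,1) GLS: per voxel, (a, b) is selected on the grid
[−0.8, 0.8] step 0.05 by maximizing −½[(n−p)·log RSS(a,b) +
log det XᵀwXw] in the whitened model; the causal whitening filter
(1 − aL)/(1 + bL) has unit leading coefficient, so the covariance
log-determinant vanishes from the criterion. One addition is needed for
identifiability: ARMA(1,1) is exactly white noise along the entire a = −b
ridge, where the likelihood is flat and finite-sample noise would select
arbitrary extremes. A weak Gaussian prior (sd 0.5, i.e. a penalty of
2(a² + b²)) resolves the ridge toward (0, 0) without influencing genuinely
correlated voxels, whose likelihood gain grows with n. On 2000 white-noise
voxels at n = 200 this yields median |a|, |b| = 0.05 and a two-sided
empirical type-I error of 0.053 at nominal 0.05; under AR(1) noise the
whitened t statistics are much closer to unit variance than OLS (tested).

Display thresholding is one-sided on signed t (activation convention);
two-sided p-values are available via `t_to_p`.

## Resting-state analysis

ReHo uses the 27-voxel neighbourhood by default (7 and 19 available), with
average ranks for ties and edge voxels using their in-mask neighbours (m
varies per voxel). Seed spheres include voxels whose centers lie within the
radius (deterministic, brute-force checkable); radius 0 means the nearest
voxel. Correlations are clipped to |r| ≤ 1 − 10⁻⁷ before atanh so z maps
stay finite. The FC map is computed on smoothed data by default (ReHo
always on unsmoothed); global-signal regression is off by default. The
nuisance-free seed GLM satisfies t = r√(df/(1−r²)) voxelwise (tested),
so the two routes are interchangeable for display.

## CVR and NVU

The delay sweep defaults to −10…15 s in 1-s steps (26 GLM fits; the step is
a package choice, the range follows the breath-hold practice the package
targets). Sweep fits use OLS — the max-t selection compares fits of the
same data against shifted regressors, where per-voxel prewhitening would
add cost without changing the argmax materially; `noise_model="arma11"` is
available. Ties in t resolve toward the smallest |delay| (parsimony toward
zero lag). Delays visited in ascending |d| with strict improvement
implement this without a second pass.

NVU labeling is deliberately mechanical: inside a user ROI, code 3 = both
task-t and CVR max-t above their thresholds, 1 = fMRI only, 2 = CVR only,
0 = neither; the codes tile the ROI exactly. Voxels of code 0 inside a
user-designated expected-function region are reported as NVU-potential.
Thresholds and ROI are user decisions, not inferences.

## DICOM interfaces

Import groups Part-10 files (DICM magic at offset 128) by
SeriesInstanceUID; folder names come from one of three patterns
(description / id_description / id_description_number) with unsafe
characters replaced by underscores. Slices are ordered along the
row×column normal; geometry is converted LPS→RAS and the volume is
canonicalized to the closest-to-RAS+ axis order, so a round trip through
the writer reproduces data and affine exactly.

Export writes one gray-scale fused series (12-bit MONOCHROME2, overlay
burned in at the display maximum — the format navigation systems import;
multiple underlays interleave within the one series) and exactly three
8-bit RGB color series, one per orthogonal plane. Patient/study identity
fields are copied from the user-selected template header
(PatientID/Name/BirthDate/Sex, StudyInstanceUID/ID/Date/Time,
AccessionNumber, ReferringPhysician, StudyDescription — the exact list is a
package decision); series UIDs and SOP UIDs are newly generated and series
numbers start at base 1000 (+ plane index) to avoid collisions with
acquired series. Modality stays "MR"; the SOP class is Secondary Capture.
No networking, compressed transfer syntaxes, or GSPS/SEG objects.

## Synthetic phantoms

The anatomy is three concentric ellipsoids (CSF shell, GM ribbon, WM core)
with T1w-like means 30/80/120 and σ = 5 noise, on a 32×32×16 grid of 3-mm
voxels by default. BOLD noise is AR(1) (coefficient 0.3) with sd 1% of the
1000-unit baseline, plus random linear+quadratic drift (1% peak) and
optional sparse 8σ spikes; task and CVR responses are 2% signal changes
(typical BOLD block effect sizes); resting networks share a 0.01–0.08 Hz
band-limited signal carrying 50% of the in-network variance. Protocol
fixtures reproduce the clinical acquisition arithmetic: 130/120-volume task
runs at TR 2 s, 180-volume rest runs, and a 70-volume breath-hold run at
TR 3 s over the 210-s paradigm (30 s rest + 3 × (15 s hold + 45 s rest)).

What the phantoms do *not* emulate: EPI distortion, physiological
(cardiac/respiratory) noise structure, spatially varying coil sensitivity,
partial-volume mixtures, or realistic anatomy. Passing tests therefore
demonstrate algorithmic correctness and calibration under the stated noise
model — not clinical performance.

Pipeline-level tests run the full workflows on a reduced 20×20×10 grid of
4-mm voxels; statistical calibration tests use 2000 voxels at n = 200, and
the multi-seed connectivity check uses 20 independent sessions. These
problem sizes are the package's test conditions; all generators are
deterministic under their seed.

## Known limitations

* CBR trusts scanner affines; if the headers are wrong, so is the
  alignment. IBR is the in-package fallback; BBR is not implemented.
* The ARMA grid (step 0.05) bounds the whitening resolution; extreme
  autocorrelation (|a| > 0.8) is clamped to the grid edge.
* The mixture segmenter assumes three separable intensity modes
  (brain-extracted or phantom input); bias fields defeat it — supply
  external probability maps in that case.
* Band-pass retention is exact only for on-bin frequencies; runs much
  shorter than 1/f_low leak.
* Exported color series are Secondary Capture objects; PACS viewers that
  insist on true MR IODs for measurements may treat them as screenshots.
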