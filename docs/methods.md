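# Methods

`qmripipe` implements a complete multiparametric quantitative MRI (qMRI)
workflow — T1, T2, T2\* and proton-density (PD) mapping with B1/B0/receive
corrections, synthetic-anatomy-based segmentation, tissue-compartment
statistics and voxel-wise permutation inference — validated end to end on a
digital brain phantom with known ground truth.  This note documents the
models, the defaults and why they were chosen, the numerical choices, and
what the synthetic validation does and does not establish.

## The digital phantom

The phantom is a parametric concentric-shell brain on a 3D grid (default
64³ voxels at 2 mm isotropic): an outer CSF envelope, a cortical
gray-matter ribbon at least three voxels thick, a white-matter interior
containing two bilateral deep-gray-matter blobs and two small CSF
ventricles.  Each tissue class carries constant ground-truth parameters;
the default table assigns cortex, WM and deep GM the patient-group
compartment means of the clinical study this pipeline emulates (cortex
T1/T2/PD = 1556.79 ms / 80.97 ms / 80.74 p.u.; WM = 894.07 / 62.15 /
66.24; deep GM = 1249.95 / 58.6 / 75.79), so that every recovery test
targets a reported value.  T2\* (WM 45 ms, cortex 40 ms, deep GM 35 ms,
CSF 200 ms) and the CSF entries (T1 4000 ms, T2 500 ms, PD ≡ 100 p.u.)
are generic 3 T values.  PD is expressed in percent units with free water
(CSF) ≡ 100.

Instrumental fields are smooth random second-order polynomials: B1 within
±20 % of nominal, B0 within ±60 Hz, receive profile within ±30 %.  The B0
bound keeps the phase difference of the B0 protocol inside (−π, π), so no
phase unwrapping is ever needed — by construction, not by algorithm.

**Cohorts.**  A cohort draws per-subject tissue means around the class
means with configurable between-subject SDs (defaults: the reported
patient-group compartment SDs, e.g. cortical T2 2.82 ms, WM T1 57.08 ms),
optionally shifts group A by an additive per-tissue effect, and attaches a
demographics table (age ≈ 33 ± 14 y, 44 % female, seizure and medication
counts) matched to the study's baseline table.  The default cohort is 27
vs 27 subjects.  The reported SDs are group-level SDs; their use as pure
between-subject SDs is a modeling choice, since the within/between variance
decomposition of the original data is not reported.

## Forward simulation

All five acquisitions are simulated voxel-wise from their steady-state
signal equations; there is no k-space, readout-train or parallel-imaging
simulation, because the fitting chain consumes magnitude images only.

- **Multi-echo fast spin echo** (TE = 13/67/93/106 ms, TR = 10 s, two
  repeats): S(TE) = rx·PD·exp(−TE/T2).  An optional stimulated-echo mode
  multiplies each echo by a factor computed from an extended-phase-graph
  (EPG) evaluation of the CPMG train at refocusing angle 160°·B1 and echo
  spacing 13.3 ms, sampled at the echo nearest each effective TE.  The
  mode is off by default, so the baseline signal is exactly exponential.
- **Variable flip angle (VFA) spoiled GE** (α = 4°/24°, TR = 16.4 ms,
  TE = 6.7 ms): ideal-spoiling SPGR equation with effective angle B1·α.
  Insufficient-spoiling corrections exist in the literature but their
  coefficients are protocol-specific; the hook is an identity no-op.
- **B1 pair**: reference GE and magnetization-prepared GE with
  I_prep = I_ref·cos(B1·β₀), β₀ = 45°; simulated at a 2× coarser grid
  (emulating the 4 mm calibration scan) by block averaging.
- **B0 pair** (TE = 4.89/7.35 ms): magnitude from a generic
  saturation-weighted GE model plus phase φᵢ = 2π·Δf·TEᵢ (+ constant
  receiver offset, default 0).  The T1 weighting of these magnitude images
  is not specified by the emulated protocol; a standard SPGR saturation
  factor is used — it cancels in the phase difference.
- **Dual-echo GE** (TE = 4.3/11 ms): SPGR weighting times exp(−TE/T2\*),
  used solely for the T2\* compensation of the VFA data.

**Noise** is Rician: independent Gaussian perturbations of SD σ on the two
quadrature channels before the magnitude operation (background voxels are
therefore Rayleigh-distributed); phase images receive the consistent
complex-noise phase.  SNR is defined as mean WM signal of the first volume
divided by σ, per acquisition.

## The fitting chain

1. **Repeat averaging** — arithmetic mean of volumes with identical TE.
2. **T2** — per voxel, nonlinear least squares of A·exp(−TE/T2) over the
   four echoes (Gauss–Newton with damped steps), initialized at the
   log-linear solution; two echoes reduce to the exact two-point formula.
   Voxels below the noise floor (first-echo signal < 3σ̂) are masked;
   after repeat averaging ≈ 4 % of pure-noise background voxels still pass
   3σ̂ — harmless, as downstream masks are anatomical.  When the
   stimulated-echo mode is on, the fit inverts the simulator's EPG factor
   (using a first uncorrected pass for the T2 it needs).
3. **B1** — arccos(I_prep/I_ref)/β₀, ratios clipped to [−1, 1] and
   counted; the low-resolution map is upsampled trilinearly (nearest-valid
   fill outside the head first).  Upsampling is exact only to
   interpolation error: on a 2× coarse grid the reconstructed B1 deviates
   by ≲ 10⁻³ (median) from the smooth truth, which propagates to ≈ 10⁻²
   worst-case voxel-wise T1 error while compartment means stay within
   0.05 %.
4. **B0** — wrap(φ₂−φ₁)/(2π·ΔTE), wrapped to (−π, π]; voxels near the
   wrap boundary are counted.  B0 is carried along and exposed to the T1
   step as a correction hook, identity by default (no published
   off-resonance correction formula is reproduced here).
5. **T2\*** — two-point (TE₂−TE₁)/ln(S₁/S₂); non-physical voxels
   (S₂ ≥ S₁) are masked.
6. **T1 (VFA)** — the two points (Iᵢ/tan αᵢ′, Iᵢ/sin αᵢ′) with
   αᵢ′ = B1·αᵢ define a line of slope exp(−TR/T1); slopes outside (0, 1)
   are masked.  The line's intercept also yields an equilibrium-amplitude
   map kept in the extras.
7. **PD** — the PD-weighted (α = 4°) image is compensated as
   M = I₁·exp(TE/T2\*)·(1−E1·cos(B1 α₁))/(sin(B1 α₁)·(1−E1)), leaving
   M = rx·PD.  The receive profile rx is then estimated and divided out,
   and the map is calibrated so the CSF mean is exactly 100 p.u.

**Receive-profile estimation.**  Two estimators are provided.  The default
(`rx_method="als"`) fits the joint multiplicative model
M ≈ level(class) · field(x), with one intensity level per tissue class and
a second-order spatial polynomial field, by alternating least squares —
the same decomposition (smooth bias field × piecewise-constant tissue
intensities) that underlies standard MR bias-field correction.  Tissue
classes are derived from the T1 map by 1D clustering in the rate domain
R1 = 1/T1 (rate-domain clustering is essential: the noise of a fitted T1
explodes for long-T1 CSF voxels where the VFA slope approaches one, and
T1-domain clusters collapse).  Because the phantom's receive field is
itself a second-order polynomial, this estimator is exact on noiseless
data; on real data its accuracy is limited by how well a low-order field
plus class levels describes the image.  The alternative
(`rx_method="smooth"`) divides M by a per-class tissue-model prediction
and heavily smooths the ratio (Gaussian, σ = 16 mm default); it removes
most of a ±30 % profile but plateaus at ≈ 1.5–2 % compartment bias from
edge effects and tissue-scale residuals, which is why it is not the
default.

## Synthetic MP-RAGE and segmentation

T1-weighted anatomies are computed from the quantitative T1 map by exact
steady-state evaluation of the MP-RAGE cycle (inversion, delay, 160
readout pulses of 9° spaced 8.1 ms, recovery to TR = 1900 ms with
TI = 900 ms): one cycle acts on the longitudinal magnetization as an
affine map whose fixed point is the steady state; the signal is read at
the center-of-k-space pulse (linear ordering, center at pulse N/2) and
weighted by PD when available.  Perfect inversion is assumed (efficiency
configurable).  The signal is strictly decreasing in T1 over
[300, 4000] ms at the default protocol, which guarantees the CSF < GM < WM
contrast ordering the segmentation relies on.

Segmentation is a deliberate re-scoping of surface-based cortical
reconstruction: 3-class k-means on intensity (classes ordered CSF < GM <
WM), with gray matter split into the cortical ribbon (largest connected
component) and deep GM (interior components).  On noiseless phantoms it
agrees with the ground-truth labels at Dice ≥ 0.95 per class.  Its known
limit: deep GM is distinguished from WM only by intensity and topology, so
a subject whose deep-GM T1 drifts toward WM T1 (plausible under the
default between-subject SD of 159 ms) can lose the 24–1000-voxel deep-GM
blobs entirely.  Cohort studies therefore use the oracle-segmentation
bypass (ground-truth labels), which the pipeline exposes as a first-class
mode; the clinical workflow being emulated used prior-based surface
segmentation, which is out of scope here.

## Compartments and summaries

Cortical values are sampled on the **middle 20 % of the ribbon**: depth is
d_WM/(d_WM+d_CSF) from Euclidean distance transforms to the WM and
CSF/background boundaries, and the mid-ribbon is 0.4 ≤ depth ≤ 0.6.  This
volumetric depth fraction replaces surface projection fractions and
demonstrably reduces boundary partial-volume bias on phantoms with mixed
boundary voxels.  WM and deep-GM masks drop voxels with T1 > 2,000 ms
(CSF partial-volume exclusion); voxels with undefined T1 are dropped too,
since their partial-volume status cannot be established.  Summaries are
unweighted voxel means with sample SD (n−1); empty compartments raise
errors rather than emitting NaN rows.

## Group inference

ROI comparisons are pooled-variance two-sided two-sample t tests on the
per-subject compartment means (df = n_A+n_B−2), uncorrected across the
nine compartment × parameter combinations, matching the exploratory
stance of the emulated analysis.

Voxel-wise comparisons run **per compartment** (mid-ribbon, WM, deep GM),
each within its own mask, so that the mask-aware Gaussian smoothing
(FWHM 10 mm default) never mixes tissue classes — for the one-voxel-thin
mid-ribbon this approximates surface smoothing.  The statistic map is the
two-sample t; threshold-free cluster enhancement (TFCE) integrates
e(h)^E·h^H·dh over thresholds (E = 0.5, H = 2, dh = max|t|/100 per map,
26-connectivity), both tails enhanced on the signed and negated maps.
Family-wise error is controlled by the permutation distribution of the
maximum enhanced statistic: group labels are permuted (seeded; the
identity permutation is always included, so corrected p ≥ 1/n_perm;
exhaustive enumeration replaces sampling when fewer arrangements exist
than requested permutations), and the corrected p of a voxel is the
fraction of null maxima at or above its observed score.  Clusters are the
connected components of corrected p < 0.05.  A classical cluster-extent
mode (cluster-forming threshold p < 0.001 voxel-wise, max-extent null) is
available as an alternative.

The production TFCE is an incremental union-find threshold sweep
(numba-compiled) that accumulates scores per component root and resolves
per-voxel scores through offset path-sums, making each of the ~100
threshold steps cost O(live components); it is verified against an
independent brute-force full-relabeling sweep to < 10⁻⁹ relative error.

## Validation scale and what it shows

The acceptance-style checks use problem sizes chosen for a desk-scale
single-CPU run: reported-mean recovery on the full 64³ grid; permutation
type-I calibration with 200 replicates of 10+10 cohorts at 32³ (500
permutations, WM mask, subject maps built from cohort ground truth plus
voxel noise — the calibration tests the inference engine, not the fitting
chain); the null-cohort restatement and the +8 ms cortical-T2 positive
control with full simulate→fit→summarize chains for 27+27 subjects at 28³
and SNR 50.  A composite requirement that all twelve α = 0.05 null tests
be simultaneously negative in ≥ 95 % of runs is not statistically
attainable (each test alone rejects ~5 % of the time), so the negative
result is asserted as: pooled rejection counts across runs must not exceed
the one-sided binomial 95 % bound for a true rate of 0.05.

**What passing does not show.**  The phantom has piecewise-constant
anatomy, polynomial fields, ideal spoiling, no motion (all co-registration
is identity), no slice profiles, no chemical shift, and boundary partial
volume only in a dedicated mode.  Recovery of the reported means
demonstrates the correctness of the estimation chain under its own forward
model — not the accuracy of the original scanner measurements, and not
robustness to the many real-data effects the generator omits.

## Known limitations

- Stimulated-echo and spoiling corrections are labeled approximations or
  identity hooks; the published corrections they stand in for are not
  reproduced.
- Intensity-only segmentation cannot separate deep GM from WM when their
  T1s coincide; use oracle labels or external segmentations there.
- The B0 map is estimated and carried through but no off-resonance
  correction of the VFA T1 is applied by default.
- The `smooth` receive-profile estimator retains percent-level bias; the
  `als` estimator assumes a low-order multiplicative field.
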