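# Methods

## Overview

`cctpipe` measures cerebral circulation time (CCT) — the arterial-to-venous
transit delay of a contrast bolus — from dynamic contrast acquisitions, and
evaluates it as a diagnostic marker for post-SAH vasospasm alongside the
classical perfusion parameters.  Because the pipeline is validated entirely
on synthetic data, this note describes both the measurement model and the
generator, and is explicit about what passing tests do and do not establish
about real acquisitions.

## Time–density curves and time to peak

A region of interest (ROI) on a dynamic series is reduced to its mean
intensity per frame.  Baseline handling follows each modality's convention:

* **DSA** — the pre-contrast mask frame defines t = 0 and its mean is the
  baseline (subtracted angiography; background is zero by construction).
* **CTP** — the mean of the first `mask_frame_index` frames (default 3) is
  the baseline; t = 0 is the start of the acquisition.  Three pre-contrast
  seconds is ample at the default bolus arrival (~7 s after scan start); for
  protocols with earlier arrival the count is configurable.

Times are frame index × frame interval relative to the reference frame; no
sub-frame acquisition-timing model is applied.

Time to peak (TTP) is the time of the curve maximum.  Two estimators:

* `argmax` (default) — earliest frame of maximum value.  Deterministic tie
  rule, matches the discrete nature of a 1 s protocol.  Quantization error
  is uniform over ±half a frame.
* `parabolic` — three-point parabolic interpolation around the discrete
  argmax (falls back to argmax at the curve boundary; never moves the peak
  by more than one frame).  Used whenever sub-frame accuracy matters, e.g.
  in the ground-truth recovery experiments: the difference of two argmax
  TTPs on a 1 s grid carries ~0.41 s RMS quantization error by itself, so a
  sub-frame estimator is required to resolve recovery errors below that.

Quality flags (`peak_at_boundary`, `low_contrast`, `constant_series`) are
advisory, never hard failures — genuinely late peaks occur in prolonged
transit and must not be discarded silently.

## Circulation-time indices

CCT = venous TTP − arterial TTP, in seconds, positive when the vein peaks
later (the physiologic case; negative values are returned but flagged).

Pairings (the ROI naming follows the anatomy: A2 = second segment of the
anterior cerebral artery, M2 = insular middle-cerebral branch, SSS =
superior sagittal sinus):

* DSA, per carotid injection: `XA-CCT_RA2`, `XA-CCT_RM2` against the
  right-side SSS reading; `XA-CCT_LA2`, `XA-CCT_LM2` against the left.
* CTP: `CT-CCT_A2` (dominant-side A2), `CT-CCT_RM2`, `CT-CCT_LM2`, all
  against the single SSS ROI.

Two readers measure every index independently; discrepancies are resolved by
the arithmetic mean before any downstream statistics.

## Perfusion comparators

* **CBV** (ml/100 g) = `100·(k_H/ρ) · area(tissue)/area(AIF)` with
  trapezoidal areas, hematocrit correction `k_H = 0.73` and brain density
  `ρ = 1.04 g/ml` (standard literature constants, configurable).
* **CBF/MTT** — truncated-SVD deconvolution.  The AIF (taken from the A2
  ROI, matching the manual-ROI workflow) forms the causal convolution matrix
  `A[i,j] = Δt·AIF[i−j]`; the flow-scaled residue solves `A·x = tissue`
  with singular values below a fraction of the largest discarded.  CBF is
  the residue peak scaled to ml/100 g/min; MTT = 60·CBV/CBF (central-volume
  principle), so the identity holds exactly for the module's outputs.
* **TTP maps** — voxelwise argmax of the baseline-corrected voxel TDC.

**Truncation fraction.**  The default 0.2 is the standard choice at clinical
SNR; it buys noise robustness at the price of systematic CBF underestimation
(−24 % measured on the noiseless exponential-residue phantom).  For low-noise
or noiseless data a cutoff of 0.05 recovers CBF and MTT within ~5 %, and
that setting is used in the noiseless QC experiments.  Two further numerical
facts worth knowing:

* The convolution matrix is singular (the AIF is zero at t = 0), so a zero
  cutoff is not a valid "exact" mode; some truncation is always required.
* A discontinuous residue (box model) excites the discarded spectral
  components, leaving a resolution-independent Gibbs overshoot (~8 % in CBF)
  for any fixed relative cutoff; with finer sampling the error converges to
  that floor, not to zero.  Smooth (exponential) residues do not suffer
  from this.

No delay-insensitive (block-circulant) variant is implemented: the phantom
controls tracer delays, so delay sensitivity costs nothing here.

## The synthetic cohort generator

The generator defines the conditions every experiment runs under.

* **Cohort**: 19 control + 22 vasospasm subjects by default.  Per-subject
  ground-truth CCTs are drawn per index from group normal distributions
  (defaults, in seconds — control mean ± SD / vasospasm mean ± SD):
  XA-CCT_RA2 4.9±0.9 / 6.0±1.3, XA-CCT_LA2 4.6±1.0 / 5.8±2.4, XA-CCT_RM2
  4.7±1.3 / 5.8±2.1, XA-CCT_LM2 4.9±0.8 / 5.9±2.1, CT-CCT_A2 5.0±2.6 /
  6.4±2.2, CT-CCT_RM2 4.9±2.2 / 6.4±2.2, CT-CCT_LM2 5.2±2.1 / 6.7±1.7 —
  truncated below at 0.5 s to exclude non-physiologic transit.  The
  truncation shifts the realized moments slightly (e.g. +0.24 s on the
  control CT-CCT_A2 mean); calibration tests therefore compare against the
  analytic truncated-normal moments, which are what the generator draws
  from.
* **Bolus model**: peak-normalized gamma-variate
  `A·((t−t0)/(αβ))^α·exp(α−(t−t0)/β)`, mode at `t0 + αβ`.  Venous curves are
  more dispersed (αβ = 9 s CTP / 3.5 s DSA vs 6 s / 2 s arterial) and lower
  in amplitude (70 vs 100 CTP; 60 vs 100 DSA).  Per subject, one venous peak
  time is drawn per acquisition (around 19.5 s for CTP, 9.5/9.1 s for the
  right/left DSA injections) and each arterial mode is placed earlier by
  exactly that index's true CCT — the ground truth is the difference of
  analytic modes by construction.  The venous peak is raised when needed to
  keep every bolus arrival ≥ 0.5 s.
* **Acquisitions**: CTP is a 64×64×4 voxel grid × 60 frames at 1 s (one
  minute at a 1-second fixed scan interval); DSA is 128×128 × 50 frames at
  0.5 s with a zero-signal mask frame at index 0.  The DSA frame rate is a
  package default — dynamic angiography protocols vary and 2 frames/s is
  typical; it is configurable.
* **Tissue**: every non-vessel CTP voxel carries baseline 40 plus the
  indicator-dilution curve `(CBF/(60·100·k_H/ρ))·(AIF ⊛ R)·Δt` with an
  exponential residue.  True MTT and CBV are drawn per group (MTT 5.5±1.1 /
  6.3±2.1 s, CBV 4.0±1.6 / 3.3±1.0 ml/100 g) and CBF := 60·CBV/MTT, so the
  central-volume identity holds in the truth.  The sampled residue's decay
  constant is calibrated so its discrete (rectangle-rule) area equals the
  specified MTT exactly — otherwise truth and any discrete indicator-dilution
  estimate would disagree by ~Δt/(2·MTT) (13 % at MTT 4 s), a sampling
  artifact rather than a method error.
* **ROIs**: square blocks sized by vessel caliber — 3×3 voxels for A2/M2
  arteries, 5×5 for the much larger SSS, 15×15 for the parenchymal tissue
  ROI.  The dominant-ACA side (Bernoulli, P = 0.5 per subject) shifts the A2
  position; the label set is fixed per modality.
* **Noise**: i.i.d. Gaussian on every voxel and frame, default SD 5 — SNR 20
  against the arterial peak amplitude of 100.
* **Readers**: each reader re-places every ROI with an integer in-plane
  displacement `round(N(0, jitter))` per axis (default jitter 0.5 voxels,
  which reproduces the ICC ≈ 0.95–0.98 agreement typical of trained readers;
  the jitter-sweep experiments vary it explicitly).  Displacements that
  would push a mask over the grid edge are clamped and flagged.  Displaced
  ROIs may overlap; larger ROIs are painted first so a drifting tissue block
  never erases a vessel ROI.
* **Clinical fields**: GCS ~ N(12.3, 3.9) control / N(10.3, 4.5) vasospasm,
  clipped to 3–15; Fisher grades drawn from the groups' categorical
  distributions (6/6/1/6 of 19 and 5/2/2/13 of 22).
* **Determinism**: everything is a pure function of (config, seed).
  Per-subject and per-reader seeds derive from the master seed by fixed
  integer arithmetic, so any subset of a cohort regenerates identically.

**What the phantom does not model**: anatomy (vessels are blocks at fixed
fractional positions), CT physics (no beam hardening, no photon statistics —
noise is white and Gaussian), contrast pharmacokinetics beyond the
gamma-variate + residue convolution, recirculation, motion, and the
waveform difference between intra-arterial and intravenous injection (the
two modalities simply use separate bolus parameters).  Passing tests
demonstrate that the *measurement and statistics machinery* is correct and
well-calibrated under known truth; they say nothing about ROI placement on
real anatomy or vendor-software equivalence.

## Statistics

* **ICC** — ICC(2,1): two-way random effects, absolute agreement, single
  measure, computed from ANOVA mean squares; the conservative choice for
  "two observers measure the same quantity".  95 % CI by the standard
  F-based interval (McGraw & Wong).  Identical readers are reported as
  ICC = 1 with a degenerate flag.
* **Pearson r** with two-sided t-based p; reported per CT-vs-XA index pair
  and per index against GCS.
* **Student's t** — pooled variance by default (Welch optional), two-sided.
* **Chi-square** — Pearson, no continuity correction, for the Fisher-grade
  distribution.
* **ROC** — empirical curve, higher score = vasospasm (direction reversed
  for CBV and CBF, which fall in vasospasm).  AUC by trapezoid in integer
  count arithmetic, which makes it exactly the Mann–Whitney statistic with
  ties counted ½.  95 % CI by the Hanley–McNeil standard error; p-value
  against AUC = 0.5 by normal approximation.  The optimal cutoff maximizes
  Youden's J over all achievable thresholds, ties broken toward higher
  sensitivity, and is reported as the midpoint between the adjacent distinct
  scores ("score ≥ cutoff" is the positive rule).
* **Multiple testing** — none; every index is tested at α = 0.05, and that
  is a documented limitation of the analysis design, not an oversight.

ROC rows are produced for all eleven variables (seven CCTs and four
perfusion parameters) regardless of group-comparison significance; filtering
to significant variables is left to the user.

## Problem sizes in the validation experiments

The recovery and calibration experiments use: 100 subjects for the CCT
round trip at SNR 20; 50 random instances (n ≤ 30 per group) for the
AUC/cutoff oracle equivalences; 50 random 41×2 tables for the ICC oracle;
10,000 replicates at n = 19 vs 22 for the t-test type-I calibration; 2,000
subjects for the binormal-AUC check; 50 seeds × 12 subjects per jitter level
for the reader-agreement sweep; and the full default 41-subject cohort,
simulated and analyzed twice, for end-to-end byte-level determinism.

## Known limitations

* Argmax TTP at a 1 s interval quantizes each timing to ±0.5 s; CCT
  differences inherit ~0.41 s RMS error.  The parabolic refinement removes
  most of this on smooth curves but is more sensitive to noise on flat
  venous peaks.
* The truncated-SVD CBF is biased low at the 0.2 clinical default (see
  above); comparisons between groups are unaffected in direction but
  absolute values should be read with the bias in mind.
* The AUC p-value uses the Hanley–McNeil normal approximation at the
  observed AUC; exact or DeLong-type inference is not implemented.
* The reader model jitters ROI *position* only; it does not model ROI size
  or shape disagreement.
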