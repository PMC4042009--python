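# Methods

## Overview

`ktblast` studies how k-t undersampling affects cardiac cine MRI and the
left-ventricular (LV) functional indices derived from it. The pipeline has
five stages: (1) a synthetic short-axis cine phantom of a contracting LV
with analytically known cavity and wall volumes; (2) simulated k-space
acquisition with complex Gaussian noise and optional signal averaging;
(3) sheared-lattice undersampling plus a central-row training scan;
(4) kt-BLAST reconstruction (training-informed Wiener-style unaliasing in
x-f space); and (5) quantification — normalised reconstruction error over a
heart-centred ROI, blood–myocardium CNR, LV volumetry/mass, and
Bland–Altman agreement statistics between scan protocols.

## Phantom model

Each slice/frame is two concentric discs on a dim background: a bright
cavity (blood pool, intensity 1.0 a.u.) inside a myocardial annulus
(0.45 a.u.), background 0.05 a.u. Radii contract between end-diastolic (ED)
and end-systolic (ES) values with a raised-cosine time course (smooth and
periodic; the minimum sits at `systole_frame_fraction` of the cycle,
default 1/3), and taper linearly from base to apex (`taper_apex = 0.6`).
Defaults are a murine operating point: 192×192 matrix over a 30 mm FOV
(0.156 mm pixels), 8 contiguous 1 mm slices, 12 frames per cycle at
500 bpm, base endocardial radii 1.95 → 1.23 mm (ED → ES) and epicardial
radii 3.17 → 2.78 mm, chosen so the analytic cohort means are EDV ≈ 63 µL,
ESV ≈ 25 µL, EF ≈ 60 %, LV mass ≈ 108 mg (wall volume is conserved over the
cycle; mass assumes 1.05 mg/mm³). An optional hypokinetic angular sector
(reduced radius excursion) emulates an infarcted wall; it changes geometry
only, not signal.

Pixels are labelled by centre-point containment with no anti-aliasing, so
mask volumes are exact voxel counts and differ from the analytic
(radius-based) volumes by at most a one-pixel band along each perimeter.
Analytic volumes — not pixel counts — are the ground truth carried
downstream. Papillary muscles, myocardial texture, flow and respiratory
motion, and coil sensitivities are deliberately not modelled.

Image indexing is `(y, x, slice, frame)`, 0-based, with y the phase-encode
axis. k-space is stored DC-at-centre; temporal frequency f uses
DC-at-index-0. All FFTs are unitary so Parseval-style checks are
scale-free.

## Acquisition and sampling

`corrupt_kspace` takes each slice/frame to k-space (unitary 2-D FFT) and
adds independent complex Gaussian noise, SD `noise_sd` per real/imaginary
channel. The default `noise_sd = 0.2` per single average puts the
three-average standard protocol at a blood–myocardium CNR of ≈ 3.4 on a
mid-ventricular ED slice, a realistic figure for murine 7 T cine imaging.
`n_averages` simulates scanner signal averaging by complex averaging of
independently corrupted acquisitions (noise SD ∝ 1/√averages).

The accelerated acquisition samples every r-th phase-encode row with the
first-row index incremented per frame: `mask[k, t] = 1` iff
`k ≡ t (mod r)`. Over r consecutive frames the lattice covers every row
exactly once (completeness), which is what makes the temporal-average image
exactly recoverable. The training scan acquires the central 16 rows at
every frame. Frames must divide by r (12 frames support r ∈ {2, 3, 4, 6});
other combinations are rejected rather than approximated. Net acceleration
accounts for the training overhead: `n_ky / (ceil(n_ky/r) + training_rows)`
— 192 rows at r = 3 with 16 training rows is a net 2.4-fold speed-up.

## kt-BLAST reconstruction

Lattice undersampling folds each x-f voxel (y, f) onto the r−1 partners at
`(y + m·n_y/r, f + m·n_frames/r) mod (n_y, n_frames)`. The training scan,
zero-filled to the full matrix (low-pass interpolation) and Fourier
transformed along time, provides the expected signal power M²(y, x, f).
Each aliased measurement a (the zero-filled x-f value rescaled by r, which
makes a static scene unbiased) is apportioned within its alias set by
shrinkage weights

    v̂ᵢ = M²ᵢ / (Σⱼ M²ⱼ + ψ) · a .

Numerical and design choices:

- **Baseline (DC) resolution** (`baseline_mode="resolve_dc"`, default): the
  temporal-average k-space is formed from each row's sampled frames (exact
  for static content by lattice completeness), subtracted in k-t before
  unaliasing, and added back at f = 0 afterwards. The training prior's f = 0
  plane is zeroed accordingly (subtracting the temporal mean exactly
  removes f = 0). Without this step static tissue ghosts; with it a
  temporally constant scene is reconstructed to machine precision at every
  supported r, independent of ψ.
- **ψ default** (`psi="auto"`): the per-sample noise power σ² is estimated
  from the sampled entries of the outermost k-space rows of the accelerated
  data (a pure-noise region of what is actually acquired), and ψ is that
  noise power expressed in the units M² lives in — the power passed by the
  training band, σ²·band/n_ky. Using raw σ² instead would compare
  band-filtered signal power against full-band noise power and over-smooth
  the dynamics substantially. In auto mode M² is additionally debiased by
  the same band-noise power (clipped at zero), since the raw training
  magnitude otherwise inflates every alias weight uniformly. With an
  explicit numeric ψ the prior is used as given and the filter is strictly
  linear in the data.
- **Degeneracy**: an alias set with ΣM² = 0 yields zeros when ψ > 0
  (signal-free region) and raises an error when ψ = 0.
- r = 1 input is returned as the plain fully sampled magnitude
  reconstruction; no filtering is applied.
- The output is the magnitude image; all error metrics and volumetry
  operate on magnitudes.

The reconstructor is exposed as a scikit-learn-style estimator
(`KTBlast().fit(training).transform(undersampled)`), with the acceleration
factor inferred and validated from the data's sampling mask.

## Quantification

**Reconstruction error.** ε is the mean of |I_f − I_u| / I_f over every
frame, slice and pixel of a 60×60 ROI centred on the heart, where I_f is
the fully sampled and I_u the undersampled reconstruction. Pixels with I_f
below 1 % of the ROI maximum are excluded from both numerator and count
(the ratio is unstable near zero); the exclusion fraction is reported.
Note ε is normalised per pixel, so in noisy low-intensity background the
ratio is noise-dominated: absolute ε values depend strongly on how much
background the ROI contains, while the trend over r is the robust signal.

**CNR.** (S_blood − S_myo)/σ with σ = √(sd²_blood + sd²_myo), measured on a
mid-ventricular slice at the ED frame; on the phantom the myocardial sample
is the full annulus (it has no distinct septum).

**LV indices.** Volumes are Simpson-style slice summations of labelled
voxels (mm³ = µL); mass is wall volume × 1.05 mg/mm³. ED/ES are the frames
of extremal cavity volume (ties to the earliest frame; a constant series is
flagged, not an error). EF = 100·(EDV − ESV)/EDV. The wall-velocity measure
is the change in sphere-equivalent cavity radius r_eq = (3V/4π)^{1/3}
between ED and ES times heart rate; the sphere convention is a declared
choice (a disc-from-midslice-area convention would give different absolute
values).

**Surrogate segmentation.** Reconstructed images are segmented by a
deterministic stand-in for manual boundary tracing: a 3×3 median prefilter
(edge-preserving speckle suppression — the counterpart of a human tracer's
noise robustness), midpoint thresholds between the phantom's nominal
intensities within a ground-truth-dilated search region, a morphological
closing, and largest-connected-component selection for the cavity. Because
magnitude images have a Rician noise floor, the background level used for
the myocardium threshold is measured from corner patches rather than
assumed. This surrogate is deliberately simple; it is more sensitive to
reconstruction blur than a human analyst, which makes the measured
acceleration-induced biases conservative (slightly pessimistic).

**Statistics.** Bland–Altman bias, sample SD of paired differences and
bias ± 2 SD limits (2, not 1.96, matching the plotted convention);
significance by two-tailed one-sample t-test of the differences.
Protocol-versus-protocol comparisons use the paired two-sample t-test,
since every subject is scanned under every protocol. No multiple-testing
correction is applied across the six indices.

## Experiment drivers and cohorts

Two designs are wired together:

- **Retrospective sweep** (`run_simulation_sweep`): 9 subjects, one
  four-average acquisition each, undersampled in software at
  r ∈ {1, 2, 3, 4, 6} (training rows taken from the same acquisition); ε
  and indices tabulated per r.
- **Protocol comparison** (`run_scan_comparison`): 6 subjects, each
  "scanned" with CINE-3 (full sampling, 3 averages), CINE-1 (full sampling,
  1 average) and ktB-3 (r = 3 lattice plus a separate 16-row training scan,
  3 averages each, independent noise per scan); Bland–Altman agreement per
  index for ktB-3 vs CINE-3, CINE-1 vs CINE-3 and ktB-3 vs CINE-1, plus CNR
  per protocol.

Between-subject anatomical variability is a 5 % lognormal jitter on the
radii (with a milder independent jitter on the ES endocardial radius, so EF
varies too). All randomness descends from a single integer seed; identical
config + seed reproduces outputs exactly.

Problem sizes (192² × 8 slices × 12 frames, 9- and 6-subject cohorts) keep
the full study at a few minutes on one CPU.

## What the phantom does and does not establish

Passing tests show the pipeline's internal consistency: exact sampling
geometry, machine-precision static-scene recovery, exact alias-set
geometry, correctly computed metrics and calibrated statistics, and the
characteristic degradation physics — ε grows with r; temporal smoothing
from the shrinkage filter inflates ESV progressively with r while EDV is
approximately maintained, depressing SV and EF; three signal averages cut
background noise by √3. Measured at the default operating point, the
accelerated protocol's group EF bias against the standard protocol is
≈ −5 to −6.5 percentage points depending on the cohort seed (ESV bias
≈ +1.7 µL, EDV ≈ −3 µL). Because the phantom has razor-sharp edges (high
temporal harmonics), no papillary muscles, no flow artefacts and a
threshold-based surrogate segmenter, these numbers characterise the
pipeline under idealised-but-harsh conditions and do not quantify
performance on real murine data.

## Known limitations

- The training prior is a zero-filled (low-pass) estimate; localized
  temporal harmonics at moving edges are under-weighted, which is the root
  of the ESV-overestimation mechanism. No smoothing along f is applied.
- The ψ heuristic assumes the outer k-space rows are signal-free; scenes
  with substantial high-ky energy would inflate ψ.
- The surrogate segmenter requires the phantom's ground-truth masks as a
  search region and its nominal intensities for thresholds; it is not a
  general cardiac segmenter, and user-supplied data need user-supplied
  masks.
- Acquisitions with frame counts not divisible by r are rejected rather
  than handled by approximate alias geometry.
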