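# Methods

This note documents the models and procedures implemented in `capscan`, the
defaults they use and why, the numerical conventions, and what the synthetic
generators do and do not emulate.

## Image model

A nucleus is rendered on a 64×64 canvas at 0.1 µm/px (yeast nuclei at
60–100× magnification; nucleus radius ~1 µm = 10 px). The nuclear envelope is
an axis-aligned ellipse (default semi-axes 10 × 8.5 px) with a Gaussian
radial cross-section of width `envelope_thickness` (1.5 px), matching the
diffraction-limited appearance of the envelope in a focal plane. The
noiseless ring intensity at envelope angle θ is

    base · maturation_weight · [(1−d)·ρ(θ) + d·ρ_d(θ)] · (E if θ in cap else 1)

where:

- `ρ(θ)` is the **NPC density field**, a nonnegative 2π-periodic mean-1
  function shared by all channels. The default is a random lognormal angular
  texture, `exp(Σ_k a_k cos(kθ+φ_k))` over Fourier modes 2–7 with log-std
  ≈ 0.4, normalized to unit mean. This emulates the punctate, cell-to-cell
  variable distribution of NPCs along the envelope and is the structure that
  two co-labeled channels share.
- `d ∈ [0,1]` is the **displaced fraction** of a channel's envelope signal
  that no longer follows the NPC density — a nucleoporin leaving NPCs while
  remaining at/near the envelope. The displaced component is given an
  *independent* random angular texture of mean 1 (same family as ρ), drawn
  per channel from the seed stream. Design rationale: a mean-1 displaced
  field conserves total intensity in expectation, so colocalization changes
  are not confounded with brightness changes; making it an independent random
  field (rather than a deterministic constant) is what actually decorrelates
  the two channels — with a constant displaced component the d=1 profile
  would be exactly flat and its Pearson correlation undefined rather than
  zero-mean.
- `E ≥ 0` is the **cap enrichment** applied on the arc within
  `cap_half_width` (default 30°) of `cap_center_angle`. The cap arc recorded
  in the ground truth is the closed set |θ − θ_cap| ≤ half-width.
- A cluster-marker channel additionally renders the DNA-circle cluster as a
  Gaussian blob just inside the envelope at the cap angle
  (`cluster_focus_intensity`, default 300 photons/px). The marker channel for
  cap quantification carries no envelope ring (a TetR-mCherry-like
  nucleoplasmic label), while colocalization pairs use two ring channels.

Detection: the noiseless image is blurred with a normalized Gaussian PSF
(default σ = 0.75 px ≈ 0.077 µm, the diffraction limit for GFP at NA 1.4),
a uniform background is added (default 40 photons/px), intensities are gain
scaled (default 1 count/photon) and noised — Poisson on signal+background by
default, Gaussian read noise optional. Defaults give a peak ring SNR of ~11.
Blur conserves total intensity to <0.1% at the enforced 3σ canvas margin.
Optional z-stacks (6 planes, 0.5 µm spacing) put the middle plane in focus;
quantification always uses a single focal plane.

What the generator does **not** emulate: 3D PSF optics, discrete single-NPC
puncta (the density field is a smooth texture), cytoplasmic autofluorescence
structure, bud/cell-cycle geometry, multi-nucleus scenes, or chromatic
offsets between channels. Passing recovery tests therefore shows the
*statistics and geometry pipeline* is correct and unbiased under realistic
noise — not that segmentation would survive every real-world artifact.

## Envelope tracing and line scans

Hand-drawn segmented lines are replaced by radial-maximum ray casting, chosen
over active contours for determinism and testability. The image is smoothed
(Gaussian σ = 1 px), an initial center is taken as the background-subtracted
intensity centroid, and for each of 180 equally spaced angles the contour
point is the radial position of maximum smoothed intensity along the ray
(0.25 px steps, sub-pixel parabolic refinement), followed by periodic median
smoothing (window 5). Because a bright cap biases the intensity centroid, the
center is refined twice by re-centering on the centroid of the traced
contour, which is brightness-unbiased. A ray is "contrasted" when its peak
exceeds the image median by 5 robust standard deviations (1.4826·MAD); if
≥20% of rays are not, tracing fails with "no envelope found". `n_samples` is
fixed at 180 so profiles are comparable across cells.

Profiles are the mean of bilinearly interpolated intensities at `linewidth`
(default 3) positions spaced 1 px along the radial direction through each
contour point; both channels are always sampled at identical positions (one
shared contour), which is a precondition for the profile correlation.

Region partition: the cap is the closed set of samples within
`cap_half_width` (default 30°; exposed in config — the true angular extent of
a cap is not observable directly) of the direction from the contour center to
the cluster focus (brightest smoothed pixel of the marker channel), or within
explicit angular bounds when no marker exists. Background `I_BG` is the
median intensity outside the 3-px-dilated nucleus mask — median rather than
mean because real images contain cytoplasmic signal. Coordinates are 0-based
with pixel centers at integer positions; angles counterclockwise from +x.

## Enrichment and ratio statistics

`RA_corrected = (I_c − I_BG)/(I_R − I_BG)` is invariant under any affine
intensity transform applied jointly to the three inputs, so it is robust to
detector gain and offset. `RA_simple = I_C/I_R` is gain-invariant only; an
additive offset moves it toward 1. Cells with `I_R ≤ I_BG` have an undefined
ratio and are excluded and logged, never imputed. Per-group summaries report
the **median** RA (robust to the right-skewed per-cell distribution) and
`log2(RA)` is recorded per cell for plotting.

At the default PSF, blur carries cap intensity across the cap boundary in
both directions; the measured median RA therefore sits slightly below the
generative `E` for `E > 1` (about −8% at E = 4, within the 15% recovery band
used in the tests), and slightly above for `E < 1`.

Group comparisons use the two-sample Student's t-test with pooled variance by
default (Welch optional), two-sided, reporting group means and SEMs. Zero
pooled variance is handled deterministically (equal means → p = 1; unequal →
p → 0, flagged degenerate). No multiple-testing correction is applied by
default; a Benjamini–Hochberg helper exists but is off.

The tandem-timer ratio divides background-corrected mCherry by sfGFP envelope
means; in the generator the red maturation weight equals the age parameter,
so the true ratio is the age parameter exactly and recovery is unbiased. The
nuclear/cytoplasmic ratio takes explicit disjoint masks and a background
estimate.

## Colocalization

Per-cell colocalization is the Pearson correlation between the two channels'
raw profiles. Background subtraction is deliberately not applied: Pearson's r
is invariant to per-channel offsets and positive gains, so subtraction is a
no-op and applying it would only suggest otherwise. Constant profiles make r
undefined; such cells are excluded, not clamped. Cohorts (young/old,
mother/daughter, wild type/mutant) are metadata supplied with the cells, and
summaries report mean r ± SEM with the cohort's median age. Independent
detection noise attenuates r toward zero (never past it), so noisy
colocalized pairs read below 1 but displacement still produces a strictly
decreasing mean r in d.

## FLIP

The two-compartment model has an envelope-bound pool B exchanging with a
nucleoplasmic pool N at rate k (`dB/dt = −kB + k_on·N`, with `k_on` set by
detailed balance so the pre-bleach pools are at equilibrium at
`bound_fraction`, default 0.5). During bleaching, N is additionally depleted
at `bleach_rate` (default 20/s — a full-power bleach empties the nucleoplasm
in well under one frame, so the bound pool decays ≈ e^{−kt}; `inf` is
supported and gives that limit exactly). Bleaching is continuous from onset,
i.e. every frame from `pre_bleach_frames` onward is a bleach frame, matching
continuous nuclear-ROI bleaching during 500 ms-interval acquisition. A
per-frame `acquisition_bleach_rate` multiplies all ROIs, including the
adjacent-cell control.

Processing: each series is normalized to its own value at the last pre-bleach
frame (idempotent; the reference frame is exactly 1), then divided by the
normalized adjacent-cell series to remove acquisition bleaching. The primary
decay summary is the **interpolated half-time** (model-free and robust); the
secondary is the rate from a least-squares fit of `A·e^{−kt} + c` with
nonnegative parameters, fitted from the last pre-bleach frame onward with
time re-zeroed there. Fit failures leave the rate missing while the half-time
is still reported. Site comparisons (cap vs equidistant-envelope control) use
a pooled t-test on per-trace half-times; traces on unequal frame grids are
resampled to the coarsest grid by linear interpolation, and traces whose
corrected signal never crosses 0.5 are dropped with a logged warning.

## Replicative lifespan

Lifespans are division counts; cells alive at experiment end are
right-censored at their last counted division. The estimator is the
Kaplan–Meier product limit — the standard choice for microfluidic RLS
cohorts, where >95% retention makes censoring minor — with ties at a division
handled in a single risk-set step (divisions are integers; ties are the
norm). The 95% band is plain-scale Greenwood clipped to [0,1] by default;
the log-minus-log (exponential Greenwood) band is available, as the plotting
convention differs between labs. The median RLS is the smallest event time t
with S(t) ≤ 0.5, which resolves an exact-0.5 plateau deterministically; a
curve that never reaches 0.5 reports "> max observed". Two-group comparisons
use the log-rank test (hypergeometric variance, 1-df chi-square), with
censored records contributing to risk sets only. Estimation is delegated to
lifelines; the tests validate it against hand-computed risk tables and a
brute-force observed-minus-expected oracle, and its null rejection rate at
α = 0.05 calibrates to ~0.05 on simulated equal-hazard cohorts of 50.

The cohort generator draws death divisions by inverse transform from a
per-division hazard, default Gompertz-like `h(t) = min(1, h0·e^{g·t})` with
`h0 = 0.0035`, `g = 0.2`, whose analytic median is exactly 18 divisions —
typical of wild-type cells on microfluidic platforms. Censoring is geometric
per division and independent; a cell whose death and censoring fall on the
same division counts as dead, mirroring how an observed death is scored.

## Determinism and problem sizes

Every generator is a pure function of its parameter object and a single
integer seed; all stochastic draws flow from one `numpy` Generator stream,
and the displaced-field draw consumes the stream identically whether or not
d > 0, so parameter sweeps at a fixed seed stay aligned. CLI outputs embed
the tool version, seed and a config hash, and OME-TIFFs use a
content-derived UUID, so equal (inputs, config, seed) give byte-identical
files.

The validation suite and `scripts/acceptance.py` use cohort sizes of 30–50
cells per condition, 100 replicate experiments for power/null fractions, 30
traces for rate recovery, and 2000 cohort pairs for log-rank calibration —
sizes chosen to hold Monte-Carlo error comfortably below the tolerances being
asserted while keeping a full run to a few minutes on one CPU.

## Known limitations

- The ray-casting tracer assumes one nucleus per image with a roughly convex,
  star-shaped (radially single-valued) envelope; strongly deformed or
  overlapping nuclei are out of scope.
- The displaced-pool texture models envelope-retained mislocalization; a
  nucleoporin that relocates to the nucleoplasm or cytoplasm would change
  total envelope intensity, which the generator deliberately holds constant.
- Detector gain/read-noise of specific microscopes is not matched; noise
  defaults are plausible rather than calibrated to a particular camera.
- FLIP ROIs are treated as reading the bound pool only; partial-volume
  contributions from the nucleoplasm inside the ROI are not modeled.
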