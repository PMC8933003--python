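# Methods

This note records the models implemented in `polycolo`, the estimators and
their assumptions, the defaults that matter, and the design choices made
where several reasonable options existed.

## Synthetic cluster fields

The generator (`polycolo.synthetic.simulate_localizations`) emulates
two-color SMLM of membrane protein clusters:

* cluster centers: homogeneous Poisson process in a rectangular ROI
  (default 10×10 µm at 2 clusters/µm² per channel);
* cluster areas: exponential, default means 3702.5 nm² (channel 1) and
  2157.1 nm² (channel 2) — the scale reported for polycystin surface
  clusters;
* colocalization: a configurable fraction of channel-2 clusters (default
  27%) is re-centered on a distinct channel-1 partner.  The displacement of
  a colocalized pair is zero by default (configurable Gaussian offset):
  imaging data constrain overlap, not a displacement law, so the simplest
  model is used;
* localizations: a fixed count per cluster (default 25) uniform in the disk
  of the drawn area, then jittered with isotropic Gaussian localization
  noise (default sd 27 nm, inside the 25–30 nm precision range typical of
  Alexa-488/647 secondary-antibody labels).  Clusters are disks because only
  areas are constrained by the data being emulated;
* nonspecific background labeling: uniform Poisson points (default
  0.5/µm²).

What the generator does **not** model: antibody linkage error, dye
photophysics beyond Bernoulli blinking (frame stacks only), cluster shape
anisotropy, spatial inhomogeneity of the membrane, and inter-cluster
interactions (true centers are independent).  Tests passing on this model
therefore validate the estimators under ideal point-process assumptions, not
segmentation robustness to structured backgrounds.

Determinism: every generator consumes a single `numpy` Generator seeded from
its config; identical config+seed gives bit-identical output.  The pipeline
expands one global seed into per-stage seeds with fixed
`SeedSequence(spawn_key)` values so stages can be rerun independently.

## Frame stacks and localization

`simulate_frames` integrates a Gaussian PSF (sd `s`) exactly over `q`-sized
pixels (erf differences) and draws per-pixel Poisson counts; emitters are on
per frame with probability `duty_cycle`.  Background counts are Poisson with
mean `b²`, so the per-pixel background noise standard deviation equals the
`b` that enters the precision formula.

`fit_localizations` detects spots as local maxima of a lightly smoothed
frame above an absolute photon threshold and fits each candidate window with
a free 2D Gaussian (x, y, s, amplitude, offset) by **Poisson
maximum likelihood** (L-BFGS-B on the negative log-likelihood).  Plain
unweighted least squares was measured at 1.2–1.5× the two-term precision
prediction because it ignores shot-noise weighting; the MLE tracks the
prediction closely at low background.  The fit window is ±⌈3s/q⌉ pixels;
`b` is estimated as the standard deviation of fit residuals outside 2.5
fitted sigmas; `N` is the integral of the fitted Gaussian.

A caveat the acceptance tests make explicit: the two-term precision
expression is an approximation.  In the background-dominated low-photon
regime (N ≈ 200 photons, b = 2), the exact Cramér–Rao bound of the
generative model lies some 11–14% above it, so the measured precision of
*any* unbiased fitter — ours performs at the bound — exceeds the formula by
that margin there.  At b = 0, or at N ≈ 1000, measured and predicted agree
to a few percent.

`exclude_early_frames` drops records before a frame cutoff (workflow
default 5000, the stabilization period of photo-switching buffers).
`drift_correct` renders time bins (default 50 nm pixels, 1-px Gaussian
blur — the binned point images are too sparse for reliable phase
correlation without smoothing), estimates per-bin shifts against the first
bin by upsampled phase cross-correlation, and interpolates piecewise
linearly between bin centers.  The trajectory is relative to the first bin's
mean position; a second pass on corrected data returns shifts below one
render pixel.

## Cluster segmentation and areas

Default route (`segment_clusters`, backend `"image"`): render at 10 nm
pixels, blur 20 nm, threshold at one localization-equivalent (the peak
intensity a single blurred localization contributes; ties included),
8-connected components seeded by density peaks and separated by watershed
(peak separation 2× the blurred spot size) so that touching clusters are
split.  Localizations are assigned to the nearest segmented footprint
within a capture radius of 1.1× the mean localization precision: footprints
already extend past the true cluster edge by the threshold contour, and
larger radii poach localizations from neighbors (the 1.1 factor was
calibrated on synthetic fields with known ground truth; at 1.5× the
channel-2 area mean biases +6%, at 1.1× the residual biases are −1%/+2%).
Components with fewer than `min_locs` (default 3) members are discarded.  A
DBSCAN point-cloud backend (eps 40 nm) is available behind the same
contract.

**Cluster area.**  The reported area is the precision-deconvolved
disk-equivalent area estimated from the member-localization scatter:
for points uniform in a disk of radius R observed with precision σ the
per-axis variance is R²/4 + σ², hence

    Â = 2π (var_x + var_y − 2σ̂²),   σ̂² = mean(precision²) of members,

clipped below at one render pixel for the physical per-cluster value.  A
thresholded-footprint pixel count (also stored) is not used as the primary
area because convolution with the localization noise and the render blur
inflates it several-fold at these cluster sizes (tens of nm radii).  The
exponential-mean fit uses the *unclipped* moment estimates: the estimate is
the true area plus zero-mean noise, so their sample mean is unbiased for
the exponential mean, while averaging positively clipped values is not
(measured +15% bias at the channel-2 scale).  The Kolmogorov–Smirnov
goodness-of-fit statistic is computed on the clipped (physical) areas.

Exponential fits report the ML mean (= sample mean), a normal-approximation
CI `mean·(1 ± 1.96/√n)`, and the KS statistic against the fitted
exponential.

Known consequences on default synthetic fields, measured against ground
truth over 30 seeds: cluster count recovered to ≈ −3.5% (physically touching
clusters merge; a watershed cannot split disks that genuinely overlap),
area means to −1%/+2% (channels 1/2), nearest-neighbor mean to ≈ +2%.

## Colocalization

Nearest-neighbor distances are Euclidean centroid distances from each
A-cluster to its closest B-cluster (KD-tree; verified against an O(n²)
brute force), with the same exponential-fit report as areas.

**Overlap criterion.**  Default `"disk"`: clusters overlap when the disks
of their measured areas, centred on their centroids, intersect.  This
matches the area operationalization above and is insensitive to the render
blur; with the `"pixel"` alternative (footprints sharing ≥ k render pixels,
both maps on one grid) the blur-inflated footprints produce ~9% chance
overlap at the default densities versus ~2% for the generative disks, which
would mask the colocalized fraction being estimated.  The criterion used is
recorded in the result metadata.

**Randomization null.**  The Costes idea — re-randomize one channel and
recompute the statistic — is applied at the cluster level: every B cluster
is rigidly translated to an independent uniform in-ROI position (shape and
area preserved, out-of-bounds proposals resampled; channel A fixed so the
observed statistic stays comparable).  The empirical one-sided p-value uses
the (k+1)/(n+1) estimator so it is never zero.  The null mean was verified
against an independently coded uniform-placement Monte-Carlo.

Pearson's r is the product-moment correlation over (masked) pixels; zero
variance is flagged (NaN + warning).  Mander's M1 is the fraction of
channel-1 intensity above its threshold residing where channel 2 exceeds
its threshold (M2 symmetric); thresholds default to 0.

## N-FRET

The sensitized-emission index with the square-root normalization:
`N-FRET = (I_DA − d·I_DD − a·I_AA)/√(I_DD·I_AA)`, reported ×100 as a
percentage.  Channels are background-subtracted (clipped at zero, clip
counts recorded) first.  Pixels with `I_DD·I_AA ≤ 1e-12 × max` are excluded
from the ROI mean to avoid division blow-up; the ROI mean is the plain
average over valid masked pixels.  Bleed-through coefficients are Theil–Sen
slopes of I_DA against the respective channel on single-labelled controls
(robust to outlier pixels; exact on noiseless controls).  The synthetic
FRET generator forms `I_DD = D(1−E)`, `I_AA = A`,
`I_DA = DE + a·I_AA + d·I_DD` plus offsets and Gaussian noise, so zero
efficiency yields exactly zero index and the index increases strictly with
the true efficiency.

## Physiology metrics

Current density is current ÷ capacitance (pA/pF).  The flow-evoked
transient is the extremum (inward = minimum by default, configurable) of
the density within a search window after the flow-on marker (default 10 s)
minus the mean over a baseline window before it (default 10 s); no
smoothing is applied, so the noiseless metric is exact.  The steady state
is the mean over a caller-placed contiguous window with a 45-s floor.  The
trace generator produces
`baseline + shift + (amplitude − shift)·exp(−Δt/τ)` between flow-on and
flow-off (defaults: baseline −5.5, amplitude −1.3, shift +4.53 pA/pF, i.e.
steady state −0.97; τ = 2 s; 100 Hz sampling, adequate for a seconds-scale
transient; noise sd 0.05 pA/pF), so the peak equals the amplitude exactly
at onset.

Myogenic tone is `100·(1 − D_active/D_passive)`.  The shear-to-flow
conversion inverts the Poiseuille wall shear `τ = 4ηQ/(πr³)` to
`Q = τπr³/(4η)`, default viscosity 0.007 poise (aqueous physiological salt
solution at 37 °C); both the formula and η are exposed because laboratory
conventions vary.

## Problem sizes and tolerances in the test suite

Statistical checks run at sizes chosen to keep each under a few minutes on
one CPU while leaving ≥3σ headroom: precision consistency uses 800 frames
per grid cell; parameter recovery pools 16 default fields (~3200 clusters
per channel) against a 10% relative band; null calibration compares a
1000-iteration null with a 1000-draw independent Monte-Carlo and checks
95%-interval coverage over 100 seeded 49 µm² fields; detection power and
trace-metric recovery also use 100 seeds.  Hypothesis-based property tests
are derandomized by fixed seeds.

## Limitations

* No 3D/astigmatic localization, multi-emitter fitting, or fiducial-based
  drift correction.
* Segmentation assumes isotropic disk-like clusters; strongly elongated
  clusters would bias the disk-equivalent area.
* The randomization null treats clusters as rigid and independent; it does
  not model exclusion between clusters.
* No pair-correlation/Ripley statistics; the overlap fraction is the only
  cluster-level colocalization effect size.
* Patch-clamp analysis implements window metrics only — no leak
  subtraction, series-resistance compensation, or event detection.
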