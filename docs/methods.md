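# Methods

This note documents the models, the numerical choices and the limits of what
the synthetic benchmarks demonstrate.

## Image and coordinate conventions

Stacks are T×H×W arrays of camera counts. A focus center (x, y) is in pixel
units, 0-based, with (0.0, 0.0) at the *center* of the top-left pixel; x
indexes columns, y rows. Calibration (pixel size in µm, frame interval in s)
always comes from configuration, never from TIFF metadata. Trajectory tables
are CSV with the fixed header
`traj_id,frame,x,y,intensity,width_x,width_y,snr`.

## Simulator

Each focus is a cluster of `n₀` fluorophores (uniform in
[1, max_stoichiometry], or 1) rendered as a pixel-integrated symmetric 2D
Gaussian PSF of width `psf_sigma` (default 1.33 px ≈ 3 px FWHM, the scale of
a GFP PSF at 120 nm pixels) with total integrated intensity
`n_active · isingle`. The background is Gaussian with mean `bg_mean` and
standard deviation `bg_std`; frames are clipped at zero and quantized to
whole counts. Defaults reproduce standard experimental conditions:
isingle = 10,000 counts, bg = 500 ± 120 counts, 10 spots, 128×128 px,
100 frames, D = 1.0 µm²/s, 0.120 µm pixels.

**Photobleaching.** Every active fluorophore bleaches independently with
probability `p_bleach_per_frame` per frame (mean bleach time 1/p frames),
giving step-wise decay with an exponential envelope. Because a fluorophore
bleaches at a uniform-random point within an exposure, the first frame in
which it is counted off receives a uniform-random fraction of `isingle`.
Bleaching is off by default; photobleaching studies enable it explicitly.
Photophysics beyond this (blinking, triplet states, emission spectra,
EMCCD gain) is deliberately not modelled.

**Diffusion.** Brownian steps are applied at the end of each frame (foci are
static during an exposure): per-axis displacements are N(0, 2DΔt), converted
to pixels. The default frame interval is 0.005 s — a typical millisecond-
scale Slimfield exposure — so D = 1 µm²/s gives a per-axis step of
σ ≈ 0.83 px, comfortably inside the linking cutoff. Foci that wander out of
the frame keep their ground-truth records and simply stop rendering; there
are no reflecting walls.

**Placement.** By default foci are placed uniformly but with a 10 px edge
margin and a 10 px minimum pairwise separation. This emulates the sparse
single-molecule regime the detection and strict-linking methods are designed
for; foci closer to an edge than the analysis half-width, or closer together
than the PSF scale, are *by design* discarded or merged by the detector, so
the default study condition keeps the field analyzable. Both constraints can
be set to 0 for unconstrained placement. Explicit positions and
stoichiometries can be supplied for controlled scenes.

**Rod-cell scenes.** Emitters are placed uniformly in the 3D volume of a
spherocylinder (defaults: 3.0 µm tip-to-tip, 0.5 µm radius — a typical
bacterium) whose midplane is the focal plane. Lateral PSF width grows with
defocus as σ(z) = σ₀·√(1 + (z/z_R)²) with z_R = 0.6 µm, and the peak is
scaled so integrated photons are conserved: out-of-focus light spreads
rather than vanishes. The copy-number correction factor is the Monte-Carlo
ratio (total emitted)/(expected detected inside the cell mask) under this
same model — with these defaults ≈ 1.17, dominated by lateral leakage of
broadened PSFs across the mask boundary.

One seeded `numpy.random.Generator` drives placement, stoichiometries,
bleaching, noise and steps, so seeded runs are bit-reproducible.

## Detection

The binarization threshold is the modal pixel intensity of the *smoothed*
image (histogram peak, numpy "auto" binning — Freedman–Diaconis with a
Sturges fallback for degenerate histograms) multiplied by
`bw_threshold_tolerance` (default 0.8), applied to the top-hat-transformed
image. The modal intensity sits at the camera background level, well above
the post-top-hat noise residual and well below PSF peaks, which is what
makes the 0.5–0.8 tolerance range effective. Binary cleanup is an opening
with a 2×2 square (removes single-pixel noise while preserving the 2–3 px
cores of near-threshold foci; a 3×3 element was found to erase real dim
foci) followed by a closing with a 3×3 cross (fills holes).

Gaussian masking uses `gauss_mask_sigma` = `inner_mask_radius` = 3 px,
convergence tolerance 0.01 px, at most 1000 iterations; the local background
is the mean of subarray pixels outside the 5 px integration circle and is
fixed during iteration. The intensity integration radius (5 px) and the mask
radius are deliberately separate parameters. Estimates that leave the
17 × 17 subarray, or fail to converge, are discarded. Duplicate seeds
converging onto the same focus (within 1 px) keep the brighter focus. Widths
are intensity-weighted second moments of the background-subtracted subarray
within the integration circle — cheap, and only used by the colocalization
overlap, where a ~10% truncation bias is immaterial.

SNR is the mean background-corrected intensity per inner pixel divided by
the standard deviation of the surrounding background pixels; with the
default conditions a single 10,000-count fluorophore scores ≈ 1.1, so the
0.4 cutoff is a permissive single-molecule filter, and background-only
frames yield essentially no false positives.

## Tracking

Linking is strict: candidate pairs within `max_displacement` (default 5 px;
the optimized demonstration set uses 7), assigned greedily by ascending
distance with ties broken by focus index. Two kinds of ambiguity terminate
trajectories instead of linking: a next-frame focus reachable from two
current foci (a collision — both end, and the coincident detection starts a
fresh trajectory), and a current focus facing two candidates that are
themselves within the cutoff of each other. There is no dropped-frame
tolerance: a missed detection always splits a trajectory. Trajectories
shorter than `min_traj_len` (default 3) are discarded at output; the
diffusion analysis applies its own, stricter length rule.

## Isingle, stoichiometry, copy number

`estimate_isingle` uses `scipy.stats.gaussian_kde` with `bw_method=0.7`
(kernel σ = 0.7 × sample SD) evaluated on a 1000-point grid over
[0, max]; the half-FWHM of the global peak serves as an error bar. The
"final half of the acquisition" option exists because late in a
photobleaching acquisition most surviving foci are single fluorophores,
concentrating the sample at Isingle. A zero-variance sample short-circuits
to its common value (the KDE would be singular).

Stoichiometry extrapolates a least-squares line through a trajectory's
2nd–4th intensity points back to its first frame (a linear stand-in for the
initial section of the exponential bleach decay that also behaves sensibly
when nothing bleached), then divides by Isingle. Three-point trajectories
are fit on all three points; one- and two-point trajectories fall back to
the first observed intensity and are flagged `extrapolated=False`. Only
trajectories starting within the first 4 frames receive stoichiometries.

The Chung-Kennedy filter replaces each point with a variance-weighted blend
of the backward and forward window means (both windows include the current
point, so on an ideal noiseless step the zero-variance window on the current
plateau wins outright and the trace passes through unchanged; both-zero ties
blend 0.5/0.5). Defaults: window 3, exponent 1.

Copy number per labelled cell is
`correction · (Σ in-mask counts − n_pixels · bg) / isingle`, with `bg` the
mean of background-labelled pixels in the first bright frame and
`correction` from the defocus model above (exposed as a plain scalar for
experimental data).

## Diffusion

MSD uses all overlapping displacement pairs (maximizing counts at low τ).
The fit covers the first 4 lags, weighted by pair count — the concrete
reading of "weighted towards low τ" — and is unconstrained by default; a
known localization precision σ can pin the intercept to 4σ². The
trajectory-length rule is strict: length > 5 frames is analyzed. Estimates
skew slightly low at high D because steps beyond the linking cutoff split
trajectories into slower-looking fragments; on the default benchmark this
bias is well inside one standard deviation of the per-trajectory estimates.

## Colocalization

The overlap integral of two circular Gaussians, normalized to 1 at zero
separation, is exp(−d²/(2(σ₁² + σ₂²))) with σᵢ the mean fitted width of
each focus. The 0.75 threshold is a free calibration parameter (at typical
widths it corresponds to d ≈ 1.4 px). Channels are assumed registered —
true for simulated data, an approximation for real microscopes that needs a
prior affine registration (out of scope here).

## Benchmark problem sizes

The reproduction script (`scripts/acceptance.py`) uses: 3 × 100-frame
photobleaching stacks for Isingle recovery; 20 × 10-frame default stacks
(~2000 matched detections) for the modal localization error, histogrammed in
0.05 px bins; 10 rod-cell scenes of 100 emitters (2000-sample Monte-Carlo
correction factor) for copy number; 10 × 100-frame stacks at D = 1.0 µm²/s
(~150–180 qualifying trajectories) for diffusion recovery. These sizes give
sampling errors comfortably below the quantities' natural spread.

## What the synthetic benchmarks do and do not show

The simulator shares its PSF, noise and bleaching model with nothing in the
analysis path except the defocus correction factor (deliberately
model-consistent), so recovery tests are meaningful end-to-end checks of
detection, localization, linking and estimation. They do *not* exercise:
non-Gaussian/EMCCD noise, photoblinking, chromatic or registration errors
between channels, sample drift, motion blur within an exposure (foci are
rendered static per frame), 3D diffusion through the focal plane, or
autofluorescent backgrounds. Real-data performance depends on parameter
choices — particularly `bw_threshold_tolerance`, `snr_filter_cutoff` and
`max_displacement` — far more than the clean-field benchmarks suggest.

## Known limitations

- The histogram-peak threshold ties detection sensitivity to the camera
  offset scale; very low-offset cameras need a retuned tolerance.
- Overlapping foci are merged or discarded, never multi-fit.
- The MSD intercept ignores motion-blur corrections.
- Stoichiometry extrapolation is linear only (an exponential variant would
  be a small change but is intentionally not provided).
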