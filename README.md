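# smtrack

Single-molecule fluorescence microscopy analysis: spot detection and
sub-pixel localization, strict nearest-neighbour tracking, single-fluorophore
brightness (Isingle) and stoichiometry estimation, diffusion-coefficient
fitting, whole-cell copy numbers, two-color colocalization — plus a
ground-truth simulator that generates matching synthetic image stacks.

It is aimed at researchers doing millisecond single-molecule imaging
(e.g. Slimfield) of fluorescently tagged proteins in live cells, who want to
know *where* their molecules are, *how many* fluorophores each tracked focus
carries, and *how fast* they move.

## The method

**Detection.** Each frame is optionally Gaussian-smoothed, background is
removed with a white top-hat transform, and the image is binarized at a
threshold derived from the pixel-intensity histogram peak scaled by
`bw_threshold_tolerance`. Connected components seed candidate foci, whose
centers are refined by *iterative Gaussian masking*: the center estimate
**r** is repeatedly replaced by

    r ← Σᵢ wᵢ(r) Iᵢ rᵢ / Σᵢ wᵢ(r) Iᵢ

over a 17 × 17 pixel square, where *w* is a Gaussian mask at the current
estimate and *I* the local-background-subtracted pixel values, until the
center moves by < 0.01 px. Foci whose mean background-corrected intensity
inside a 5-px radius, divided by the standard deviation of the surrounding
background pixels, falls below `snr_filter_cutoff` (default 0.4) are
discarded.

**Tracking.** Detections in consecutive frames are linked when separated by
≤ `max_displacement` pixels; ambiguous assignments terminate the
trajectories involved (no gap bridging, no guessing).

**Isingle and stoichiometry.** Pooled background-corrected intensities
(optionally only from the final, mostly-bleached half of the acquisition)
are fit with a Gaussian kernel density estimate (bandwidth factor 0.7); the
peak is the single-fluorophore brightness. A trajectory's stoichiometry is
its initial intensity — a straight line through its 2nd–4th intensity
points extrapolated back to its first frame, correcting for photobleaching —
divided by Isingle.

**Diffusion.** Per trajectory, MSD(τ) is fit over the first four lags with
pair-count weights; D = gradient/4 for 2D Brownian motion.

**Copy number.** Masked, background-corrected cell intensity divided by
Isingle, scaled by a defocus correction computed from the simulator's
optical model.

**Colocalization.** Cross-channel pairs within 5 px are accepted when the
Gaussian overlap integral exp(−d²/(2(σ₁²+σ₂²))) of the fitted widths
exceeds a threshold.

## Worked example

```sh
python examples/simulate_and_track.py
```

```
284 detections over 30 frames -> 11 trajectories
median localization error: 0.228 px (sub-pixel: fitted centers land within a fraction of a 120 nm pixel)
mean trajectory length: 25.8 frames
```

Ten simulated foci diffusing at 1 µm²/s are recovered as (mostly) unbroken
trajectories; the 0.23 px median error at 120 nm pixels is ~27 nm, an order
of magnitude below the diffraction limit. The other scripts in `examples/`
demonstrate stoichiometry (`photobleach_stoichiometry.py`: recovers Isingle
14,062 from an input of 14,000 counts and per-focus fluorophore counts
across 1–10), diffusion fitting, rod-cell copy numbers and two-color
colocalization.

The same pipeline is scriptable from a shell:

```sh
smtrack simulate,track,postprocess demo num_frames=50 seed=1
```

writes `demo.tif`, `demo_ground_truth.csv`, `demo_trajectories.csv`,
`demo_stoichiometry.csv`, `demo_diffusion.csv` and summary plots; trailing
`key=value` arguments override any named default parameter.

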