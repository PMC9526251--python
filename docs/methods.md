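# Methods

This note documents the models, conventions and numerical choices behind
each analysis, what the synthetic generators do and do not emulate, and
the known limitations.

## Units and conventions

Lengths are micrometres internally, velocities nm/min, times minutes;
wavelengths enter the API in nanometres. Voxel coordinates are 0-based
and a voxel's centre is its coordinate, so the geometric centre of a
w×h image is ((w−1)/2, (h−1)/2). All tolerance thresholds are inclusive
on the passing side (a uniformity of exactly 50 % passes): published
tolerance tables mix strict and non-strict inequalities, and the
inclusive convention is the one that never fails a measurement for a
rounding artefact.

The normalised-power SD tolerance defaults to 0.02. Printed tolerance
summaries sometimes carry 0.2 for this quantity, but 0.2 would pass
traces with 20 % swings that the companion STAB ≥ 97 % bound rejects;
0.02 is the value consistent with the stability factor and with the
scale of max-normalised laser traces. Either value can be set in a
config file.

## Theoretical resolution and sampling

The three modality formulas (see README) give the diffraction-limited
FWHM of the PSF, not the Rayleigh maximum-to-first-minimum distance.
The point-scanning confocal form uses the excitation wavelength (the
scanned spot defines the resolution at a ≥1 A.U. pinhole); the
spinning-disk form uses emission and assumes the pinholes sample below
1 A.U., with no pinhole-size correction. NA > n is rejected — the
axial confocal term takes √(n² − NA²).

The Nyquist pixel bound is λex/(8·NA), relaxed by a factor 1.6 for a
1 A.U. pinhole. The integer-nanometre report truncates rather than
rounds: the criterion is an upper bound on the pixel size, so the
conservative integer report is the largest whole nanometre that still
satisfies it (43 nm for NA 1.4 at 488 nm, where the exact value is
43.57 nm). Sampling passes when the pixel (or z-step) is at most half
the resolution on that axis.

## PSF measurement

Beads are found as local maxima of the maximum-intensity z-projection
above a user prominence (default 10 % of the dynamic range in the CLI).
Exclusion rules *mark* candidates rather than dropping them: too close
to a border (closer than the ROI half-side), too close to another
candidate (closer than twice the ROI side), containing a saturated
voxel, or outside the optional central zone (a centred window of side
0.30·min(w, h), avoiding off-axis aberrations). Detection merges
plateau maxima within one ROI half-extent so a flat-topped (finite-size
or saturated) bead yields one candidate.

Each kept bead is measured on three single-voxel-wide profiles through
the brightest voxel of its ROI (ties broken toward the lowest (z, y, x)
index), fitted with a Gaussian-plus-constant by least squares,
initialised from the profile maximum, intensity centroid and second
moment. FWHM = 2√(2 ln 2)·σ ≈ 2.35·σ. R² = 1 − SS_res/SS_tot per
profile; the summary filters beads per axis at R² ≥ 0.95, so a bead
with a poor axial fit still informs the lateral statistics. The ROI
side is six expected FWHMs per axis — wide enough to contain >99 % of a
Gaussian bead plus local background; these sizes are this package's
convention, exposed as parameters.

SBR is the mean of the Otsu-segmented bead on the brightest plane over
the mean of a 1 µm annulus dilated around the segmentation. SNR is
√(max voxel rescaled to a 12-bit range); it is a unitless proxy, not a
photon count, and is not background-subtracted. Fewer than five
analysed beads triggers a warning, matching the usual protocol minimum.

## Field illumination

The image is blurred with a Gaussian (σ = 2 px) before anything else,
so isolated hot pixels and dust neither saturate the analysis nor set
the extrema; both I_min and I_max are read from the blurred image.
Saturation is likewise evaluated after the blur: only a solid saturated
region survives smoothing at the clip value. The normalised image is
binned into equal-width isointensity steps (10 by default); the
reference zone is the top band (90–100 %), and centering uses that
zone's geometric centre rather than the single max pixel (also
reported) because a flat-topped profile makes the max pixel location
arbitrary. For confocal inputs the full delivered frame is analysed;
zoom is not modelled.

## Coregistration

Per channel, a bead's centre is the intensity-weighted centroid of its
ROI after subtracting the median of the ROI border voxels (clipped at
zero) — the subtraction stops a constant background from pulling the
centroid toward the ROI centre. The ROI is the PSF-sized detection ROI
enlarged by the bead radius (default diameter 1 µm, the recommended
bead size for this measurement; 0.2 µm beads give very high
coefficients of variation), so the full bead is contained and the
centroid is unbiased.

The reference distance r_ref is the radius of the ellipsoid with
semi-axes (R_lat, R_lat, R_ax) — the *full* theoretical resolution
values — along the measured displacement direction:
`r_ref = 1/√((u_x²+u_y²)/R_lat² + u_z²/R_ax²)`. With this convention a
pure lateral shift equal to the lateral resolution scores a ratio of
exactly 1. Half-width semi-axes would double every ratio; the
convention is declared here and configurable in the analysis. The
resolution is computed from the shorter-wavelength channel of each pair
(the most stringent value). With C channels all C·(C−1)/2 pairs are
reported; a bead undetectable in one channel skips only the affected
pairs.

## Power stability

STAB_power = 100·[1 − (P_max − P_min)/(P_max + P_min)] and the SD of
the max-normalised trace are both scale invariant; the min–max form is
deliberately outlier-sensitive (a single dip is an instability). The
warm-up time has no canonical definition; the convention here is the
earliest time after which every sample stays within ±1 % (configurable)
of the mean over the final window. A trace whose end lies outside its
own settled band reports "not stabilised". Default cadences describe
the usual protocols (5 min @ 1 Hz short term, 2 h @ 30 s mid term,
monthly long term) but any strictly increasing time base is accepted.
Long-term monitoring is descriptive (per-session table), with no event
inference.

## Stage drift and repeatability

The tracker takes the 3D intensity centroid of the dominant bead per
frame, thresholding each background-subtracted frame at half its
maximum; lost frames are flagged and never interpolated.

τ_stab uses an anchor-frame criterion: the earliest frame k such that
*every* later frame stays within R_lat of the anchor in x and y and
within R_ax in z simultaneously. The last frame cannot anchor (there
would be nothing to confirm stability), so a track that drifts to the
end reports "not stabilised". This operationalises "drift below the
resolution of the system", which admits several readings
(displacement-from-start, step-wise); the anchor-frame reading is the
declared convention. V_b and V_a are the mean step speed ‖Δp‖/Δt in
nm/min before and after the anchor. Classification: τ < 45 min,
V < 15 nm/min is *standard*; τ ∈ [45, 120] min, V_b ≤ 100 and
V_a ≤ 50 nm/min *acceptable*; anything worse *critical*; each quantity
is classed against its own bounds and the overall class is the worst.

Repeatability is the sample SD (ddof = 1) of the x and y coordinates
over reference-position revisits, flagged against 0.2 µm. Reference
frames are selected by schedule (every even index of the 9-position
cycle by default), never inferred from image content. σ is invariant
under rigid translation of all visits.

## Camera dark noise

From T dark frames: the temporal-mean image gives the offset (its
global mean, ADU) and the DSNU (its spatial SD × gain, e⁻); the
temporal SD image × gain is the read-noise map, summarised by RMS and
median (vendors publish either; both are always reported). Sample SDs
(ddof = 1) are used throughout. At T = 100 the DSNU estimate is
contaminated by residual temporal noise (∝ σ/√T) and therefore exceeds
the large-T value — the generators reproduce this, and 100 frames is
the recommended compromise. Dark current is treated as zero at the
short (~10 ms) exposures of the protocol. VAR = 100·N_theor/N_exp
compares against the datasheet value; values above 100 mean the sensor
beats its spec. Hot pixels are counted (default threshold 5× the median
noise), never corrected.

## Synthetic generators

All generators are deterministic under a fixed seed and emit a truth
sidecar sufficient to compute expected metrics without rerunning them.
Beads are separable anisotropic Gaussians, optionally convolved
per-axis with a uniform-sphere line profile to model finite bead size
(normalised so `amplitude` is the rendered peak); noise is Poisson shot
noise plus Gaussian read noise, quantised to the bit depth. Vignettes
are isotropic Gaussian profiles parameterised by the corner-to-peak
intensity ratio, which is the uniformity ground truth (×100) for a
centred peak. Drift tracks are exponential relaxations with plateau
jitter; repeatability visits are i.i.d. Gaussian repositioning errors;
dark stacks are a fixed Gaussian offset map (plus optional sinusoidal
column pattern) with i.i.d. temporal noise.

Deliberately not modelled: vectorial/high-NA PSF structure, depth- and
field-dependent aberrations (coma, astigmatism, spherical), detector
fixed-pattern correlations beyond the column term, pinhole crosstalk,
and stage vibration spectra. Passing the synthetic suites therefore
demonstrates the *estimators* are correct on data satisfying the
models' assumptions; it does not certify behaviour on aberrated
real-world acquisitions, where the R²/SBR exclusion rules are the main
line of defence.

## Problem sizes in the test battery

The validation suites use sizes chosen to make the statistical claims
meaningful while keeping the battery quick to run routinely: 20 beads
at SBR ≥ 3 for PSF recovery (median lateral error < 5 %, axial < 8 %),
5 beads for noiseless oracle checks (< 0.5 % error), 256² fields for
illumination, 100-frame (vs 9000-frame for the DSNU comparison) dark
series at 32–64² pixels, and 91-frame overnight drift tracks.

## Known limitations

* Single-voxel line profiles are noise-sensitive by design (they mirror
  the established workflow); a 3D fit would be more efficient but would
  measure something slightly different on aberrated PSFs.
* The SNR proxy ignores background and gain, and is only comparable
  between acquisitions at the same normalisation.
* Warm-up detection is a windowed-band heuristic; oscillating sources
  can alias against the window length.
* Batch mode forwards one shared option set to every file, so it suits
  homogeneous acquisition series only.
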