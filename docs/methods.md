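# Methods

This note documents the models, estimators and numerical choices behind
`simqc`, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Data model

Raw 3D-SIM data are plane sequences over channel (C), pattern phase (P),
z-slice (Z), pattern angle (A) and time (T). The canonical ordering is
"CPZAT" with the *fastest-varying axis first*: channel changes quickest
along the sequence, then phase, then z, then angle, then time. This matches
the acquisition loop of OMX-style instruments (all phases of a z-slice
before a stage step, a full z-stack before a pattern rotation). The paper
ordering string itself does not fix the direction; fastest-first is this
package's convention and all sidecar metadata is interpreted that way.
Vendor exports are handled as "TIFF + declared source order": the `zeiss`
and `nikon` entries in `ORDER_PRESETS` are editable placeholders, since
export orderings vary with acquisition software settings.

Missing pixel sizes default to 0.08 μm (raw xy) and 0.125 μm (z) — typical
3D-SIM sampling — with a logged warning; they are always overridable.
Reconstructed stacks are 5-D float arrays at twice the raw lateral sampling
with a `full_range` flag recording that below-mode intensities were not
clipped upstream; the histogram-based checks warn loudly when it is unset.

## Raw-data checks

**Channel intensity profile.** All statistics derive from per-plane mean
intensities. TIV is the min-max range as a percent of the maximum over the
9-z window centred on the middle slice (±4 z-sections — the axial support a
reconstruction draws on per output slice); for Z < 9 the window truncates to
the whole stack with a log note. Bleaching decay is estimated per angle by
least squares on log(mean) versus within-angle acquisition index and
reported as the percent lost from the first to the last plane of that angle,
averaged over angles; the log-linear fit is this package's estimator choice
for an exponential decay. Flicker normalizes each (angle, phase) series by
its own window maximum. All four statistics are invariant under global
intensity scaling.

**Raw Fourier projection.** Each plane is multiplied by a separable edge
taper spanning 6% of the image width per side (the left half of a Gaussian
with σ = border/3, so the outermost pixel is attenuated to ~1%; the profile
shape is a package choice, only the border percentage is prescribed), 2-D
Fourier transformed, and log(amplitude²) max-projected over all
phases/z/angles per channel. The central disc (diameter 1/8 of the width)
is filled with the minimum before min-max rescaling, since the DC region
otherwise dominates the display range.

**Motion & illumination variation.** Requires exactly 3 angles. Per z-plane
the phase average of each angle is rescaled so its mean equals the grand
mean, removing uniform gain differences, and the three images are merged as
cyan/magenta/yellow via R = (M+Y)/2, G = (C+Y)/2, B = (C+M)/2. The merge is
rescaled by the *joint* min/max of the three output channels: independent
per-channel scaling would keep every channel in [0, 1] too, but it destroys
hue (a cyan-only feature would no longer satisfy R < G = B) and is
degenerate for constant channels, so joint scaling is used and each channel
still lies in [0, 1].

**Modulation contrast-to-noise.** Per voxel and angle, the raw counts are
Anscombe transformed (2·√(x + 3/8)) so Poisson noise becomes approximately
unit-variance Gaussian; the P phase images of the 2·zw+1 surrounding
z-sections (default zw = 1, truncated at the stack edges so the map keeps
the input dimensions) are stacked into one series of length
L_FT = P·(2·zw+1) and Fourier transformed along it. Because the pattern
phase cycles P times along this series, stripe order O lands exactly at
1-based plane L_FT·O/P + 1. The voxel value is
MCNR = √(A₁² + A₂²)/σ_N, where A_O is the order-O amplitude (second order
requires P ≥ 5) and σ_N is the standard deviation, over the xy-plane of the
same z-section, of the highest-frequency (Nyquist) component's magnitude —
taken to be noise dominated. The quadrature combination of order amplitudes
and the per-z-plane, whole-field scope of σ_N are package decisions; the
per-angle maps are combined by the arithmetic mean. Two consequences are
worth knowing:

- For noise-free synthetic input σ_N = 0 and the map is reported as +inf
  with a warning rather than failing.
- For *pure noise* input the order amplitudes are Rayleigh-distributed
  magnitudes whose mean is an O(1) multiple (~2–3×) of σ_N, so the MCNR of
  an unmodulated scenario sits near 3, not near 0. The statistic separates
  modulation *above* this baseline; the tests assert the baseline and the
  strict growth of the feature mean with true modulation depth.

The feature mean averages the map over its Otsu foreground (threshold from
the MCNR stack histogram), and the suggested Wiener constant is
w = 0.17/MCNR² — an empirical rule of thumb; the exponent is read as a
square, and both readings coincide at MCNR = 1.

## Reconstructed-data checks

**Histogram mode of float data** is computed as the centre of the tallest
bin of a 256-bin histogram spanning the data's min-max range. This binning
is used consistently (intensity histogram, auto-cutoffs, threshold utility);
its granularity is visible as a ≲ range/256 offset in mode-dependent
quantities.

**Intensity histogram.** Min*/Max* are means of the lowest/highest 0.05% of
voxels, floored at 100 pixels; MMR = (Max* − Mode)/|Min* − Mode|. A zero
denominator (lower tail equal to the mode) is the signature of clipped data
and yields a NaN sentinel with a warning. Tail pixel counts are reported so
truncation zeros or saturation skewing the tails can be spotted. MMR is
invariant under affine intensity shifts.

**Spherical aberration mismatch.** ZMV = std(per-slice minima)/mean(Otsu
foreground), population standard deviation. Requires Z ≥ 3 and a
non-constant stack (Otsu needs contrast). Invariant under positive global
scaling.

**Fourier plots.** Default pre-processing subtracts the stack mode and
clips negatives ("auto-cutoff": removes the lower half of the background
noise); a manual value or no cutoff can be chosen. Each z-slice's centred
amplitude spectrum is displayed as amplitude^0.2 inside a fixed [2, 40]
display window — the clamp is applied *post-gamma* as a display range, a
deliberate reading since the alternative (pre-gamma) was not determinable;
the underlying arrays are stored unclamped. Options: a 6% edge window, a
log-power display with per-slice mode-max rescaling, and a blurred 16-colour
rendering. Ring overlays are drawn at pixel radius X·pixel_xy/d for each
configured resolution d (defaults 0.2, 0.13, 0.1 μm, configurable — chosen
to bracket typical 3D-SIM lateral resolution). The radial profile is the
annulus mean of the raw (pre-gamma) amplitude of the central slice, one bin
per integer radius, ⌊X/2⌋ bins. The axial plot transforms the central xz
reslice after linear interpolation of z by pixel_z/pixel_xy to isotropic
voxels. No resolution number is extracted automatically: the inflection
point of the radial profile is for the user to read, as automated estimates
from a single profile are not robust.

**Modulation contrast map.** The MCNR map is upscaled to the reconstruction
grid by nearest-neighbour 2× (bicubic would smear the saturation mask),
mapped through a 256-entry purple→red→orange→yellow LUT with a display
ceiling of 24 (package choices; the original LUT is not published), and
multiplied by the reconstructed intensity normalized to its maximum. Voxels
saturated in *any* raw angle/phase (≥ 2^bit_depth − 1) are rendered pure
green scaled by intensity.

## Calibration tools

**Illumination pattern focus.** Slices are flicker-corrected by
ref-mean/slice-mean ratios; the stripe orientation is estimated from the
dominant off-centre FFT peak of the central slice (rather than asking the
user), the first-phase sub-stack is rotated so stripes run vertically,
resliced to xz and max-projected along the stripe direction, one panel per
angle on a shared scale. A focused axial modulation appears as a single
bright layer at the sample plane; an offset one produces staggered bright
segments. Note the projected stripe brightness goes as 1 + |M(z)|, so a
strongly offset cosine envelope can produce *two* bright layers (at M = ±1);
tests therefore assert displacement of the peak away from the sample layer
rather than its exact position.

**Illumination phase steps.** Per angle, each analysed slice's 2-D spectrum
is masked — a DC disc of radius X/16 and 3-pixel-wide bands along both
frequency axes (mask geometry is configurable; the values exclude DC
leakage and edge artifacts at the tested image sizes) — and the strongest
remaining peak on the mean power, restricted to the kx > 0 half-plane so
conjugate pairs resolve consistently, is taken as the first stripe order.
The complex argument at that fixed frequency pixel, read from every phase
image over the z-range around the plane of best focus (defaulting to the z
of maximum mean intensity, a package choice) and unwrapped, gives the phase
series; the sign convention makes the mean step positive. Reported: the
standard deviation of successive steps (stepping accuracy) and of residuals
about a uniform progression (offset stability). Because successive
differences of independently jittered phases have variance 2σ², the
recovered step-std estimates √2·σ of a per-step jitter σ.

## Utilities

Pseudo-widefield averages all phases and angles per slice — the sum of a
sinusoid over P equally spaced phases is exactly zero, so stripes cancel —
then upscales 2× bicubically (clipped at 0 to suppress undershoot) to match
the reconstructed grid; optional simple-ratio normalization equalizes plane
means first. The 16-bit conversion maps each channel linearly with
threshold→0 and channel-max→65535 ("filling the 16-bit range" read as a
per-channel linear map), rejecting degenerate ranges. The stack FFT windows
(6% default), zero-pads to the next power-of-two square, and returns
log-power, gamma-corrected or plain amplitude spectra.

## Batch runner and quality tiers

`run_all` executes the default suite: intensity profile,
motion/illumination variation and modulation contrast on raw data; the
intensity histogram and the lateral and axial Fourier plots on
reconstructions; and the modulation contrast map when both stacks are
present. The Fourier projection and the aberration-mismatch check are off
by default because they require specific sample characteristics (dense
high-SNR samples; flat bead layers). Metric tiers (ok/caution/concern)
derive only from the configurable thresholds in
`simqc.report.DEFAULT_THRESHOLDS`; the shipped values (e.g. TIV caution
above 30%, MCNR concern below 4) are starting points for a facility to
calibrate against its own instruments, not universal standards. QC is
advisory: a concern tier never changes the exit status.

## The synthetic generator

`generate_raw_sim` implements the image-formation model the checks assume:
an emission distribution (e.g. a Gaussian-blurred bead field from
`generate_bead_field`; the generator does not blur again — illumination
multiplies the already-blurred object, which is what makes the stripe
modulation depth exactly recoverable from phase extremes) times

  I(x, y, z) = 1 + m·M(z − δz)·cos(2πk(x·cosθ_a + y·sinθ_a) + φ_p)

with φ_p = 2πp/P plus optional per-step jitter, axial envelope
M(z') = cos(2πz'/T_z) (default period 1 μm; the true 3D pattern's axial
form is instrument-specific — a cosine reproduces the focused/defocused
phenomenology the pattern-focus tool looks for), per-angle gains,
(1−b)^index bleaching along the CPZAT acquisition sequence, per-plane
flicker, then Poisson noise, Gaussian read noise, clipping at zero and
optional saturation at 2^bit_depth − 1. Default stripe orientations are
(15°, 75°, 135°): offset from the camera axes, as on real instruments, and
necessary for the phase-step tool, which masks both frequency axes. With
all noise terms disabled every generated statistic matches its closed form
to ~1e-9 relative, which the oracle tests rely on.

`generate_recon_like` builds reconstruction-*shaped* stacks (zero-mode
background, constant-valued positive features, optional negative ringing
lobes and Gaussian noise) whose extreme-tail means are known exactly — the
oracle for the histogram check. `pseudo_reconstruct` is a first-order
demodulation proxy (multiply each phase image by the cosine of its known
pattern phase and sum; for an ideal acquisition the output per slice is
m·M(z−δz)·density): when the pattern focus is offset, M changes sign within
the sample's axial support and genuine negative lobes appear — the
phenomenology of reconstructing with a mismatched OTF. It performs no
frequency reassignment and is a test fixture, not a SIM reconstruction.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: OTF-based image formation (no frequency-
dependent attenuation, no out-of-focus blur structure), vectorial PSFs,
polarization-dependent excitation, depth-dependent aberrations, camera
fixed-pattern noise, and sample motion. The checks' *definitions* are
validated against closed forms and constructed oracles; their diagnostic
thresholds on real instruments must be calibrated empirically.

## Problem sizes and numerical notes

The validation suite runs the checks on 32–64 pixel lateral fields, 5–15
z-sections, 5 phases and 1–3 angles — large enough for every frequency-
domain structure the checks rely on (stripe orders at 8 cycles per field,
masked DC regions, annulus statistics) while keeping the full suite around
a few seconds. Phase-exactness tests use stripe frequencies that land on
integer FFT grid points; off-grid frequencies incur spectral leakage of
order 1e-4 radians in recovered phases, which is a property of any
FFT-peak phase estimator, not of the stepping statistics. Degenerate inputs
are defined rather than left to chance: empty rescale ranges return zeros,
σ_N = 0 yields +inf MCNR with a warning, MMR with a zero denominator is
NaN, and Otsu on constant stacks raises.
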