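# simqc

Quality control for three-dimensional structured illumination microscopy
(3D-SIM), as a scriptable Python library with a thin `simqc` command-line
interface.

3D-SIM doubles lateral and axial resolution by imaging a sample under a fine
striped illumination pattern at several phases (typically P = 5) and angles
(typically A = 3) per z-plane, then computationally recombining the
frequency-shifted information. The reconstruction is unforgiving: bleaching,
illumination imbalance, weak stripe contrast, saturation or a miscalibrated
pattern all turn into artifacts that are easy to mistake for structure.
`simqc` gives facility staff and SIM users objective, numerical checks on
both the raw acquisition and the reconstructed result, plus calibration
tools and common processing utilities — without requiring ImageJ or any
vendor software.

## What it computes

**Raw-data checks** (`simqc.rawchecks`)

- *Channel intensity profile* — per-plane mean intensities in acquisition
  order and summary statistics: total intensity variation
  `TIV = 100·(max−min)/max` over the central 9-z window (±4 z-sections, the
  range a reconstruction draws on per slice), per-angle bleaching decay from
  a log-linear fit, the maximum relative intensity difference between
  angles, and flicker.
- *Raw Fourier projection* — maximum projection of edge-windowed
  log-power spectra; first/second-order stripe spots per angle indicate a
  well-calibrated pattern.
- *Motion & illumination variation* — phase-averaged, intensity-normalized
  angle images merged as cyan/magenta/yellow; motion or uneven illumination
  shows up as colour.
- *Modulation contrast-to-noise (MCNR)* — per voxel, the Anscombe-transformed
  phase series of the ±1 neighbouring z-sections is Fourier-transformed along
  the phase axis (series length `L_FT = P·(2·zw+1)`; stripe order O lands at
  1-based plane `L_FT·O/P + 1`); the first/second-order amplitudes combined
  in quadrature are divided by the xy standard deviation of the
  noise-dominated highest-frequency component:
  `MCNR = sqrt(A₁² + A₂²)/σ_N`. The feature mean over the Otsu foreground
  gives a suggested Wiener filter constant `w = 0.17/MCNR²` for
  generalized-Wiener SIM reconstruction.

**Reconstructed-data checks** (`simqc.reconchecks`) — these need *untrimmed*
32-bit reconstructions (negatives not clipped):

- *Intensity histogram* — min-to-max ratio
  `MMR = (Max* − Mode)/|Min* − Mode|` of the extreme 0.05% tails (≥100
  pixels); low values mean reconstructed noise/ringing rivals the features.
- *Spherical aberration mismatch* — z-minimum variation
  `ZMV = std(slice minima)/mean(feature intensity)`, elevated when the OTF
  used for reconstruction does not match the sample.
- *Fourier plots* — gamma-0.2 lateral amplitude spectra with resolution-ring
  overlays (radius `X·pixel_xy/d` for resolution `d`), a radial profile of
  the central slice, and an axial spectrum from the isotropically resliced
  central xz-section.
- *Modulation contrast map* — the reconstruction recoloured by the raw MCNR
  through a heat LUT, with raw-saturated voxels flagged pure green.

**Calibration tools** (`simqc.calibration`) — illumination pattern focus
(orthogonal projection of the stripes per angle) and illumination phase steps
(realized pattern phase per step from the first-order Fourier peak, with
step- and offset-stability statistics).

**Utilities** (`simqc.utils`) — pseudo-widefield (phase/angle average +
2× bicubic), threshold & 16-bit conversion, and a windowed stack FFT.

**Synthetic acquisitions** (`simqc.synth`) — a raw-SIM simulator with known
ground truth (stripe frequency/orientation, modulation depth, axial pattern
focus, bleaching, flicker, per-angle gains, Poisson/read noise, saturation)
that backs the entire validation suite.

Raw data are plain multi-page TIFFs in the canonical CPZAT plane ordering
(channel fastest, then phase, z, angle, time), with a small JSON or
key=value sidecar declaring the dimension counts; `simqc.reorder_to_cpzat`
converts from any declared vendor ordering.

## Worked example

```python
import numpy as np
from simqc import (SimScenario, generate_bead_field, generate_raw_sim,
                   channel_intensity_profile, mcnr, pseudo_reconstruct,
                   reconstructed_intensity_histogram)

# a bead field on a fluorescent background, imaged with 80% stripe
# modulation, mild bleaching, Poisson noise and 2-count read noise
density = 50.0 + generate_bead_field((9, 64, 64), 150, seed=7)
scenario = SimScenario(shape=(9, 64, 64), m=0.8, axial_period_um=2.0,
                       bleach_per_plane=0.0005, poisson=True,
                       read_noise=2.0, seed=11)
raw, truth = generate_raw_sim(density, scenario)

cip = channel_intensity_profile(raw)
print(f"TIV              : {cip.tiv[0]:.1f} %")
print(f"decay (bleaching): {cip.decay[0]:.1f} %")
print(f"angle difference : {cip.max_angle_diff[0]:.2f} %")
print(f"flicker          : {cip.flicker[0]:.1f} %")

res = mcnr(raw)
print(f"feature-mean MCNR: {res.feature_mean_mcnr[0]:.2f}")
print(f"suggested Wiener : {res.wiener_suggestion[0]:.4f}")

recon = pseudo_reconstruct(raw, truth)   # demodulation stand-in for a recon
rih = reconstructed_intensity_histogram(recon)
print(f"MMR              : {rih.mmr[0]:.2f}")
```

prints

```
TIV              : 17.0 %
decay (bleaching): 1.8 %
angle difference : 4.43 %
flicker          : 12.3 %
feature-mean MCNR: 18.11
suggested Wiener : 0.0005
MMR              : 13.47
```

A TIV of 17% says the plane means inside the central 9-z window (135 raw
images here) swing by 17% of their maximum — mostly the mild bleaching and
the axial illumination envelope. The feature-mean MCNR of 18 indicates
strong stripe contrast over the noise (values below ~4 are cause for
concern), and the correspondingly small suggested Wiener constant means the
reconstruction filter can afford to be sharp. The MMR of 13 reflects a
clean, high-contrast pseudo-reconstruction whose features tower over the
ringing tail.

The same pipeline runs from the shell:

```
simqc simulate raw.tif --n-beads 150 --seed 7
simqc run --raw raw.tif --out qc/     # summary.csv, simqc.log, renderings
```

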