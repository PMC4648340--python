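"""System-calibration tools: illumination pattern focus and phase steps.

Both tools want raw data of a dense, high-contrast sample — typically a
single layer ("lawn") of sub-resolution fluorescent beads — where the
illumination stripes are directly visible.

* **Illumination pattern focus (IPF)** shows, per angle, an orthogonal (xz)
  maximum projection taken along the stripe direction after rotating the
  stripes vertical.  A well-focused axial modulation appears as a single
  bright layer; an axially offset pattern produces a staggered "zipper".
* **Illumination phase steps (IPS)** measures the realized pattern phase of
  every raw phase image from the argument of the first-order peak in its 2-D
  Fourier transform, and reports the accuracy of the phase stepping (standard
  deviation of successive steps) and the stability of the phase offset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .hyperstack import RawSIMStack, SimqcError

logger = logging.getLogger("simqc")


class StripeDetectionError(SimqcError):
    """No usable first-order stripe peak found in the Fourier spectrum."""


# ---------------------------------------------------------------------------
# Fourier-peak helpers
# ---------------------------------------------------------------------------

def _fourier_mask(shape, disc_radius=None, band_halfwidth=1):
    """Boolean mask (True = usable) for a centred 2-D spectrum.

    Blocks the high-intensity DC region (disc of radius ``X/16`` by default)
    and bands of half-width ``band_halfwidth`` pixels along both frequency
    axes, where sample structure and edge artifacts dominate.
    """
    ny, nx = shape
    cy, cx = ny // 2, nx // 2
    if disc_radius is None:
        disc_radius = nx / 16.0
    yy, xx = np.ogrid[0:ny, 0:nx]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 > disc_radius ** 2
    mask &= np.abs(yy - cy) > band_halfwidth
    mask &= np.abs(xx - cx) > band_halfwidth
    return mask


def _first_order_peak(power, mask):
    """Position of the strongest masked peak, restricted to the kx > 0
    half-plane so conjugate pairs resolve consistently."""
    ny, nx = power.shape
    cx = nx // 2
    half = np.zeros_like(mask)
    half[:, cx + 1:] = True
    usable = mask & half
    if not usable.any():
        raise StripeDetectionError("empty search region for stripe peak")
    masked = np.where(usable, power, -np.inf)
    iy, ix = np.unravel_index(int(np.argmax(masked)), power.shape)
    if not np.isfinite(masked[iy, ix]) or masked[iy, ix] <= 0:
        raise StripeDetectionError("no stripe peak above zero power")
    return iy, ix


def detect_stripe_orientation(image, disc_radius=None):
    """Stripe normal direction (radians) from the dominant off-centre FFT peak."""
    spec = np.fft.fftshift(np.fft.fft2(image))
    power = np.abs(spec) ** 2
    mask = _fourier_mask(image.shape, disc_radius=disc_radius,
                         band_halfwidth=0)
    ny, nx = image.shape
    iy, ix = _first_order_peak(power, mask)
    return float(np.arctan2(iy - ny // 2, ix - nx // 2))


# ---------------------------------------------------------------------------
# Illumination Pattern Focus
# ---------------------------------------------------------------------------

@dataclass
class IpfMontage:
    """Per-angle orthogonal projections of the illumination pattern."""

    panels: np.ndarray           # (A, Z, X) xz max-projections
    montage: np.ndarray          # panels stacked vertically, shared scale
    norm_factors: np.ndarray     # (A, Z) slice normalization factors applied
    stripe_angles_rad: np.ndarray   # (A,) estimated stripe normal directions

    def plot(self, path=None):
        import matplotlib.pyplot as plt

        a = self.panels.shape[0]
        fig, axes = plt.subplots(a, 1, figsize=(6, 1.2 * a), squeeze=False)
        vmax = self.panels.max() or 1.0
        for i in range(a):
            axes[i, 0].imshow(self.panels[i], cmap="gray", vmin=0, vmax=vmax,
                              aspect="auto")
            axes[i, 0].set_ylabel(f"angle {i + 1}", fontsize=8)
            axes[i, 0].set_xticks([])
            axes[i, 0].set_yticks([])
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path
        return fig


def illumination_pattern_focus(raw: RawSIMStack, channel=0, t=0,
                               phase=0) -> IpfMontage:
    """Orthogonal view of the axial illumination pattern per angle.

    For each angle the first-phase sub-stack is flicker-corrected by a simple
    ratio of mean slice intensities, rotated so the stripes run vertically
    (orientation estimated from the dominant first-order FFT peak of the
    central slice), resliced to an xz view and maximum-projected along the
    stripe direction.  The montage stacks one panel per angle on a shared
    intensity scale.
    """
    T, A, Z, P, C, Y, X = raw.data.shape
    panels = np.empty((A, Z, X))
    factors = np.empty((A, Z))
    angles = np.empty(A)
    for a in range(A):
        sub = raw.data[t, a, :, phase, channel].astype(np.float64)  # (Z, Y, X)
        slice_means = sub.mean(axis=(1, 2))
        ref = slice_means.mean()
        f = np.where(slice_means > 0, ref / np.maximum(slice_means, 1e-300), 1.0)
        factors[a] = f
        sub = sub * f[:, None, None]

        theta = detect_stripe_orientation(sub[Z // 2])
        angles[a] = theta
        # the detected peak is the stripe normal; rotating the image by
        # +theta brings the normal onto +x, i.e. stripes vertical
        deg = np.rad2deg(theta)
        rotated = ndimage.rotate(sub, deg, axes=(1, 2), reshape=False,
                                 order=1, mode="constant")
        panels[a] = rotated.max(axis=1)   # project along y (stripe direction)

    montage = panels.reshape(A * Z, X)
    return IpfMontage(panels=panels, montage=montage, norm_factors=factors,
                      stripe_angles_rad=angles)


# ---------------------------------------------------------------------------
# Illumination Phase Steps
# ---------------------------------------------------------------------------

@dataclass
class IpsResult:
    """Recovered illumination phases and phase-stepping statistics."""

    peak_positions: np.ndarray   # (A, 2) detected (ky, kx) frequency pixels
    phase_series: np.ndarray     # (A, n) unwrapped phases, radians
    mean_step: np.ndarray        # (A,) radians
    phase_step_std: np.ndarray   # (A,) std of successive steps
    phase_offset_std: np.ndarray  # (A,) std of offset residuals
    z_slices: tuple              # z-range analysed (half-open)

    def plot(self, path=None):
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3))
        for a in range(self.phase_series.shape[0]):
            ax.plot(self.phase_series[a], "o-", ms=3, label=f"angle {a + 1}")
        ax.set_xlabel("phase step (within z-range)")
        ax.set_ylabel("unwrapped phase (rad)")
        ax.legend(fontsize="small")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path
        return fig


def illumination_phase_steps(raw: RawSIMStack, z_range=1, channel=0, t=0,
                             disc_radius=None, band_halfwidth=1) -> IpsResult:
    """Recover the realized pattern phase of every raw step.

    Slices within ``z_range`` of the plane of best focus (the z of maximum
    mean intensity) are Fourier-transformed; the DC disc and both frequency
    axes are masked, and per angle the strongest remaining peak — the first
    stripe order — is located on the mean power over the analysed slices.
    The complex argument at that fixed frequency pixel, read from every
    phase image and unwrapped, gives the phase series.  The sign convention
    makes the mean step positive.  Reported statistics: the standard
    deviation of successive phase steps (stepping accuracy) and of the
    residuals about a uniform progression (offset stability).
    """
    T, A, Z, P, C, Y, X = raw.data.shape
    mean_per_z = raw.data[t, :, :, :, channel].mean(axis=(0, 2, 3, 4))
    z_best = int(np.argmax(mean_per_z))
    z0 = max(0, z_best - z_range)
    z1 = min(Z, z_best + z_range + 1)
    zs = range(z0, z1)
    n = len(zs) * P

    mask = _fourier_mask((Y, X), disc_radius=disc_radius,
                         band_halfwidth=band_halfwidth)
    peaks = np.empty((A, 2), dtype=int)
    series = np.empty((A, n))
    mean_step = np.empty(A)
    step_std = np.empty(A)
    offset_std = np.empty(A)
    for a in range(A):
        specs = np.empty((len(zs), P, Y, X), dtype=complex)
        for i, z in enumerate(zs):
            for p in range(P):
                specs[i, p] = np.fft.fftshift(
                    np.fft.fft2(raw.data[t, a, z, p, channel]))
        power = (np.abs(specs) ** 2).mean(axis=(0, 1))
        iy, ix = _first_order_peak(power, mask)
        peaks[a] = (iy, ix)
        raw_phases = np.angle(specs[:, :, iy, ix]).reshape(n)
        unwrapped = np.unwrap(raw_phases)
        steps = np.diff(unwrapped)
        if steps.size and steps.mean() < 0:
            unwrapped = -unwrapped          # positive-slope convention
            steps = -steps
        series[a] = unwrapped
        mean_step[a] = steps.mean() if steps.size else 0.0
        step_std[a] = steps.std() if steps.size else 0.0
        resid = unwrapped - (unwrapped[0]
                             + mean_step[a] * np.arange(n))
        offset_std[a] = resid.std()
    return IpsResult(peak_positions=peaks, phase_series=series,
                     mean_step=mean_step, phase_step_std=step_std,
                     phase_offset_std=offset_std, z_slices=(z0, z1))
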