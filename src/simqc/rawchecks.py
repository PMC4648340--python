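"""Raw-data quality checks.

Four checks diagnose problems in raw SIM acquisitions before reconstruction:

* **Channel intensity profile (CIP)** — per-plane mean intensities, total
  intensity variation (TIV) over the central 9-z window, per-angle bleaching
  decay, maximum intensity difference between angles, and flicker.
* **Raw Fourier projection (FPJ)** — a maximum-intensity projection of the
  per-plane log-power spectra; the first/second-order stripe frequencies of a
  well-calibrated system show up as pairs of spots per angle.
* **Motion & illumination variation (MIV)** — phase-averaged, intensity
  normalized angle images merged as cyan/magenta/yellow; motion or uneven
  illumination appears as coloured regions, stable data as grey.
* **Modulation contrast-to-noise (MCN)** — per-voxel modulation
  contrast-to-noise ratio (MCNR) from a 1-D discrete Fourier transform along
  the phase axis, a feature-mean MCNR over the Otsu foreground, and a
  suggested Wiener filter constant for the reconstruction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .hyperstack import DimensionError, RawSIMStack, SimqcError
from .utils import gaussian_edge_window

logger = logging.getLogger("simqc")

#: Empirical numerator of the Wiener-parameter suggestion w = 0.17 / MCNR^2.
WIENER_NUMERATOR = 0.17

#: Channel colours for profile plots: 1st red, 2nd green, 3rd blue, rest black.
CHANNEL_COLOURS = ("red", "green", "blue", "black")


def _range_pct(values):
    """min-max range as a percentage of the maximum; 0 for an all-zero series."""
    mx = float(np.max(values))
    if mx <= 0:
        return 0.0
    return 100.0 * (mx - float(np.min(values))) / mx


# ---------------------------------------------------------------------------
# Channel Intensity Profile
# ---------------------------------------------------------------------------

@dataclass
class CipStats:
    """Per-channel intensity statistics of a raw acquisition."""

    plane_means: np.ndarray        # (C, N) in acquisition order (p, z, a, t)
    tiv: np.ndarray                # (C,) total intensity variation, %
    decay_per_angle: np.ndarray    # (C, A) bleaching decay, %
    decay: np.ndarray              # (C,) mean decay over angles, %
    max_angle_diff: np.ndarray     # (C,) %
    flicker: np.ndarray            # (C,) %
    window: tuple[int, int]        # central z-window actually used (half-open)
    n_window_images: int = 0       # raw images per channel inside the window

    def plot(self, path=None, relative=False):
        """Plot per-plane mean intensity per channel (absolute or relative)."""
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 3))
        for c in range(self.plane_means.shape[0]):
            y = self.plane_means[c]
            if relative and y.max() > 0:
                y = y / y.max()
            colour = CHANNEL_COLOURS[min(c, len(CHANNEL_COLOURS) - 1)]
            ax.plot(y, color=colour, lw=0.8, label=f"channel {c}")
        ax.set_xlabel("plane (phase, z, angle, time order)")
        ax.set_ylabel("relative mean intensity" if relative else "mean intensity")
        ax.legend(fontsize="small")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path
        return fig


def channel_intensity_profile(raw: RawSIMStack) -> CipStats:
    """Per-plane intensity profile and summary statistics.

    TIV is the min-max range of plane means, as a percent of the maximum,
    over all phases/angles/times within a 9-z window about the central slice
    (the reconstruction of one slice draws on +-4 neighbouring z-sections, so
    intensity swings inside this window feed artifacts).  Decay per angle
    comes from a log-linear least-squares fit of plane mean versus
    within-angle acquisition index, reported as the percent lost from first
    to last plane of that angle.  The angle difference is the largest
    relative gap between per-angle window means, and flicker averages the
    min-max range of each (angle, phase) series over the window.
    """
    T, A, Z, P, C, Y, X = raw.data.shape
    means = raw.data.mean(axis=(5, 6))              # (T, A, Z, P, C)

    zc = Z // 2
    z0, z1 = max(0, zc - 4), min(Z, zc + 5)
    if Z < 9:
        logger.info("CIP: stack has %d z-sections; 9-z window truncated to "
                    "[%d, %d)", Z, z0, z1)

    # profile in acquisition order (phase, z, angle, time) per channel
    prof = np.transpose(means, (4, 0, 1, 2, 3)).reshape(C, T * A * Z * P)

    tiv = np.empty(C)
    decay_pa = np.empty((C, A))
    angle_diff = np.empty(C)
    flicker = np.empty(C)
    for c in range(C):
        win = means[:, :, z0:z1, :, c]
        tiv[c] = _range_pct(win)

        for a in range(A):
            # within-angle acquisition order: phase fastest, then z, then time
            series = means[:, a, :, :, c].reshape(T * Z * P)
            n = series.size
            if n < 2 or np.any(series <= 0):
                decay_pa[c, a] = 0.0
                continue
            slope = np.polyfit(np.arange(n), np.log(series), 1)[0]
            decay_pa[c, a] = 100.0 * (1.0 - np.exp(slope * (n - 1)))

        mu_a = win.mean(axis=(0, 2, 3))             # per-angle window means
        angle_diff[c] = _range_pct(mu_a) if mu_a.max() > 0 else 0.0

        ranges = [_range_pct(win[:, a, :, p])
                  for a in range(A) for p in range(P)]
        flicker[c] = float(np.mean(ranges))

    return CipStats(plane_means=prof, tiv=tiv, decay_per_angle=decay_pa,
                    decay=decay_pa.mean(axis=1), max_angle_diff=angle_diff,
                    flicker=flicker, window=(z0, z1),
                    n_window_images=T * A * (z1 - z0) * P)


# ---------------------------------------------------------------------------
# Raw Fourier Projection
# ---------------------------------------------------------------------------

def raw_fourier_projection(raw: RawSIMStack, window_pct=6.0) -> np.ndarray:
    """Maximum-intensity projection of per-plane log-power spectra.

    Each plane is edge-windowed (default 6% of the image width), Fourier
    transformed, and its log(amplitude^2) spectrum max-projected over all
    phases, z-sections and angles per channel.  The central disc (diameter
    1/8 of the image width) is filled with the minimum before a min-max
    rescale, so the display contrast favours the stripe-order spots.

    Returns an array of shape (C, S, S) scaled to [0, 1].
    """
    T, A, Z, P, C, Y, X = raw.data.shape
    size = max(Y, X)
    win = gaussian_edge_window((Y, X), window_pct)
    y0, x0 = (size - Y) // 2, (size - X) // 2
    out = np.empty((C, size, size))
    tiny = np.finfo(np.float64).tiny
    for c in range(C):
        proj = np.full((size, size), -np.inf)
        for t in range(T):
            for a in range(A):
                for z in range(Z):
                    for p in range(P):
                        padded = np.zeros((size, size))
                        padded[y0:y0 + Y, x0:x0 + X] = \
                            raw.data[t, a, z, p, c] * win
                        amp = np.abs(np.fft.fftshift(np.fft.fft2(padded)))
                        np.maximum(proj, np.log(amp ** 2 + tiny), out=proj)
        # fill central disc (diameter size/8) with the minimum amplitude value
        cy = cx = size // 2
        yy, xx = np.ogrid[0:size, 0:size]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= (size / 16.0) ** 2
        proj[disc] = proj.min()
        lo, hi = proj.min(), proj.max()
        out[c] = (proj - lo) / (hi - lo) if hi > lo else np.zeros_like(proj)
    return out


# ---------------------------------------------------------------------------
# Motion & Illumination Variation
# ---------------------------------------------------------------------------

@dataclass
class MivImage:
    """Phase-averaged, normalized per-angle images and their CMY merge."""

    angle_images: np.ndarray   # (C, Z, 3, Y, X) normalized angle images
    rgb: np.ndarray            # (C, Z, Y, X, 3) in [0, 1]


def motion_illumination_variation(raw: RawSIMStack, t=0) -> MivImage:
    """Merge phase-averaged angle images as cyan / magenta / yellow.

    The phases of each angle at each z-plane are averaged; each angle image
    is then scaled so its mean matches the grand mean of the three (removing
    uniform gain differences) and assigned cyan, magenta or yellow.  The
    additive CMY merge uses R = (M+Y)/2, G = (C+Y)/2, B = (C+M)/2, followed
    by a joint min-max rescale so every RGB channel lies in [0, 1] while
    colour ratios are preserved.  Requires exactly three angles.
    """
    if raw.n_angles != 3:
        raise DimensionError(
            f"motion/illumination check assumes 3 angles, got {raw.n_angles}")
    T, A, Z, P, C, Y, X = raw.data.shape
    phase_avg = raw.data[t].mean(axis=2)            # (A, Z, C, Y, X)

    angle_images = np.empty((C, Z, 3, Y, X))
    rgb = np.empty((C, Z, Y, X, 3))
    for c in range(C):
        for z in range(Z):
            imgs = phase_avg[:, z, c].astype(np.float64)      # (3, Y, X)
            mus = imgs.mean(axis=(1, 2))
            grand = mus.mean()
            scaled = np.stack([
                imgs[a] * (grand / mus[a]) if mus[a] > 0 else imgs[a]
                for a in range(3)])
            angle_images[c, z] = scaled
            cyan, magenta, yellow = scaled
            merged = np.stack([(magenta + yellow) / 2.0,
                               (cyan + yellow) / 2.0,
                               (cyan + magenta) / 2.0], axis=-1)
            lo, hi = merged.min(), merged.max()
            rgb[c, z] = (merged - lo) / (hi - lo) if hi > lo \
                else np.zeros_like(merged)
    return MivImage(angle_images=angle_images, rgb=rgb)


# ---------------------------------------------------------------------------
# Modulation Contrast-to-Noise
# ---------------------------------------------------------------------------

def anscombe(x):
    """Variance-stabilizing Anscombe transform, 2*sqrt(x + 3/8).

    Poisson-distributed input comes out with approximately unit Gaussian
    variance, so that downstream noise estimates are intensity independent.
    """
    x = np.asarray(x, dtype=np.float64)
    if np.any(x < 0):
        raise SimqcError("Anscombe transform requires non-negative input")
    return 2.0 * np.sqrt(x + 0.375)


def phase_order_indices(n_phases: int, zw: int = 1):
    """1-based plane indices of the stripe orders in the phase-axis DFT.

    Stacking the P phase images of the 2*zw+1 z-sections around a slice gives
    a series of length ``L_FT = P * (2*zw + 1)`` along which the pattern phase
    cycles P times; order O of the modulation therefore lands at 1-based DFT
    plane ``L_FT * O / P + 1``.
    """
    if n_phases < 3:
        raise DimensionError("need at least 3 phases")
    if zw < 0:
        raise DimensionError("z half-width must be >= 0")
    l_ft = n_phases * (2 * zw + 1)
    idx1 = l_ft // n_phases + 1
    idx2 = 2 * l_ft // n_phases + 1
    return l_ft, idx1, idx2


@dataclass
class McnrResult:
    """Per-voxel modulation contrast-to-noise map and summary values."""

    mcnr_map: np.ndarray            # (C, Z, Y, X), averaged over angles
    feature_mean_mcnr: np.ndarray   # (C,)
    wiener_suggestion: np.ndarray   # (C,) suggested filter constants
    z_window: int                   # zw half-width used
    order1_power: np.ndarray        # (C, Z, Y, X) |first-order| amplitude
    order2_power: np.ndarray        # (C, Z, Y, X) |second-order| amplitude
    noise_sigma: np.ndarray         # (C, Z) per-slice noise level


def _dft_component(series, k):
    """|sum_n series[n] * exp(-2*pi*i*k*n/L)| along axis 0."""
    l = series.shape[0]
    phase = np.exp(-2j * np.pi * k * np.arange(l) / l)
    return np.abs(np.tensordot(phase, series, axes=(0, 0)))


def mcnr(raw: RawSIMStack, zw: int = 1, t: int = 0) -> McnrResult:
    """Per-voxel modulation contrast-to-noise ratio.

    For every voxel the Anscombe-transformed phase images of the 2*zw+1
    neighbouring z-sections (window truncated at the stack edges) are stacked
    into one series per angle and Fourier-transformed along it.  The
    amplitudes of the first and second stripe orders are combined in
    quadrature and divided by the noise level — the standard deviation, over
    the xy-plane, of the highest-frequency component for the same z-plane —
    then averaged over angles.  The feature-mean MCNR averages the map over
    its Otsu foreground, and the suggested Wiener filter constant is
    ``0.17 / MCNR^2``.  Second order requires at least 5 phases; with fewer,
    only the first order contributes.
    """
    T, A, Z, P, C, Y, X = raw.data.shape
    if P < 3:
        raise DimensionError("phase-axis DFT needs at least 3 phases")
    use_second = P >= 5

    a1_map = np.zeros((C, Z, Y, X))
    a2_map = np.zeros((C, Z, Y, X))
    mcnr_map = np.zeros((C, Z, Y, X))
    noise = np.zeros((C, Z))
    warned = False
    for c in range(C):
        for z in range(Z):
            zlo, zhi = max(0, z - zw), min(Z, z + zw + 1)
            nz_win = zhi - zlo
            l_ft = P * nz_win
            k1, k2, kn = nz_win, 2 * nz_win, l_ft // 2
            acc = np.zeros((Y, X))
            a1_acc = np.zeros((Y, X))
            a2_acc = np.zeros((Y, X))
            sig_acc = 0.0
            for a in range(A):
                # (nz_win, P, Y, X) -> phase series, phase fastest within z
                block = raw.data[t, a, zlo:zhi, :, c]
                series = anscombe(block).reshape(l_ft, Y, X)
                amp1 = _dft_component(series, k1)
                amp2 = _dft_component(series, k2) if use_second else 0.0
                noise_amp = _dft_component(series, kn)
                sigma = float(noise_amp.std())
                sig_acc += sigma
                a1_acc += amp1
                a2_acc += amp2 if use_second else 0.0
                modulation = np.sqrt(amp1 ** 2 + amp2 ** 2) if use_second \
                    else amp1
                if sigma == 0.0:
                    if not warned:
                        warnings.warn(
                            "noise level is zero (noise-free input); "
                            "MCNR reported as +inf", stacklevel=2)
                        warned = True
                    acc += np.where(modulation > 0, np.inf, 0.0)
                else:
                    acc += modulation / sigma
            mcnr_map[c, z] = acc / A
            a1_map[c, z] = a1_acc / A
            a2_map[c, z] = a2_acc / A
            noise[c, z] = sig_acc / A

    feature_mean = np.empty(C)
    wiener = np.empty(C)
    for c in range(C):
        vals = mcnr_map[c]
        finite = vals[np.isfinite(vals)]
        if finite.size == 0 or np.all(finite == finite.flat[0]):
            feature_mean[c] = float(np.mean(vals))
        else:
            thr = threshold_otsu(finite)
            fg = vals >= thr
            feature_mean[c] = float(np.mean(vals[fg]))
        w = wiener_suggestion(feature_mean[c])
        wiener[c] = np.nan if w is None else w

    return McnrResult(mcnr_map=mcnr_map, feature_mean_mcnr=feature_mean,
                      wiener_suggestion=wiener, z_window=zw,
                      order1_power=a1_map, order2_power=a2_map,
                      noise_sigma=noise)


def wiener_suggestion(feature_mean_mcnr):
    """Suggested Wiener filter constant, w = 0.17 / MCNR^2.

    An empirical rule of thumb for generalized-Wiener SIM reconstruction:
    higher modulation contrast tolerates a smaller (sharper) filter constant.
    Returns ``None`` with a warning when the MCNR is not positive.
    """
    fm = float(feature_mean_mcnr)
    if not fm > 0:
        warnings.warn(f"Wiener suggestion undefined for MCNR = {fm}",
                      stacklevel=2)
        return None
    return WIENER_NUMERATOR / fm ** 2
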