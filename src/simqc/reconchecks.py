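"""Reconstructed-data quality checks.

* **Reconstructed intensity histogram (RIH)** — the proportion of intensities
  below the histogram mode (reconstructed noise and ringing) relative to the
  feature intensities above it, summarized as the min-to-max ratio
  MMR = (Max* - Mode) / |Min* - Mode| of the extreme-tail means.
* **Spherical aberration mismatch (SAM)** — per-slice minima against the mean
  Otsu-selected feature intensity; the z-minimum variation
  ZMV = std(slice minima) / mean(feature intensity) grows when the optical
  transfer function used for reconstruction does not match the sample.
* **Reconstructed Fourier plots** — gamma-corrected lateral amplitude spectra
  with resolution-ring annotations (FTL), a radial amplitude profile of the
  central slice (FTR), and an axial spectrum from the isotropically resliced
  central xz-section (FTO).
* **Modulation contrast map (MCM)** — the reconstruction recoloured by the
  raw-data MCNR through a heat look-up table, with raw-saturated voxels
  flagged pure green.

These checks require untrimmed 32-bit reconstructions covering the full
intensity range (negative ringing not clipped upstream).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .hyperstack import DimensionError, RawSIMStack, ReconStack, SimqcError
from .rawchecks import McnrResult
from .utils import gaussian_edge_window, histogram_mode

logger = logging.getLogger("simqc")

#: Default resolution-ring annotations for the lateral Fourier plot (um).
DEFAULT_RING_RESOLUTIONS = (0.2, 0.13, 0.1)

#: Display ceiling of the MCNR heat LUT.
MCNR_DISPLAY_MAX = 24.0


def _warn_if_trimmed(recon: ReconStack, check: str):
    if not recon.full_range:
        warnings.warn(
            f"{check}: reconstructed stack flagged as intensity-trimmed; "
            "the check needs the full (untrimmed) range — deactivate "
            "'discard negatives' / 'baseline cut' in the reconstruction "
            "software", stacklevel=3)


# ---------------------------------------------------------------------------
# Reconstructed Intensity Histogram
# ---------------------------------------------------------------------------

@dataclass
class RihStats:
    """Histogram statistics of a full-range reconstructed stack (per channel)."""

    mode: np.ndarray        # (C,) modal intensity (256-bin histogram)
    min_star: np.ndarray    # (C,) mean of the lowest tail
    max_star: np.ndarray    # (C,) mean of the highest tail
    n_min: np.ndarray       # (C,) pixels in the lower tail
    n_max: np.ndarray       # (C,) pixels in the upper tail
    mmr: np.ndarray         # (C,) min-to-max ratio; NaN when undefined
    hist_counts: np.ndarray     # (C, 256)
    hist_centers: np.ndarray    # (C, 256)

    def plot(self, path=None, channel=0):
        import matplotlib.pyplot as plt

        fig, (ax, axl) = plt.subplots(2, 1, figsize=(6, 4), sharex=True)
        x = self.hist_centers[channel]
        y = self.hist_counts[channel]
        ax.fill_between(x, y, color="black")
        ax.set_ylabel("count")
        axl.fill_between(x, np.log10(y + 1), color="grey")
        axl.set_ylabel("log10 count")
        axl.set_xlabel("intensity")
        for a in (ax, axl):
            a.axvline(self.mode[channel], color="red", lw=0.8)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path
        return fig


def reconstructed_intensity_histogram(recon: ReconStack,
                                      tail_fraction=0.0005,
                                      min_tail_pixels=100) -> RihStats:
    """Extreme-tail statistics and min-to-max ratio of a reconstruction.

    The mode is taken from a 256-bin histogram over the stack's min-max
    range.  Min* and Max* are the means of the lowest and highest
    ``tail_fraction`` of intensities (default 0.05%), subject to a minimum of
    ``min_tail_pixels`` pixels; the tail pixel counts are reported so that
    artifacts (zeros from truncation, saturated pixels) skewing the tails
    can be spotted.  MMR = (Max* - Mode) / |Min* - Mode| is NaN when the
    lower tail coincides with the mode — the signature of clipped data.
    """
    _warn_if_trimmed(recon, "reconstructed intensity histogram")
    C = recon.n_channels
    out = {k: np.empty(C) for k in
           ("mode", "min_star", "max_star", "n_min", "n_max", "mmr")}
    counts = np.empty((C, 256))
    centers = np.empty((C, 256))
    for c in range(C):
        vals = recon.data[:, c].ravel().astype(np.float64)
        n = vals.size
        mode = histogram_mode(vals)
        n_tail = int(min(max(round(tail_fraction * n), min_tail_pixels), n))
        part = np.partition(vals, (n_tail - 1, n - n_tail))
        min_star = float(part[:n_tail].mean())
        max_star = float(part[n - n_tail:].mean())
        denom = abs(min_star - mode)
        if denom == 0.0:
            warnings.warn("MMR undefined: lower tail equals the mode "
                          "(clipped-data signature)", stacklevel=2)
            mmr = np.nan
        else:
            mmr = (max_star - mode) / denom
        h, edges = np.histogram(vals, bins=256,
                                range=(vals.min(), vals.max())
                                if vals.min() < vals.max()
                                else (vals.min() - 0.5, vals.max() + 0.5))
        counts[c] = h
        centers[c] = 0.5 * (edges[:-1] + edges[1:])
        out["mode"][c] = mode
        out["min_star"][c] = min_star
        out["max_star"][c] = max_star
        out["n_min"][c] = out["n_max"][c] = n_tail
        out["mmr"][c] = mmr
    return RihStats(hist_counts=counts, hist_centers=centers, **out)


# ---------------------------------------------------------------------------
# Spherical Aberration Mismatch
# ---------------------------------------------------------------------------

@dataclass
class SamStats:
    """Per-slice minima, feature means and the z-minimum variation (ZMV)."""

    slice_minima: np.ndarray     # (C, Z)
    feature_means: np.ndarray    # (C, Z) per-slice Otsu-foreground means
    feature_mean: np.ndarray     # (C,) stack-wide feature mean
    zmv: np.ndarray              # (C,)

    def plot(self, path=None, channel=0):
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 3))
        ax.plot(self.slice_minima[channel], "o-", label="slice minimum")
        ax.plot(self.feature_means[channel], "s-", label="feature mean")
        ax.set_xlabel("z-section")
        ax.set_ylabel("intensity")
        ax.legend(fontsize="small")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path
        return fig


def spherical_aberration_mismatch(recon: ReconStack, t=0) -> SamStats:
    """Z-minimum variation of a reconstructed stack.

    ZMV = std(per-slice minima) / mean(Otsu-foreground intensity).  Deep
    slice-to-slice swings of the minimum relative to the features indicate
    reconstruction with a mismatched optical transfer function (usually
    spherical aberration, or an axially offset illumination pattern focus).
    """
    _warn_if_trimmed(recon, "spherical aberration mismatch")
    if recon.n_z < 3:
        raise DimensionError("need at least 3 z-sections for the ZMV")
    C, Z = recon.n_channels, recon.n_z
    minima = np.empty((C, Z))
    feat_z = np.empty((C, Z))
    feat = np.empty(C)
    zmv = np.empty(C)
    for c in range(C):
        vol = recon.data[t, c].astype(np.float64)
        minima[c] = vol.min(axis=(1, 2))
        if np.all(vol == vol.flat[0]):
            raise SimqcError("feature segmentation failed: constant stack")
        thr = threshold_otsu(vol)
        fg = vol >= thr
        if not fg.any():
            raise SimqcError("feature segmentation failed: empty foreground")
        feat[c] = float(vol[fg].mean())
        for z in range(Z):
            fz = fg[z]
            feat_z[c, z] = float(vol[z][fz].mean()) if fz.any() else np.nan
        zmv[c] = float(minima[c].std() / feat[c])
    return SamStats(slice_minima=minima, feature_means=feat_z,
                    feature_mean=feat, zmv=zmv)


# ---------------------------------------------------------------------------
# Reconstructed Fourier plots (FTL / FTO / FTR)
# ---------------------------------------------------------------------------

@dataclass
class FourierOptions:
    """Options record of one Fourier-plot run."""

    cutoff: object = "auto"       # "auto", None, or a manual value
    window: bool = False          # apply the 6% edge window
    log_power: bool = False       # log(amplitude^2) + mode-max rescale
    lut: bool = False             # blurred 16-colour display variant
    gamma: float = 0.2
    display_range: tuple = (2.0, 40.0)   # post-gamma display clamp
    ring_resolutions: tuple = DEFAULT_RING_RESOLUTIONS


@dataclass
class FourierPlotSet:
    """Lateral/axial spectra and the radial amplitude profile (per channel)."""

    ftl: np.ndarray              # (C, Z, Y, X) displayed lateral spectra
    fto: np.ndarray              # (C, Zi, X) displayed axial spectrum
    ftr: np.ndarray              # (C, n_bins) radial profile of the central z
    ring_radii_px: dict          # resolution (um) -> pixel radius, or {}
    options: FourierOptions = field(default_factory=FourierOptions)
    ftl_lut: np.ndarray | None = None   # (C, Z, Y, X, 3) when options.lut

    def plot(self, path=None, channel=0):
        import matplotlib.pyplot as plt

        zc = self.ftl.shape[1] // 2
        fig, axes = plt.subplots(1, 3, figsize=(11, 3.5))
        img = self.ftl[channel, zc]
        lo, hi = self.options.display_range
        axes[0].imshow(img, cmap="gray", vmin=lo, vmax=hi)
        cy, cx = img.shape[0] / 2, img.shape[1] / 2
        for res, r in self.ring_radii_px.items():
            circ = plt.Circle((cx, cy), r, fill=False, color="yellow", lw=0.8)
            axes[0].add_patch(circ)
            axes[0].annotate(f"{res} um", (cx, cy - r), color="yellow",
                             fontsize=7, ha="center")
        axes[0].set_title("lateral (central z)")
        axes[1].imshow(self.fto[channel], cmap="gray", vmin=lo, vmax=hi,
                       aspect="auto")
        axes[1].set_title("axial (resliced)")
        axes[2].plot(self.ftr[channel])
        axes[2].set_title("radial profile")
        axes[2].set_xlabel("frequency (pixels)")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return path
        return fig


def _radial_profile(img):
    """Annulus-mean of a centred 2-D spectrum; one bin per integer radius."""
    ny, nx = img.shape
    cy, cx = ny // 2, nx // 2
    yy, xx = np.ogrid[0:ny, 0:nx]
    r = np.sqrt((yy - cy) ** 2.0 + (xx - cx) ** 2.0).astype(int)
    n_bins = min(ny, nx) // 2
    flat_r = r.ravel()
    keep = flat_r < n_bins
    sums = np.bincount(flat_r[keep], weights=img.ravel()[keep],
                       minlength=n_bins)
    counts = np.bincount(flat_r[keep], minlength=n_bins)
    return sums / np.maximum(counts, 1)


def _lut16(img, lo, hi):
    """Blurred 16-colour rendering of a displayed spectrum."""
    import matplotlib.cm as cm

    sm = ndimage.gaussian_filter(img, 1.0)
    levels = np.clip((sm - lo) / (hi - lo), 0, 1 - 1e-9)
    idx = (levels * 16).astype(int)
    table = cm.get_cmap("jet", 16)(np.arange(16))[:, :3] \
        if hasattr(cm, "get_cmap") else None
    if table is None:
        import matplotlib.pyplot as plt
        table = plt.get_cmap("jet", 16)(np.arange(16))[:, :3]
    return table[idx]


def apply_cutoff(vol, cutoff="auto"):
    """Background cutoff used by the Fourier plots.

    ``"auto"`` subtracts the stack mode — the lower half of the background
    noise distribution — and clips negatives to zero; a numeric cutoff is
    subtracted the same way; ``None`` leaves the data untouched.
    """
    if cutoff is None:
        return np.asarray(vol, dtype=np.float64)
    thr = histogram_mode(vol) if cutoff == "auto" else float(cutoff)
    return np.clip(np.asarray(vol, dtype=np.float64) - thr, 0.0, None)


def fourier_plots(recon: ReconStack, options: FourierOptions | None = None,
                  t=0) -> FourierPlotSet:
    """Lateral, axial and radial Fourier views of a reconstruction.

    By default the stack mode (the lower half of the background noise) is
    subtracted and negatives are clipped before transforming, so that
    reconstructed noise does not dominate the spectrum; a manual cutoff or no
    cutoff can be requested instead.  Each z-slice gives a centred amplitude
    spectrum displayed as amplitude**gamma (gamma = 0.2) within a fixed
    display range, or as a mode-max rescaled log-power spectrum.  Resolution
    rings are annotated at pixel radius ``X * pixel_xy / d`` for each
    configured resolution ``d``; the radial profile is the annulus-mean
    amplitude of the central slice, and the axial spectrum transforms the
    central xz-section after interpolating z to isotropic voxels.
    """
    opts = options or FourierOptions()
    if opts.cutoff == "auto" and not recon.full_range:
        _warn_if_trimmed(recon, "Fourier plots (auto-cutoff)")
    C, Z = recon.n_channels, recon.n_z
    Y, X = recon.shape_yx
    tiny = np.finfo(np.float64).tiny

    win = gaussian_edge_window((Y, X), 6.0) if opts.window else 1.0

    ftl = np.empty((C, Z, Y, X))
    ftr = np.empty((C, min(Y, X) // 2))
    ftl_lut = np.empty((C, Z, Y, X, 3)) if opts.lut else None

    for c in range(C):
        vol = apply_cutoff(recon.data[t, c], opts.cutoff)
        for z in range(Z):
            amp = np.abs(np.fft.fftshift(np.fft.fft2(vol[z] * win)))
            if opts.log_power:
                lp = np.log(amp ** 2 + tiny)
                mode = histogram_mode(lp)
                hi = lp.max()
                ftl[c, z] = (lp - mode) / (hi - mode) if hi > mode \
                    else np.zeros_like(lp)
            else:
                ftl[c, z] = amp ** opts.gamma
            if opts.lut:
                lo, hi_d = (0.0, 1.0) if opts.log_power else opts.display_range
                ftl_lut[c, z] = _lut16(ftl[c, z], lo, hi_d)
            if z == Z // 2:
                ftr[c] = _radial_profile(amp)

    # axial spectrum: central xz reslice, z interpolated to isotropic voxels
    zoom_z = recon.pixel_z / recon.pixel_xy
    fto_list = []
    for c in range(C):
        vol = apply_cutoff(recon.data[t, c], opts.cutoff)
        xz = vol[:, Y // 2, :]
        iso = ndimage.zoom(xz, (zoom_z, 1.0), order=1) if zoom_z != 1.0 else xz
        winz = gaussian_edge_window(iso.shape, 6.0) if opts.window else 1.0
        amp = np.abs(np.fft.fftshift(np.fft.fft2(iso * winz)))
        if opts.log_power:
            lp = np.log(amp ** 2 + tiny)
            mode = histogram_mode(lp)
            hi = lp.max()
            fto_list.append((lp - mode) / (hi - mode) if hi > mode
                            else np.zeros_like(lp))
        else:
            fto_list.append(amp ** opts.gamma)
    fto = np.stack(fto_list)

    rings = {}
    if recon.pixel_xy and recon.pixel_xy > 0:
        for d in opts.ring_resolutions:
            rings[d] = X * recon.pixel_xy / d
    else:
        warnings.warn("pixel size unknown; resolution rings omitted",
                      stacklevel=2)
    return FourierPlotSet(ftl=ftl, fto=fto, ftr=ftr, ring_radii_px=rings,
                          options=opts, ftl_lut=ftl_lut)


# ---------------------------------------------------------------------------
# Modulation Contrast Map
# ---------------------------------------------------------------------------

def mcnr_lut(n=256):
    """Heat LUT for MCNR display: purple -> red -> orange -> yellow."""
    anchors = np.array([
        [0.5, 0.0, 0.5],   # purple (low contrast)
        [1.0, 0.0, 0.0],   # red
        [1.0, 0.5, 0.0],   # orange
        [1.0, 1.0, 0.0],   # yellow (high contrast)
    ])
    pos = np.linspace(0, 1, len(anchors))
    x = np.linspace(0, 1, n)
    return np.stack([np.interp(x, pos, anchors[:, i]) for i in range(3)],
                    axis=1)


@dataclass
class McmImage:
    """Reconstruction recoloured by raw-data modulation contrast."""

    rgb: np.ndarray              # (C, Z, Y, X, 3)
    saturation_mask: np.ndarray  # (C, Z, Y, X) bool, on the recon grid


def _upscale2_nearest(vol):
    """Nearest-neighbour 2x upscale of the last two axes (keeps masks crisp)."""
    return np.repeat(np.repeat(vol, 2, axis=-1), 2, axis=-2)


def modulation_contrast_map(recon: ReconStack, mcnr_result: McnrResult,
                            raw: RawSIMStack, t=0) -> McmImage:
    """Colour the reconstruction by the underlying raw modulation contrast.

    Each voxel takes the heat-LUT colour of its (2x nearest-neighbour
    upscaled) MCNR value, scaled by the reconstructed intensity normalized to
    the image maximum.  Voxels saturated in one or more raw angles/phases
    (at or above ``2**bit_depth - 1``) are rendered pure green: their stripe
    information is missing and local artifacts are likely.
    """
    C, Z = recon.n_channels, recon.n_z
    Y2, X2 = recon.shape_yx
    Yr, Xr = raw.shape_yx
    if (Y2, X2) != (2 * Yr, 2 * Xr) or mcnr_result.mcnr_map.shape[1] != Z:
        raise DimensionError(
            "reconstruction must be 2x the raw xy size with matching z "
            f"(recon {recon.data.shape}, raw yx {raw.shape_yx})")

    lut = mcnr_lut()
    level = raw.saturation_level
    # saturated in any angle or phase, per (z, c) voxel
    sat_raw = (raw.data[t] >= level).any(axis=(0, 2))   # (Z, C, Y, X)

    rgb = np.empty((C, Z, Y2, X2, 3))
    sat_out = np.empty((C, Z, Y2, X2), dtype=bool)
    for c in range(C):
        vol = recon.data[t, c].astype(np.float64)
        mx = vol.max()
        intensity = vol / mx if mx > 0 else np.zeros_like(vol)
        mmap = _upscale2_nearest(
            np.nan_to_num(mcnr_result.mcnr_map[c], posinf=MCNR_DISPLAY_MAX))
        idx = np.clip(mmap / MCNR_DISPLAY_MAX, 0.0, 1.0 - 1e-9)
        colour = lut[(idx * lut.shape[0]).astype(int)]
        sat = _upscale2_nearest(sat_raw[:, c])
        sat_out[c] = sat
        out = colour * intensity[..., None]
        out[sat] = np.array([0.0, 1.0, 0.0]) * intensity[sat, None]
        rgb[c] = out
    return McmImage(rgb=rgb, saturation_mask=sat_out)
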