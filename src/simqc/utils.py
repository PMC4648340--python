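"""Image-processing utilities: pseudo-widefield, 16-bit conversion, stack FFT.

Also hosts two helpers shared by several checks: the Gaussian edge-taper
window applied before Fourier transforms, and the binned histogram mode used
as the default background level of 32-bit reconstructed data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .hyperstack import RawSIMStack, ReconStack, SimqcError


class DegenerateRangeError(SimqcError):
    """Intensity range collapses (e.g. threshold equals the stack maximum)."""


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def gaussian_edge_window(shape, window_pct=6.0):
    """Separable edge-taper window: 1 in the interior, Gaussian roll-off over
    a border of ``window_pct`` percent of each axis length.

    The taper is the left half of a Gaussian whose sigma is a third of the
    border width, so the outermost pixel is attenuated to ~1%.  The profile
    shape is a package choice; only the border percentage is prescribed.
    """
    if not 0 <= window_pct <= 50:
        raise SimqcError(f"window_pct must be in [0, 50], got {window_pct}")
    if window_pct == 0:
        return np.ones(shape)

    def profile(n):
        border = max(window_pct / 100.0 * n, 1.0)
        sigma = border / 3.0
        d = np.minimum(np.arange(n), n - 1 - np.arange(n)) + 0.5
        w = np.ones(n)
        inside = d < border
        w[inside] = np.exp(-0.5 * ((border - d[inside]) / sigma) ** 2)
        return w

    ny, nx = shape
    return np.outer(profile(ny), profile(nx))


def histogram_mode(values, bins=256):
    """Mode of float data: center of the tallest bin of a ``bins``-bin
    histogram spanning the data's min-max range."""
    values = np.asarray(values).ravel()
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return lo
    counts, edges = np.histogram(values, bins=bins, range=(lo, hi))
    i = int(np.argmax(counts))
    return float(0.5 * (edges[i] + edges[i + 1]))


# ---------------------------------------------------------------------------
# pseudo-widefield
# ---------------------------------------------------------------------------

@dataclass
class PseudoWidefield:
    """Widefield-equivalent image assembled from raw SIM data."""

    image: np.ndarray          # (T, C, Z, 2Y, 2X)
    normalized: bool
    pixel_xy: float
    pixel_z: float


def pseudo_widefield(raw: RawSIMStack, normalize=False) -> PseudoWidefield:
    """Average all phases and angles per slice and upscale 2x (bicubic).

    Averaging over the P equally spaced phase steps cancels the stripe
    modulation exactly (the phase sum of a sinusoid over a full period is
    zero), leaving the equivalent widefield image; the 2x bicubic rescale
    matches the reconstructed pixel grid.  With ``normalize``, every raw
    plane is first scaled by reference-mean / plane-mean ("simple ratio"),
    correcting bleaching and flicker.
    """
    data = raw.data.astype(np.float64)
    T, A, Z, P, C, Y, X = data.shape
    if normalize:
        means = data.mean(axis=(5, 6), keepdims=True)
        ref = means.mean(axis=(1, 2, 3), keepdims=True)  # per (t, c)
        with np.errstate(invalid="ignore", divide="ignore"):
            factors = np.where(means > 0, ref / means, 1.0)
        data = data * factors
    avg = data.mean(axis=(1, 3))          # (T, Z, C, Y, X)
    avg = np.moveaxis(avg, 2, 1)          # (T, C, Z, Y, X)
    out = np.empty((T, C, Z, 2 * Y, 2 * X))
    for t in range(T):
        for c in range(C):
            for z in range(Z):
                out[t, c, z] = resize(avg[t, c, z], (2 * Y, 2 * X), order=3,
                                      anti_aliasing=False, preserve_range=True)
    np.clip(out, 0.0, None, out=out)      # suppress bicubic undershoot
    return PseudoWidefield(out, normalized=bool(normalize),
                           pixel_xy=raw.pixel_xy / 2, pixel_z=raw.pixel_z)


# ---------------------------------------------------------------------------
# threshold & 16-bit conversion
# ---------------------------------------------------------------------------

def threshold_16bit(recon: ReconStack, threshold="auto"):
    """Discard intensities below a threshold and fill the 16-bit range.

    ``threshold`` is ``"auto"`` (per-channel stack histogram mode) or a
    per-channel sequence / scalar.  Mapping per channel is linear:
    values <= threshold go to 0 and the channel maximum goes to 65535.
    """
    data = recon.data.astype(np.float64)
    C = recon.n_channels
    if threshold == "auto":
        thrs = [histogram_mode(data[:, c]) for c in range(C)]
    else:
        thrs = np.broadcast_to(np.atleast_1d(np.asarray(threshold, dtype=float)),
                               (C,))
    out = np.empty_like(data)
    for c in range(C):
        vol = data[:, c]
        thr = float(thrs[c])
        mx = float(vol.max())
        if mx <= thr:
            raise DegenerateRangeError(
                f"channel {c}: max intensity {mx} <= threshold {thr}")
        out[:, c] = np.round(65535.0 * np.clip(vol - thr, 0.0, mx - thr)
                             / (mx - thr))
    return out.astype(np.uint16)


# ---------------------------------------------------------------------------
# stack FFT
# ---------------------------------------------------------------------------

def _next_pow2(n):
    return 1 << (int(n) - 1).bit_length()


def stack_fft(stack, window_pct=6.0, scaling="log", gamma=0.2):
    """2-D Fourier transform of each slice of a stack.

    Each slice is edge-windowed (``window_pct`` of the image width), zero
    padded to the next power-of-two square, transformed, and the centred
    amplitude spectrum returned with the requested scaling: ``"log"`` for
    log(amplitude^2), ``"gamma"`` for amplitude**gamma, or ``None`` for the
    plain amplitude.
    """
    arr = stack.planes() if isinstance(stack, RawSIMStack) else np.asarray(stack)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[None]
    if arr.ndim != 3:
        raise SimqcError("stack_fft expects a 2-D image or (N, Y, X) stack")
    n, y, x = arr.shape
    size = _next_pow2(max(y, x))
    win = gaussian_edge_window((y, x), window_pct)
    out = np.empty((n, size, size))
    y0 = (size - y) // 2
    x0 = (size - x) // 2
    for i in range(n):
        padded = np.zeros((size, size))
        padded[y0:y0 + y, x0:x0 + x] = arr[i] * win
        amp = np.abs(np.fft.fftshift(np.fft.fft2(padded)))
        if scaling == "log":
            out[i] = np.log(amp ** 2 + np.finfo(np.float64).tiny)
        elif scaling == "gamma":
            out[i] = amp ** gamma
        elif scaling is None or scaling == "none":
            out[i] = amp
        else:
            raise SimqcError(f"unknown scaling {scaling!r}")
    return out[0] if squeeze else out
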