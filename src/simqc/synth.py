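"""Synthetic raw-SIM acquisitions with known ground truth.

The generator emulates the image-formation model the quality checks assume:
a fluorophore density (typically a field of sub-resolution beads blurred by a
Gaussian PSF) multiplied by a striped illumination pattern

    I_ap(x, y, z) = 1 + m * M(z - dz) * cos(2*pi*k*(x cos(theta_a) + y
                    sin(theta_a)) + phi_p),      phi_p = 2*pi*p / P,

with modulation depth ``m``, stripe frequency ``k`` (cycles / pixel), one
orientation per pattern angle, and an axial modulation envelope
``M(z') = cos(2*pi*z'/T_z)`` whose focus can be offset from the sample plane
by ``dz`` micrometres.  On top of the ideal signal the generator applies
per-angle gain imbalance, exponential photobleaching along the acquisition
sequence, per-plane intensity flicker, Poisson shot noise, Gaussian read
noise and optional saturation clipping at the camera's bit depth.

Every generator is reproducible under a fixed seed, and with all noise terms
disabled the produced statistics match their closed forms, which is what the
test-suite oracles rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .hyperstack import (DEFAULT_PIXEL_XY, DEFAULT_PIXEL_Z, DimensionError,
                         RawSIMStack, ReconStack)

__all__ = [
    "SimScenario", "GroundTruth", "generate_bead_field", "generate_raw_sim",
    "generate_recon_like", "pseudo_reconstruct",
]


@dataclass
class SimScenario:
    """Full parameterization of one synthetic acquisition.

    Defaults describe a small but realistic 3D-SIM acquisition: 5 phases,
    3 pattern angles 60 degrees apart (offset 15 degrees from the camera axes,
    as on real instruments), stripe frequency 1/8 cycles per pixel, strong
    modulation, an axial pattern period of 1 um and no imperfections.
    """

    shape: tuple[int, int, int] = (9, 64, 64)  # (Z, Y, X)
    n_phases: int = 5
    n_angles: int = 3
    n_channels: int = 1
    n_time: int = 1
    k: float = 0.125                      # stripe frequency, cycles/pixel
    angles_deg: tuple = (15.0, 75.0, 135.0)
    m: float = 0.8                        # modulation depth in [0, 1]
    axial_period_um: float = 1.0          # period of the axial envelope M
    focus_offset_um: float = 0.0          # dz: axial pattern-focus offset
    angle_gains: tuple | None = None      # s_a, one per angle (default all 1)
    bleach_per_plane: float = 0.0         # b: fraction lost per plane
    flicker: float = 0.0                  # f: per-plane multiplicative jitter
    phase_jitter_sigma: float = 0.0       # radians, per acquisition step
    poisson: bool = False
    read_noise: float = 0.0               # sigma_r, counts
    bit_depth: int = 16
    saturate: bool = False
    pixel_xy: float = DEFAULT_PIXEL_XY
    pixel_z: float = DEFAULT_PIXEL_Z
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.m <= 1.0:
            raise DimensionError(f"modulation depth must be in [0,1], got {self.m}")
        if not 0.0 <= self.bleach_per_plane < 1.0:
            raise DimensionError("bleach fraction must be in [0,1)")
        if self.angle_gains is None:
            self.angle_gains = tuple(1.0 for _ in range(self.n_angles))
        if len(self.angle_gains) != self.n_angles:
            raise DimensionError("need one gain per angle")
        if any(s <= 0 for s in self.angle_gains):
            raise DimensionError("angle gains must be positive")
        if len(self.angles_deg) < self.n_angles:
            raise DimensionError("need one orientation per angle")


@dataclass
class GroundTruth:
    """Exact quantities behind one generated acquisition (test oracle)."""

    m: float
    k: float
    angles_deg: tuple
    focus_offset_um: float
    phases: np.ndarray          # (A, Z, P) pattern phase per acquisition step
    plane_means: np.ndarray     # expected (noise-free) mean per CPZAT plane
    bead_positions: np.ndarray | None = None

    def __post_init__(self):
        # per z-block the phase steps must be strictly increasing modulo 2*pi
        steps = np.diff(self.phases, axis=-1) % (2 * np.pi)
        if np.any(steps <= 0):
            raise DimensionError("ground-truth phases not strictly increasing mod 2*pi")


# ---------------------------------------------------------------------------
# bead fields
# ---------------------------------------------------------------------------

def generate_bead_field(shape, n_beads, psf_sigma_xy=1.5, psf_sigma_z=1.0,
                        flux=1000.0, seed=None, z_layer=None,
                        return_positions=False):
    """A 3-D fluorophore density of Gaussian-blurred point sources.

    Parameters
    ----------
    shape : (Z, Y, X) volume size in voxels.
    n_beads : number of sub-resolution beads to scatter.
    psf_sigma_xy, psf_sigma_z : Gaussian PSF widths in voxels; must be > 0.
    flux : integrated intensity per bead.
    z_layer : if given, all beads sit in this single z-slice (a "bead lawn"
        used by the calibration tools); otherwise z is uniform random.
    return_positions : also return the (n_beads, 3) voxel positions.
    """
    if psf_sigma_xy <= 0 or psf_sigma_z <= 0:
        raise DimensionError("PSF sigmas must be positive")
    if n_beads < 0:
        raise DimensionError("n_beads must be >= 0")
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    vol = np.zeros(shape, dtype=np.float64)
    if n_beads == 0:
        pos = np.empty((0, 3), dtype=int)
    else:
        # keep margins so per-bead flux is not lost over the volume border
        margin = min(max(2, int(round(3 * psf_sigma_xy))), (min(ny, nx) - 1) // 2)
        ys = rng.integers(margin, ny - margin, size=n_beads)
        xs = rng.integers(margin, nx - margin, size=n_beads)
        if z_layer is not None:
            zs = np.full(n_beads, int(z_layer))
        else:
            zm = min(int(np.ceil(2 * psf_sigma_z)), (nz - 1) // 2)
            zs = rng.integers(zm, nz - zm, size=n_beads)
        pos = np.stack([zs, ys, xs], axis=1)
        np.add.at(vol, (zs, ys, xs), flux)
        vol = ndimage.gaussian_filter(
            vol, sigma=(psf_sigma_z, psf_sigma_xy, psf_sigma_xy),
            mode="constant")
    if return_positions:
        return vol, pos
    return vol


# ---------------------------------------------------------------------------
# raw acquisition
# ---------------------------------------------------------------------------

def _axial_envelope(z_index, z_center, scenario: SimScenario):
    zp = (z_index - z_center) * scenario.pixel_z - scenario.focus_offset_um
    return np.cos(2 * np.pi * zp / scenario.axial_period_um)


def generate_raw_sim(density, scenario: SimScenario, bead_positions=None):
    """Simulate a raw SIM acquisition of ``density`` under ``scenario``.

    ``density`` is the emission distribution (already PSF-blurred, e.g. the
    output of :func:`generate_bead_field`); each plane is the density slice
    multiplied by the striped illumination, scaled by the per-angle gain,
    bleaching and flicker factors, then degraded by Poisson and read noise
    and finally clipped (and optionally saturated at ``2**bit_depth - 1``).

    Returns the :class:`~simqc.hyperstack.RawSIMStack` (CPZAT ordering) and a
    :class:`GroundTruth` record of the exact pattern parameters.
    """
    density = np.asarray(density, dtype=np.float64)
    nz, ny, nx = scenario.shape
    if density.shape != (nz, ny, nx):
        raise DimensionError(
            f"density shape {density.shape} != scenario shape {scenario.shape}")
    P, A, C, T = (scenario.n_phases, scenario.n_angles,
                  scenario.n_channels, scenario.n_time)
    rng = np.random.default_rng(scenario.seed)

    phases = 2 * np.pi * np.arange(P) / P
    phases = np.broadcast_to(phases, (A, nz, P)).copy()
    if scenario.phase_jitter_sigma > 0:
        phases = phases + rng.normal(0.0, scenario.phase_jitter_sigma,
                                     size=phases.shape)

    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    z_center = (nz - 1) / 2.0

    data = np.empty((T, A, nz, P, C, ny, nx), dtype=np.float64)
    plane_means = np.empty(T * A * nz * P * C)
    b = scenario.bleach_per_plane
    for t in range(T):
        for a in range(A):
            th = np.deg2rad(scenario.angles_deg[a])
            carrier = 2 * np.pi * scenario.k * (xx * np.cos(th) + yy * np.sin(th))
            for z in range(nz):
                env = scenario.m * _axial_envelope(z, z_center, scenario)
                for p in range(P):
                    illum = 1.0 + env * np.cos(carrier + phases[a, z, p])
                    for c in range(C):
                        # acquisition index in the CPZAT plane sequence
                        idx = c + C * (p + P * (z + nz * (a + A * t)))
                        plane = scenario.angle_gains[a] * (1.0 - b) ** idx \
                            * density[z] * illum
                        if scenario.flicker > 0:
                            plane = plane * (1.0 + scenario.flicker * rng.normal())
                        np.clip(plane, 0.0, None, out=plane)
                        plane_means[idx] = plane.mean()
                        data[t, a, z, p, c] = plane

    if scenario.poisson:
        data = rng.poisson(data).astype(np.float64)
    if scenario.read_noise > 0:
        data = data + rng.normal(0.0, scenario.read_noise, size=data.shape)
        np.clip(data, 0.0, None, out=data)
    if scenario.saturate:
        np.clip(data, None, 2.0 ** scenario.bit_depth - 1, out=data)

    stack = RawSIMStack(data, bit_depth=scenario.bit_depth,
                        pixel_xy=scenario.pixel_xy, pixel_z=scenario.pixel_z)
    truth = GroundTruth(m=scenario.m, k=scenario.k,
                        angles_deg=tuple(scenario.angles_deg[:A]),
                        focus_offset_um=scenario.focus_offset_um,
                        phases=phases, plane_means=plane_means,
                        bead_positions=bead_positions)
    return stack, truth


# ---------------------------------------------------------------------------
# reconstruction-like stacks
# ---------------------------------------------------------------------------

def generate_recon_like(shape=(8, 64, 64), n_features=12, feature_value=100.0,
                        ringing_amp=0.0, noise_floor=0.0, feature_size=3,
                        seed=None, pixel_xy=DEFAULT_PIXEL_XY / 2,
                        pixel_z=DEFAULT_PIXEL_Z):
    """A synthetic full-range float stack shaped like reconstruction output.

    Constant-valued feature blocks at ``+feature_value`` sit on a zero-mode
    background; when ``ringing_amp`` > 0 each feature carries an adjacent
    negative lobe at ``-ringing_amp``, mimicking the ringing that real
    reconstructions put around bright features.  Optional zero-mean Gaussian
    background noise of width ``noise_floor`` is added.  Because the tails are
    constant-valued by construction, the extreme-tail means (and hence the
    min-to-max ratio) are known exactly, which the histogram-check tests use
    as their oracle.
    """
    if ringing_amp < 0:
        raise DimensionError("ringing_amp must be >= 0")
    nz, ny, nx = shape
    rng = np.random.default_rng(seed)
    vol = np.zeros(shape, dtype=np.float64)
    s = int(feature_size)
    for _ in range(int(n_features)):
        z = int(rng.integers(0, nz))
        y = int(rng.integers(0, max(ny - s, 1)))
        x = int(rng.integers(s, max(nx - 2 * s, s + 1)))
        vol[z, y:y + s, x:x + s] = feature_value
        if ringing_amp > 0:
            lobe = vol[z, y:y + s, x - s:x]
            lobe[lobe == 0] = -ringing_amp
    if noise_floor > 0:
        vol = vol + rng.normal(0.0, noise_floor, size=vol.shape)
    return ReconStack(vol[None, None].astype(np.float32),
                      pixel_xy=pixel_xy, pixel_z=pixel_z, full_range=True)


def pseudo_reconstruct(raw: RawSIMStack, truth: GroundTruth,
                       upscale=True) -> ReconStack:
    """First-order demodulation proxy for a SIM reconstruction.

    Multiplies each raw phase image by the cosine of its known pattern phase
    and sums over phases and angles, which isolates the modulated (first
    order) component: for an ideal acquisition the result per slice is
    proportional to ``m * M(z - dz) * density``.  When the axial pattern focus
    is offset, the envelope ``M`` changes sign within the sample's axial
    support and the output acquires genuine negative lobes — the same
    phenomenology as reconstructing with a mismatched optical transfer
    function.  This is a fixture for the reconstructed-data checks, not a SIM
    reconstruction (no frequency reassignment is performed).
    """
    T, A, Z, P, C = raw.data.shape[:5]
    ny, nx = raw.shape_yx
    yy, xx = np.mgrid[0:ny, 0:nx].astype(np.float64)
    out = np.zeros((T, C, Z, ny, nx))
    for a in range(A):
        th = np.deg2rad(truth.angles_deg[a])
        carrier = 2 * np.pi * truth.k * (xx * np.cos(th) + yy * np.sin(th))
        for z in range(Z):
            for p in range(P):
                ref = np.cos(carrier + truth.phases[a, z, p])
                for t in range(T):
                    for c in range(C):
                        out[t, c, z] += raw.data[t, a, z, p, c] * ref
    out *= 2.0 / (P * A)
    if upscale:
        from skimage.transform import resize

        up = np.empty((T, C, Z, 2 * ny, 2 * nx))
        for t in range(T):
            for c in range(C):
                for z in range(Z):
                    up[t, c, z] = resize(out[t, c, z], (2 * ny, 2 * nx),
                                         order=3, anti_aliasing=False,
                                         preserve_range=True)
        out = up
    return ReconStack(out.astype(np.float32), pixel_xy=raw.pixel_xy / 2,
                      pixel_z=raw.pixel_z, full_range=True)
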