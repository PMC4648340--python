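"""Data model and I/O for raw and reconstructed SIM stacks.

Raw 3D-SIM acquisitions are sequences of 2-D planes cycling over five
dimensions: channel (C), illumination-pattern phase (P), z-slice (Z),
illumination-pattern angle (A) and time (T).  All checks in this package
assume the canonical "CPZAT" ordering, in which the channel index varies
fastest along the plane sequence, then phase, then z, then angle, then time
(the acquisition loop of OMX-style instruments: all phases of one z-slice are
collected before moving the stage, and all z-slices of one angle before
rotating the pattern).

Vendors export other orderings; :func:`reorder_to_cpzat` permutes a plane
sequence from any declared ordering into CPZAT.  TIFF I/O uses plain
multi-page TIFF plus a small JSON/key=value sidecar carrying the dimension
counts and pixel sizes, so no proprietary container parsing is needed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

logger = logging.getLogger("simqc")

#: Default pixel sizes (micrometres) assumed when metadata is missing.
DEFAULT_PIXEL_XY = 0.08
DEFAULT_PIXEL_Z = 0.125

#: Editable order-string presets for common instrument exports.  "omx" is the
#: canonical ordering; the vendor entries are placeholders that users should
#: adjust to match their local export settings.
ORDER_PRESETS = {
    "omx": "CPZAT",
    "zeiss": "PZCAT",
    "nikon": "PCZAT",
}

_LETTERS = "CPZAT"


class SimqcError(Exception):
    """Base class for all errors raised by this package."""


class DimensionError(SimqcError):
    """Plane counts or array shapes inconsistent with the declared dimensions."""


class FormatError(SimqcError):
    """Malformed order string, sidecar or file."""


class CropError(SimqcError):
    """Crop region out of bounds or empty."""


@dataclass(frozen=True)
class DimensionOrder:
    """A permutation of the letters C, P, Z, A, T.

    The first letter names the axis that varies fastest along the plane
    sequence, the last the slowest.
    """

    order_string: str

    def __post_init__(self):
        s = self.order_string.upper()
        if sorted(s) != sorted(_LETTERS):
            raise FormatError(
                f"order string must be a permutation of {_LETTERS!r}, got {self.order_string!r}"
            )
        object.__setattr__(self, "order_string", s)

    def index(self, letter: str) -> int:
        return self.order_string.index(letter.upper())


CPZAT = DimensionOrder("CPZAT")


@dataclass(frozen=True)
class CropRegion:
    """Half-open pixel/slice bounds; xy bounds refer to the raw pixel grid."""

    x0: int
    x1: int
    y0: int
    y1: int
    z0: int
    z1: int

    def __post_init__(self):
        if self.x0 >= self.x1 or self.y0 >= self.y1 or self.z0 >= self.z1:
            raise CropError(f"empty crop region {self}")
        if min(self.x0, self.y0, self.z0) < 0:
            raise CropError(f"negative crop bound in {self}")

    def doubled_xy(self) -> "CropRegion":
        """The same region on the 2x-oversampled reconstructed grid."""
        return CropRegion(2 * self.x0, 2 * self.x1, 2 * self.y0, 2 * self.y1,
                          self.z0, self.z1)


def _check_pixel_sizes(pixel_xy, pixel_z):
    if pixel_xy is None:
        logger.warning("pixel_xy missing; defaulting to %.3f um", DEFAULT_PIXEL_XY)
        pixel_xy = DEFAULT_PIXEL_XY
    if pixel_z is None:
        logger.warning("pixel_z missing; defaulting to %.3f um", DEFAULT_PIXEL_Z)
        pixel_z = DEFAULT_PIXEL_Z
    return float(pixel_xy), float(pixel_z)


@dataclass
class RawSIMStack:
    """A raw SIM acquisition in canonical CPZAT ordering.

    ``data`` is indexed ``[t, a, z, p, c, y, x]``; flattening the first five
    axes yields the CPZAT plane sequence (channel fastest).
    """

    data: np.ndarray
    bit_depth: int = 16
    pixel_xy: float = DEFAULT_PIXEL_XY
    pixel_z: float = DEFAULT_PIXEL_Z

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 7:
            raise DimensionError(
                f"raw stack data must be 7-D (t,a,z,p,c,y,x), got shape {self.data.shape}"
            )
        if not 8 <= self.bit_depth <= 32:
            raise DimensionError(f"bit_depth must be in [8, 32], got {self.bit_depth}")
        if self.n_phases < 1:
            raise DimensionError("need at least 1 phase")
        if self.n_angles < 1:
            raise DimensionError("need at least 1 angle")
        if np.issubdtype(self.data.dtype, np.floating) and np.any(self.data < 0):
            raise DimensionError("raw intensities must be non-negative")

    # -- dimension accessors -------------------------------------------------
    @property
    def n_time(self) -> int:
        return self.data.shape[0]

    @property
    def n_angles(self) -> int:
        return self.data.shape[1]

    @property
    def n_z(self) -> int:
        return self.data.shape[2]

    @property
    def n_phases(self) -> int:
        return self.data.shape[3]

    @property
    def n_channels(self) -> int:
        return self.data.shape[4]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[5], self.data.shape[6]

    @property
    def saturation_level(self) -> float:
        return float(2 ** self.bit_depth - 1)

    def planes(self) -> np.ndarray:
        """The CPZAT plane sequence as an (N, Y, X) array (a view)."""
        t, a, z, p, c, y, x = self.data.shape
        return self.data.reshape(t * a * z * p * c, y, x)

    @classmethod
    def from_planes(cls, planes, *, n_channels, n_phases, n_z, n_angles, n_time,
                    **kwargs) -> "RawSIMStack":
        """Assemble a stack from a CPZAT-ordered plane sequence."""
        planes = np.asarray(planes)
        n = n_channels * n_phases * n_z * n_angles * n_time
        if planes.shape[0] != n:
            raise DimensionError(
                f"{planes.shape[0]} planes != C*P*Z*A*T = {n}"
            )
        data = planes.reshape(n_time, n_angles, n_z, n_phases, n_channels,
                              *planes.shape[1:])
        return cls(data, **kwargs)


@dataclass
class ReconStack:
    """A reconstructed SIM stack: 5-D float array indexed ``[t, c, z, y, x]``.

    ``full_range`` records that negative / below-mode intensities were *not*
    clipped upstream; the histogram-based checks are only meaningful then.
    ``pixel_xy`` is half the raw pixel size (the reconstruction doubles the
    lateral sampling).
    """

    data: np.ndarray
    pixel_xy: float = DEFAULT_PIXEL_XY / 2
    pixel_z: float = DEFAULT_PIXEL_Z
    full_range: bool = True

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32) \
            if self.data is not None else None
        if self.data.ndim != 5:
            raise DimensionError(
                f"recon stack data must be 5-D (t,c,z,y,x), got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise DimensionError("recon stack contains non-finite values")

    @property
    def n_time(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_z(self) -> int:
        return self.data.shape[2]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[3], self.data.shape[4]


# ---------------------------------------------------------------------------
# dimension reordering
# ---------------------------------------------------------------------------

def reorder_to_cpzat(planes, source_order, *, n_channels, n_phases, n_z,
                     n_angles, n_time, **stack_kwargs) -> RawSIMStack:
    """Permute a plane sequence from ``source_order`` into canonical CPZAT.

    ``source_order`` names the axis that varies fastest first.  The mapping is
    bijective: every input plane appears exactly once in the output.
    """
    if isinstance(source_order, str):
        source_order = DimensionOrder(source_order)
    planes = np.asarray(planes)
    sizes = {"C": n_channels, "P": n_phases, "Z": n_z, "A": n_angles, "T": n_time}
    n = int(np.prod(list(sizes.values())))
    if planes.shape[0] != n:
        raise DimensionError(f"{planes.shape[0]} planes != C*P*Z*A*T = {n}")

    # numpy reshape is slowest-axis first, so reverse the fastest-first string
    slow_to_fast = source_order.order_string[::-1]
    shaped = planes.reshape([sizes[let] for let in slow_to_fast]
                            + list(planes.shape[1:]))
    # target axis order, slowest first: T, A, Z, P, C
    perm = [slow_to_fast.index(let) for let in "TAZPC"]
    perm += list(range(5, shaped.ndim))
    data = np.ascontiguousarray(np.transpose(shaped, perm))
    return RawSIMStack(data, **stack_kwargs)


# ---------------------------------------------------------------------------
# TIFF I/O with sidecar metadata
# ---------------------------------------------------------------------------

_RAW_KEYS = ("order", "C", "P", "Z", "A", "T", "bit_depth", "pixel_xy", "pixel_z")


def _sidecar_path(path) -> Path:
    return Path(str(path) + ".json")


def _parse_sidecar(path) -> dict:
    """Parse a JSON or key=value sidecar file."""
    text = Path(path).read_text()
    try:
        return json.loads(text)
    except json.JSONDecodeError:
        meta = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, _, val = line.partition("=")
            meta[key.strip()] = val.strip()
        if not meta:
            raise FormatError(f"sidecar {path} is neither JSON nor key=value")
        return meta


def write_raw_tiff(path, stack: RawSIMStack) -> None:
    """Write a raw stack as a CPZAT-ordered multi-page TIFF + JSON sidecar."""
    tifffile.imwrite(path, stack.planes(), photometric='minisblack')
    meta = {
        "kind": "raw",
        "order": "CPZAT",
        "C": stack.n_channels, "P": stack.n_phases, "Z": stack.n_z,
        "A": stack.n_angles, "T": stack.n_time,
        "bit_depth": stack.bit_depth,
        "pixel_xy": stack.pixel_xy, "pixel_z": stack.pixel_z,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_raw_tiff(path, sidecar=None, **overrides) -> RawSIMStack:
    """Read a multi-page TIFF as a raw SIM stack.

    Dimension counts and the source ordering come from the sidecar (JSON or
    key=value) next to the file, or from keyword overrides (``order``, ``C``,
    ``P``, ``Z``, ``A``, ``T``, ``bit_depth``, ``pixel_xy``, ``pixel_z``).
    """
    planes = tifffile.imread(path)
    if planes.ndim == 2:
        planes = planes[None]
    meta: dict = {}
    sidecar = sidecar if sidecar is not None else (
        _sidecar_path(path) if _sidecar_path(path).exists() else None)
    if sidecar is not None:
        meta.update(_parse_sidecar(sidecar))
    meta.update({k: v for k, v in overrides.items() if v is not None})
    missing = [k for k in ("C", "P", "Z", "A", "T") if k not in meta]
    if missing:
        raise FormatError(f"missing dimension counts {missing} for {path}")
    order = str(meta.get("order", "CPZAT"))
    if order.lower() in ORDER_PRESETS:
        order = ORDER_PRESETS[order.lower()]
    pixel_xy, pixel_z = _check_pixel_sizes(meta.get("pixel_xy"), meta.get("pixel_z"))
    return reorder_to_cpzat(
        planes, order,
        n_channels=int(meta["C"]), n_phases=int(meta["P"]), n_z=int(meta["Z"]),
        n_angles=int(meta["A"]), n_time=int(meta["T"]),
        bit_depth=int(meta.get("bit_depth", 16)),
        pixel_xy=pixel_xy, pixel_z=pixel_z,
    )


def write_recon_tiff(path, stack: ReconStack) -> None:
    """Write a reconstructed stack as 32-bit float multi-page TIFF + sidecar."""
    t, c, z, y, x = stack.data.shape
    tifffile.imwrite(path, stack.data.reshape(t * c * z, y, x).astype(np.float32),
                     photometric='minisblack')
    meta = {
        "kind": "recon", "T": t, "C": c, "Z": z,
        "pixel_xy": stack.pixel_xy, "pixel_z": stack.pixel_z,
        "full_range": bool(stack.full_range),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_recon_tiff(path, sidecar=None, **overrides) -> ReconStack:
    """Read a 32-bit float multi-page TIFF as a reconstructed stack.

    Pages are ordered z fastest, then channel, then time.
    """
    planes = tifffile.imread(path)
    if planes.ndim == 2:
        planes = planes[None]
    meta: dict = {}
    sidecar = sidecar if sidecar is not None else (
        _sidecar_path(path) if _sidecar_path(path).exists() else None)
    if sidecar is not None:
        meta.update(_parse_sidecar(sidecar))
    meta.update({k: v for k, v in overrides.items() if v is not None})
    t = int(meta.get("T", 1))
    c = int(meta.get("C", 1))
    z = int(meta.get("Z", planes.shape[0] // max(t * c, 1)))
    if t * c * z != planes.shape[0]:
        raise DimensionError(
            f"page count {planes.shape[0]} != T*C*Z = {t * c * z}")
    pixel_xy, pixel_z = _check_pixel_sizes(meta.get("pixel_xy"), meta.get("pixel_z"))
    full_range = meta.get("full_range", True)
    if isinstance(full_range, str):
        full_range = full_range.lower() in ("1", "true", "yes")
    return ReconStack(planes.reshape(t, c, z, *planes.shape[1:]),
                      pixel_xy=pixel_xy, pixel_z=pixel_z,
                      full_range=bool(full_range))


# ---------------------------------------------------------------------------
# cropping
# ---------------------------------------------------------------------------

def crop(stack, region: CropRegion):
    """Crop a raw or reconstructed stack to ``region``.

    The region is expressed on the raw pixel grid; for a :class:`ReconStack`
    the xy bounds are doubled so that paired raw/recon crops cover the same
    physical boundaries.  All channel / phase / angle / time planes are kept.
    """
    if isinstance(stack, RawSIMStack):
        r = region
        y, x = stack.shape_yx
        if r.x1 > x or r.y1 > y or r.z1 > stack.n_z:
            raise CropError(f"region {r} outside raw stack bounds")
        data = stack.data[:, :, r.z0:r.z1, :, :, r.y0:r.y1, r.x0:r.x1]
        return RawSIMStack(data.copy(), bit_depth=stack.bit_depth,
                           pixel_xy=stack.pixel_xy, pixel_z=stack.pixel_z)
    if isinstance(stack, ReconStack):
        r = region.doubled_xy()
        y, x = stack.shape_yx
        if r.x1 > x or r.y1 > y or r.z1 > stack.n_z:
            raise CropError(f"region {r} outside recon stack bounds")
        data = stack.data[:, :, r.z0:r.z1, r.y0:r.y1, r.x0:r.x1]
        return ReconStack(data.copy(), pixel_xy=stack.pixel_xy,
                          pixel_z=stack.pixel_z, full_range=stack.full_range)
    raise TypeError(f"cannot crop object of type {type(stack)!r}")
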