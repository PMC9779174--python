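"""Visible-band (RGB) vegetation indices.

Nineteen per-pixel vegetation indices computed from 8-bit RGB imagery, used
to separate green vegetation from bare soil in nadir grassland scenes.
Chromatic-space indices operate on brightness-normalised coordinates
``r = R/(R+G+B)`` etc.; raw-space ratio indices operate on the 8-bit digital
numbers directly.  All arithmetic is double precision (squared-channel
indices such as MGRVI overflow 8-bit integer arithmetic).

Degenerate pixels (black pixels, zero ratio denominators) are mapped to
neutral values so that every index map is finite: a black pixel has
chromatic coordinates (1/3, 1/3, 1/3) and any ratio with a zero denominator
evaluates to 0 at that pixel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

logger = logging.getLogger("desertfvc")

__all__ = [
    "INDEX_REGISTRY",
    "INDEX_NAMES",
    "IndexDefinition",
    "UnknownIndexError",
    "validate_rgb_image",
    "normalize_chromatic",
    "compute_index",
    "compute_all_indices",
    "load_rgb_image",
    "save_index_map_csv",
    "save_index_map_tiff",
]

# CIVE coefficients as published (the green coefficient is kept as a named
# constant because the value in circulation differs between sources; it can
# be overridden per call via the ``constants`` mapping).
CIVE_RED = 0.441
CIVE_GREEN = 0.881
CIVE_BLUE = 0.385
CIVE_OFFSET = 18.78745

# Exponent of the red chromatic coordinate in the VEG index.
VEG_ALPHA = 0.667


class UnknownIndexError(KeyError):
    """Raised when an index name is not in the registry."""


def validate_rgb_image(image: np.ndarray) -> np.ndarray:
    """Check an H x W x 3 array of 8-bit intensities and return it.

    Accepts any integer dtype (or a float array holding exact integers) with
    values in [0, 255].
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 RGB array, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty image")
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(arr == np.round(arr)):
            raise ValueError("RGB intensities must be integers")
    elif not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"unsupported dtype {arr.dtype}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("RGB intensities must lie in [0, 255]")
    return arr


def normalize_chromatic(image: np.ndarray) -> np.ndarray:
    """Brightness-normalised chromatic coordinates.

    Returns an H x W x 3 float array ``(r, g, b)`` with
    ``r = R/(R+G+B)`` and so on; ``r + g + b == 1`` at every pixel.  Black
    pixels (R+G+B = 0) map to the neutral point (1/3, 1/3, 1/3).
    """
    arr = validate_rgb_image(image).astype(np.float64)
    total = arr.sum(axis=2, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        chrom = np.where(total > 0, arr / total, 1.0 / 3.0)
    return chrom


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with 0 wherever den == 0."""
    out = np.zeros(np.broadcast_shapes(num.shape, den.shape), dtype=np.float64)
    np.divide(num, den, out=out, where=den != 0)
    return out


# ---------------------------------------------------------------------------
# Index formulas.  Each takes (raw, chrom, constants) where raw and chrom are
# H x W x 3 float arrays, and returns an H x W float map.
# ---------------------------------------------------------------------------

def _gli(raw, chrom, c):
    R, G, B = raw[..., 0], raw[..., 1], raw[..., 2]
    return _safe_div(2 * G - R - B, 2 * G + R + B)


def _exg(raw, chrom, c):
    r, g, b = chrom[..., 0], chrom[..., 1], chrom[..., 2]
    return 2 * g - r - b


def _exr(raw, chrom, c):
    r, g = chrom[..., 0], chrom[..., 1]
    return 1.4 * r - g


def _exb(raw, chrom, c):
    g, b = chrom[..., 1], chrom[..., 2]
    return 1.4 * b - g


def _ngbdi(raw, chrom, c):
    G, B = raw[..., 1], raw[..., 2]
    return _safe_div(G - B, G + B)


def _ngrdi(raw, chrom, c):
    R, G = raw[..., 0], raw[..., 1]
    return _safe_div(G - R, G + R)


def _exgr(raw, chrom, c):
    return _exg(raw, chrom, c) - _exr(raw, chrom, c)


def _mgrvi(raw, chrom, c):
    R, G = raw[..., 0], raw[..., 1]
    return _safe_div(G**2 - R**2, G**2 + R**2)


def _rgbvi(raw, chrom, c):
    R, G, B = raw[..., 0], raw[..., 1], raw[..., 2]
    return _safe_div(G**2 - B * R, G**2 + B * R)


def _gbri(raw, chrom, c):
    g, b = chrom[..., 1], chrom[..., 2]
    return _safe_div(b, g)


def _rgri(raw, chrom, c):
    r, g = chrom[..., 0], chrom[..., 1]
    return _safe_div(r, g)


def _cive(raw, chrom, c):
    r, g, b = chrom[..., 0], chrom[..., 1], chrom[..., 2]
    return c["red"] * r - c["green"] * g + c["blue"] * b + c["offset"]


def _veg(raw, chrom, c):
    r, g, b = chrom[..., 0], chrom[..., 1], chrom[..., 2]
    alpha = c["alpha"]
    ok = (r > 0) & (b > 0)
    out = np.zeros(g.shape, dtype=np.float64)
    ra = np.ones_like(r)
    bb = np.ones_like(b)
    np.power(r, alpha, out=ra, where=ok)
    np.power(b, 1.0 - alpha, out=bb, where=ok)
    np.divide(g, ra * bb, out=out, where=ok)
    return out


def _devi(raw, chrom, c):
    # Printed as G/3G + R/3G + B/3G, i.e. (G+R+B)/(3G); 0 where G == 0.
    R, G, B = raw[..., 0], raw[..., 1], raw[..., 2]
    return _safe_div(R + G + B, 3 * G)


def _egrbdi(raw, chrom, c):
    R, G, B = raw[..., 0], raw[..., 1], raw[..., 2]
    gg = (2 * G) ** 2
    return _safe_div(gg - B * R, gg + B * R)


def _vmsavi(raw, chrom, c):
    # MSAVI-structured form on chromatic coordinates, radicand clamped at 0.
    r, g, b = chrom[..., 0], chrom[..., 1], chrom[..., 2]
    exg = 2 * g - r - b
    radicand = np.maximum((2 * g + 1) ** 2 - 8 * exg, 0.0)
    return (2 * g + 1 - np.sqrt(radicand)) / 2


def _g(raw, chrom, c):
    return chrom[..., 1].copy()


def _com(raw, chrom, c):
    return (
        0.25 * _exg(raw, chrom, c)
        + 0.3 * _exgr(raw, chrom, c)
        + 0.33 * _cive(raw, chrom, c)
        + 0.12 * _veg(raw, chrom, c)
    )


def _com2(raw, chrom, c):
    return (
        0.36 * _exg(raw, chrom, c)
        + 0.47 * _cive(raw, chrom, c)
        + 0.17 * _veg(raw, chrom, c)
    )


@dataclass(frozen=True)
class IndexDefinition:
    """One vegetation index: name, input space, formula, fixed constants."""

    name: str
    full_name: str
    input_space: str  # "raw" or "chromatic"
    func: Callable[[np.ndarray, np.ndarray, Mapping[str, float]], np.ndarray]
    constants: Mapping[str, float] = field(default_factory=dict)


_CIVE_CONSTANTS = {
    "red": CIVE_RED,
    "green": CIVE_GREEN,
    "blue": CIVE_BLUE,
    "offset": CIVE_OFFSET,
}
_VEG_CONSTANTS = {"alpha": VEG_ALPHA}
_COM_CONSTANTS = {**_CIVE_CONSTANTS, **_VEG_CONSTANTS}

#: Registry of the 19 indices, in canonical order.
INDEX_REGISTRY: dict[str, IndexDefinition] = {
    d.name: d
    for d in [
        IndexDefinition("GLI", "Green Leaf Index", "raw", _gli),
        IndexDefinition("ExG", "Excess Green", "chromatic", _exg),
        IndexDefinition("ExR", "Excess Red", "chromatic", _exr),
        IndexDefinition("ExB", "Excess Blue", "chromatic", _exb),
        IndexDefinition("NGBDI", "Normalized Green Blue Difference Index", "raw", _ngbdi),
        IndexDefinition("NGRDI", "Normalized Green Red Difference Index", "raw", _ngrdi),
        IndexDefinition("ExGR", "Excess Green minus Excess Red", "chromatic", _exgr),
        IndexDefinition("MGRVI", "Modified Green Red Vegetation Index", "raw", _mgrvi),
        IndexDefinition("RGBVI", "Red Green Blue Vegetation Index", "raw", _rgbvi),
        IndexDefinition("GBRI", "Green Blue Ratio Index", "chromatic", _gbri),
        IndexDefinition("RGRI", "Red Green Ratio Index", "chromatic", _rgri),
        IndexDefinition("CIVE", "Color Index of Vegetation", "chromatic", _cive, _CIVE_CONSTANTS),
        IndexDefinition("VEG", "Vegetative", "chromatic", _veg, _VEG_CONSTANTS),
        IndexDefinition("DEVI", "Difference Excess Vegetation Index", "raw", _devi),
        IndexDefinition("EGRBDI", "Excess Green Red Blue Difference Index", "raw", _egrbdi),
        IndexDefinition("V-MSAVI", "Visible-band Modified Soil Adjusted Vegetation Index", "chromatic", _vmsavi),
        IndexDefinition("g", "Green Chromatic Coordinate", "chromatic", _g),
        IndexDefinition("COM", "Combined", "chromatic", _com, _COM_CONSTANTS),
        IndexDefinition("COM2", "Combined 2", "chromatic", _com2, _COM_CONSTANTS),
    ]
}

INDEX_NAMES: tuple[str, ...] = tuple(INDEX_REGISTRY)
assert len(INDEX_NAMES) == 19


def compute_index(
    image: np.ndarray,
    name: str,
    *,
    chromatic: np.ndarray | None = None,
    constants: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Evaluate one vegetation index over an RGB image.

    Parameters
    ----------
    image : H x W x 3 array of 8-bit intensities.
    name : registry name of the index (case-sensitive, e.g. ``"ExG"``).
    chromatic : precomputed output of :func:`normalize_chromatic` (optional,
        avoids recomputation when evaluating many indices).
    constants : overrides for the index's fixed coefficients, merged over
        the registry defaults (e.g. ``{"green": 0.811}`` for CIVE).

    Returns
    -------
    H x W float64 map; every value finite.
    """
    if name not in INDEX_REGISTRY:
        raise UnknownIndexError(
            f"unknown vegetation index {name!r}; valid names: {', '.join(INDEX_NAMES)}"
        )
    raw = validate_rgb_image(image).astype(np.float64)
    if chromatic is None:
        chromatic = normalize_chromatic(image)
    definition = INDEX_REGISTRY[name]
    consts = dict(definition.constants)
    if constants:
        consts.update(constants)
    values = definition.func(raw, chromatic, consts)
    if not np.all(np.isfinite(values)):
        raise AssertionError(f"index {name} produced non-finite values")
    return values


def compute_all_indices(
    image: np.ndarray,
    names: tuple[str, ...] | list[str] | None = None,
) -> dict[str, np.ndarray]:
    """All (or a subset of) index maps, keyed by name in registry order."""
    if names is None:
        names = INDEX_NAMES
    else:
        unknown = set(names) - set(INDEX_NAMES)
        if unknown:
            raise UnknownIndexError(
                f"unknown vegetation indices {sorted(unknown)}; "
                f"valid names: {', '.join(INDEX_NAMES)}"
            )
        names = tuple(n for n in INDEX_NAMES if n in set(names))
    chromatic = normalize_chromatic(image)
    return {n: compute_index(image, n, chromatic=chromatic) for n in names}


# ---------------------------------------------------------------------------
# I/O helpers
# ---------------------------------------------------------------------------

def load_rgb_image(path) -> np.ndarray:
    """Read a PNG/JPEG/TIFF image as 8-bit RGB; alpha channels are dropped."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        raise ValueError(f"{path}: single-band image, expected RGB")
    if arr.shape[2] == 4:
        logger.warning("%s: alpha channel ignored", path)
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: expected 8-bit image, got {arr.dtype}")
    return validate_rgb_image(arr)


def save_index_map_csv(values: np.ndarray, path) -> None:
    """Write a per-pixel index map as CSV (intended for small images)."""
    np.savetxt(path, np.asarray(values, dtype=np.float64), delimiter=",", fmt="%.9g")


def save_index_map_tiff(values: np.ndarray, path) -> None:
    """Write an index map as a single-band float32 TIFF."""
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(values, dtype=np.float32), extension=".tiff")
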