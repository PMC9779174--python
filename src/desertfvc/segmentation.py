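"""Otsu binarization of vegetation-index maps.

An index map is split into vegetation / non-vegetation at the histogram
threshold that maximizes the between-class variance

    sigma_B^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2

over an ``n_bins`` histogram spanning [min, max] of the map.  Which side of
the threshold is vegetation is not fixed by the index formula (some indices
are vegetation-high, e.g. ExG; others vegetation-low, e.g. RGRI or CIVE),
so polarity is resolved from the image itself: the class whose pixels have
the higher mean green chromatic coordinate is labelled vegetation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateInputError",
    "ThresholdResult",
    "otsu_threshold",
    "resolve_polarity",
    "binarize",
    "save_mask_png",
    "load_mask_png",
]


class DegenerateInputError(ValueError):
    """Input admits no two-class split (e.g. a constant index map)."""


@dataclass(frozen=True)
class ThresholdResult:
    """Outcome of Otsu thresholding one index map."""

    threshold: float
    between_class_variance: float
    histogram_bins: int
    polarity: str | None = None  # "above" or "below" = vegetation side

    def with_polarity(self, polarity: str) -> "ThresholdResult":
        return ThresholdResult(
            self.threshold, self.between_class_variance, self.histogram_bins, polarity
        )


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> ThresholdResult:
    """Maximum between-class-variance threshold of a scalar sample.

    The histogram has ``n_bins`` equal bins over [min, max]; candidate
    thresholds are the interior bin edges.  Ties in sigma_B^2 are broken
    toward the smallest threshold.

    Raises
    ------
    DegenerateInputError
        If the sample holds fewer than 2 distinct values.
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    if vals.size == 0 or not np.all(np.isfinite(vals)):
        raise ValueError("values must be a non-empty finite array")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        raise DegenerateInputError(
            "degenerate: no threshold separates one value"
        )
    counts, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    n = counts.sum()

    # Cumulative class weights and means for splits after bin i (i = 0..n_bins-2).
    w0 = np.cumsum(counts)[:-1]
    w1 = n - w0
    csum = np.cumsum(counts * centers)
    total = csum[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = np.where(w0 > 0, csum[:-1] / w0, 0.0)
        mu1 = np.where(w1 > 0, (total - csum[:-1]) / w1, 0.0)
    sigma_b = (w0 / n) * (w1 / n) * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = 0.0

    best = int(np.argmax(sigma_b))  # argmax returns the first (smallest t) maximum
    return ThresholdResult(
        threshold=float(edges[best + 1]),
        between_class_variance=float(sigma_b[best]),
        histogram_bins=int(n_bins),
    )


def resolve_polarity(
    index_map: np.ndarray,
    threshold: float,
    chromatic: np.ndarray,
    override: str | None = None,
) -> str:
    """Decide which side of the threshold is vegetation.

    The class with the higher mean green chromatic coordinate is labelled
    vegetation; on an exact tie the above-threshold class is chosen.  A
    manual ``override`` ("above"/"below") bypasses the data-driven rule.
    """
    if override is not None:
        if override not in ("above", "below"):
            raise ValueError("polarity override must be 'above' or 'below'")
        return override
    vals = np.asarray(index_map, dtype=np.float64)
    g = np.asarray(chromatic)[..., 1]
    if vals.shape != g.shape:
        raise ValueError("index map and chromatic image shapes differ")
    above = vals >= threshold
    if not above.any() or above.all():
        raise DegenerateInputError("polarity undefined: one class is empty")
    return "above" if g[above].mean() >= g[~above].mean() else "below"


def binarize(
    index_map: np.ndarray,
    chromatic: np.ndarray,
    n_bins: int = 256,
    polarity_override: str | None = None,
) -> tuple[np.ndarray, ThresholdResult]:
    """Otsu-threshold an index map into a binary vegetation mask.

    Returns ``(mask, result)`` where ``mask`` is uint8 with 1 = vegetation
    and ``result`` records threshold, sigma_B^2 and resolved polarity.
    """
    vals = np.asarray(index_map, dtype=np.float64)
    if not np.all(np.isfinite(vals)):
        raise ValueError("index map must be finite")
    result = otsu_threshold(vals, n_bins=n_bins)
    polarity = resolve_polarity(
        vals, result.threshold, chromatic, override=polarity_override
    )
    above = vals >= result.threshold
    mask = above if polarity == "above" else ~above
    return mask.astype(np.uint8), result.with_polarity(polarity)


def save_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG with values {0, 255}."""
    import imageio.v3 as iio

    arr = np.asarray(mask)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask must be binary (0/1)")
    iio.imwrite(path, (arr * 255).astype(np.uint8), extension=".png")


def load_mask_png(path) -> np.ndarray:
    """Read a mask written by :func:`save_mask_png` back to a 0/1 array."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if not np.isin(arr, (0, 255)).all():
        raise ValueError(f"{path}: not a binary 0/255 mask")
    return (arr > 0).astype(np.uint8)
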