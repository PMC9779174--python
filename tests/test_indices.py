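"""Vegetation-index formulas: examples, invariants and a scalar-loop oracle."""

import math

import numpy as np
import pytest

from desertfvc.indices import (
    INDEX_NAMES,
    INDEX_REGISTRY,
    UnknownIndexError,
    compute_all_indices,
    compute_index,
    normalize_chromatic,
)

# ---------------------------------------------------------------------------
# Scalar-loop reference: each formula written independently for one pixel.
# ---------------------------------------------------------------------------

def _chrom(R, G, B):
    s = R + G + B
    if s == 0:
        return (1 / 3, 1 / 3, 1 / 3)
    return (R / s, G / s, B / s)


def _ratio(num, den):
    return num / den if den != 0 else 0.0


def _scalar_cive(r, g, b):
    return 0.441 * r - 0.881 * g + 0.385 * b + 18.78745


def _scalar_veg(r, g, b):
    if r == 0 or b == 0:
        return 0.0
    return g / (r**0.667 * b**0.333)


def scalar_index(name, R, G, B):
    r, g, b = _chrom(R, G, B)
    exg = 2 * g - r - b
    exr = 1.4 * r - g
    if name == "GLI":
        return _ratio(2 * G - R - B, 2 * G + R + B)
    if name == "ExG":
        return exg
    if name == "ExR":
        return exr
    if name == "ExB":
        return 1.4 * b - g
    if name == "NGBDI":
        return _ratio(G - B, G + B)
    if name == "NGRDI":
        return _ratio(G - R, G + R)
    if name == "ExGR":
        return exg - exr
    if name == "MGRVI":
        return _ratio(G**2 - R**2, G**2 + R**2)
    if name == "RGBVI":
        return _ratio(G**2 - B * R, G**2 + B * R)
    if name == "GBRI":
        return _ratio(b, g)
    if name == "RGRI":
        return _ratio(r, g)
    if name == "CIVE":
        return _scalar_cive(r, g, b)
    if name == "VEG":
        return _scalar_veg(r, g, b)
    if name == "DEVI":
        return _ratio(G + R + B, 3 * G)
    if name == "EGRBDI":
        return _ratio((2 * G) ** 2 - B * R, (2 * G) ** 2 + B * R)
    if name == "V-MSAVI":
        rad = max((2 * g + 1) ** 2 - 8 * exg, 0.0)
        return (2 * g + 1 - math.sqrt(rad)) / 2
    if name == "g":
        return g
    if name == "COM":
        return (0.25 * exg + 0.3 * (exg - exr) + 0.33 * _scalar_cive(r, g, b)
                + 0.12 * _scalar_veg(r, g, b))
    if name == "COM2":
        return 0.36 * exg + 0.47 * _scalar_cive(r, g, b) + 0.17 * _scalar_veg(r, g, b)
    raise AssertionError(name)


# ---------------------------------------------------------------------------
# Chromatic normalisation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "pixel, expected",
    [
        ((100, 100, 100), (1 / 3, 1 / 3, 1 / 3)),
        ((50, 100, 50), (0.25, 0.5, 0.25)),
        ((0, 0, 0), (1 / 3, 1 / 3, 1 / 3)),
    ],
)
def test_chromatic_pixels(pixel, expected):
    img = np.array([[pixel]], dtype=np.uint8)
    np.testing.assert_allclose(normalize_chromatic(img)[0, 0], expected, atol=1e-12)


def test_chromatic_sums_to_one(random_image):
    chrom = normalize_chromatic(random_image)
    total = random_image.sum(axis=2)
    sums = chrom.sum(axis=2)
    assert np.all(np.abs(sums[total > 0] - 1.0) < 1e-9)
    assert chrom.min() >= 0 and chrom.max() <= 1


# ---------------------------------------------------------------------------
# Point examples frozen from hand/oracle arithmetic
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "name, pixel, expected",
    [
        ("ExG", (0, 255, 0), 2.0),                    # pure green: (r,g,b)=(0,1,0)
        ("GLI", (80, 80, 80), 0.0),                   # gray symmetry
        ("CIVE", (100, 100, 100), 18.769116666666665),  # (0.441-0.881+0.385)/3 + 18.78745
        ("MGRVI", (60, 80, 40), 0.28),                # (80^2-60^2)/(80^2+60^2)
        ("DEVI", (60, 90, 30), 180 / 270),            # (R+G+B)/(3G)
        ("g", (50, 100, 50), 0.5),
    ],
)
def test_index_point_values(name, pixel, expected):
    img = np.array([[pixel]], dtype=np.uint8)
    assert compute_index(img, name)[0, 0] == pytest.approx(expected, abs=1e-12)


def test_degenerate_pixels_are_neutral():
    img = np.zeros((1, 1, 3), dtype=np.uint8)
    for name in INDEX_NAMES:
        value = compute_index(img, name)[0, 0]
        assert np.isfinite(value)
    # raw-space ratio indices give 0 on the black pixel (zero denominator);
    # VEG sees the neutral chromatic point (1/3, 1/3, 1/3) and gives 1.
    for name in ["GLI", "NGBDI", "NGRDI", "MGRVI", "RGBVI", "EGRBDI", "DEVI"]:
        assert compute_index(img, name)[0, 0] == 0.0
    assert compute_index(img, "VEG")[0, 0] == pytest.approx(1.0)


def test_unknown_index_rejected(random_image):
    with pytest.raises(UnknownIndexError, match="ExG"):
        compute_index(random_image, "NDVI")


def test_cive_constant_override():
    img = np.array([[[100, 100, 100]]], dtype=np.uint8)
    v = compute_index(img, "CIVE", constants={"green": 0.811})[0, 0]
    assert v == pytest.approx((0.441 - 0.811 + 0.385) / 3 + 18.78745, abs=1e-12)


# ---------------------------------------------------------------------------
# Whole-registry behaviour
# ---------------------------------------------------------------------------

def test_registry_has_19_unique_indices():
    assert len(INDEX_REGISTRY) == 19
    assert len(set(INDEX_NAMES)) == 19


def test_compute_all_returns_19_maps(random_image):
    maps = compute_all_indices(random_image)
    assert list(maps) == list(INDEX_NAMES)
    for values in maps.values():
        assert values.shape == random_image.shape[:2]
        assert np.all(np.isfinite(values))


def test_gray_image_zeroes_symmetric_indices():
    # ExGR is excluded: on gray it equals -ExR = -(1.4/3 - 1/3) != 0.
    img = np.full((5, 5, 3), 77, dtype=np.uint8)
    maps = compute_all_indices(img)
    for name in ["ExG", "GLI", "NGRDI", "NGBDI", "MGRVI"]:
        np.testing.assert_allclose(maps[name], 0.0, atol=1e-12)
    np.testing.assert_allclose(maps["ExGR"], -(1.4 / 3 - 1 / 3), atol=1e-12)


def test_scalar_loop_oracle_agreement(random_image):
    """Vectorised maps equal an independent per-pixel scalar evaluation."""
    maps = compute_all_indices(random_image)
    h, w = random_image.shape[:2]
    for name in INDEX_NAMES:
        for i in range(h):
            for j in range(w):
                R, G, B = (int(v) for v in random_image[i, j])
                assert maps[name][i, j] == pytest.approx(
                    scalar_index(name, R, G, B), abs=1e-9
                ), (name, R, G, B)


SCALE_INVARIANT = [
    "ExG", "ExR", "ExB", "ExGR", "CIVE", "VEG", "COM", "COM2",   # chromatic
    "GLI", "NGBDI", "NGRDI", "MGRVI", "RGBVI", "GBRI", "RGRI",
    "EGRBDI", "g", "DEVI",                                        # raw ratios
]


@pytest.mark.parametrize("c", [0.5, 2.0])
def test_scale_invariance(c, rng):
    """Global intensity scaling leaves every ratio-form index unchanged."""
    base = 2 * rng.integers(1, 64, size=(12, 12, 3))  # even, so c=0.5 is exact
    scaled = np.round(base * c).astype(np.int64)
    # restrict to exactly representable scalings (no rounding error)
    exact = np.all(scaled == base * c, axis=2)
    assert exact.all()
    for name in SCALE_INVARIANT:
        a = compute_index(base.astype(np.uint8), name)
        b = compute_index(scaled.astype(np.uint8), name)
        np.testing.assert_allclose(a, b, atol=1e-9, err_msg=name)


def test_boundedness(rng):
    imgs = rng.integers(0, 256, size=(8, 10, 10, 3), dtype=np.uint8)
    bounds = {
        "GLI": (-1, 1), "NGBDI": (-1, 1), "NGRDI": (-1, 1), "MGRVI": (-1, 1),
        "RGBVI": (-1, 1), "EGRBDI": (-1, 1), "g": (0, 1), "ExG": (-1, 2),
    }
    for img in imgs:
        for name, (lo, hi) in bounds.items():
            values = compute_index(img, name)
            assert values.min() >= lo - 1e-12 and values.max() <= hi + 1e-12, name


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st
    from hypothesis.extra.numpy import arrays

    _pixels = arrays(np.uint8, (4, 4, 3), elements=st.integers(0, 255))

    @given(_pixels)
    @settings(max_examples=100, deadline=None)
    def test_chromatic_normalisation_properties(img):
        chrom = normalize_chromatic(img)
        np.testing.assert_allclose(chrom.sum(axis=2), 1.0, atol=1e-9)
        assert chrom.min() >= 0.0 and chrom.max() <= 1.0

    @given(_pixels)
    @settings(max_examples=50, deadline=None)
    def test_all_indices_finite_on_arbitrary_images(img):
        for name, values in compute_all_indices(img).items():
            assert np.all(np.isfinite(values)), name
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


def test_invalid_images_rejected():
    with pytest.raises(ValueError):
        compute_index(np.zeros((4, 4), dtype=np.uint8), "ExG")
    with pytest.raises(ValueError):
        compute_index(np.full((2, 2, 3), 300, dtype=np.int64), "ExG")
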