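"""Seeded synthetic grassland scenes with ground-truth vegetation masks.

The generator emulates the statistical structure the index pipeline
assumes in nadir UAV imagery of desert grassland: greenish vegetation
patches (random overlapping ellipses) over yellow-brown soil, with
per-pixel Gaussian colour variation, optional additive sensor noise and
optional darkened shadow pixels inside vegetation.  A ``spectral_overlap``
knob interpolates the vegetation palette toward the soil palette,
controlling how separable the two classes are — the main driver of index
failure at high cover.

Every operation is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np
import pandas as pd

from .fvc import assign_grade
from .reference import DEFAULT_ROI_COUNTS, ROI, ROISet

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "generate_scene",
    "generate_grade_panel",
    "sample_rois",
    "write_scene",
    "panel_manifest",
]

#: Mean RGB of green vegetation over yellow-brown soil; per-channel sd.
#: The sd models within-material chromatic spread: real grassland materials
#: are chromatically consistent (their large intensity variation is mostly
#: spatially structured brightness), so the per-pixel iid spread is kept
#: small relative to the class separation, and class separability is
#: controlled through ``spectral_overlap`` instead.
DEFAULT_VEGETATION_MEAN = (70.0, 120.0, 55.0)
DEFAULT_SOIL_MEAN = (160.0, 140.0, 105.0)
DEFAULT_PALETTE_SD = 4.0

#: Extra spectral overlap applied to the non-desertification grade by the
#: panel generator: dense, heterogeneous cover is where vegetation and soil
#: colours intermix most, and where index pipelines are expected to fail.
NON_DESERTIFICATION_OVERLAP = 0.45
DEFAULT_OVERLAP = 0.15

#: Per-grade target FVCs of the default panel (jittered per seed): fixed
#: base values spread through each severity band the way a field survey's
#: images spread — in particular only one non-desertification scene sits in
#: the very-high-cover regime where colour indices break down.
PANEL_FVC_TARGETS = {
    "Severe": ((1.8, 2.5, 3.0, 3.3, 3.7, 4.2), 0.3),
    "High": ((7.0, 9.5, 13.0, 15.0, 16.0, 18.0), 1.0),
    "Moderate": ((26.0, 31.0, 32.0, 33.5, 43.0, 45.5), 1.5),
    "Slight": ((51.8, 52.3, 53.0, 53.6, 54.5, 55.3), 0.4),
    "Non-desertification": ((72.5, 76.3, 83.4, 86.2, 89.3, 96.5), 1.0),
}


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic scene."""

    target_fvc: float
    height: int = 512
    width: int = 512
    vegetation_mean: tuple[float, float, float] = DEFAULT_VEGETATION_MEAN
    soil_mean: tuple[float, float, float] = DEFAULT_SOIL_MEAN
    palette_sd: float = DEFAULT_PALETTE_SD
    patch_radius: tuple[float, float] = (6.0, 24.0)
    spectral_overlap: float = DEFAULT_OVERLAP
    noise_sd: float = 2.0
    #: Confuser material: dry brown-yellow vegetation and green-yellow soil
    #: litter.  Both remain closer to their own class in 3-D RGB space (so
    #: the supervised reference classifies them correctly) but sit on the
    #: wrong side of typical 1-D index thresholds in green-chromaticity —
    #: the 19 indices misclassify them at different rates.
    #:
    #: ``mixed_fraction`` of each class is mild texture (pull uniform over
    #: ``mixed_beta``, staying on its own side of index thresholds).  On top
    #: of that, per scene a seeded fraction up to ``dry_cross_max`` of the
    #: vegetation is rendered fully dry (crossing index thresholds), and a
    #: litter pixel count up to ``litter_cross_max`` times the vegetation
    #: area is scattered over the soil (litter accumulates near plants, so
    #: its mass scales with cover).  The two draws are independent, making
    #: the index-FVC error signed and bounded at roughly +/- the maxima,
    #: at every cover level.
    mixed_fraction: float = 0.06
    mixed_beta: tuple[float, float] = (0.15, 0.4)
    dry_cross_max: float = 0.012
    litter_cross_max: float = 0.012
    cross_beta: tuple[float, float] = (0.8, 0.95)
    #: Dry vegetation is a fixed brown-yellow; litter is defined relative to
    #: the effective palettes (part-way green plus a bright-yellow off-axis
    #: offset) so that it stays 3-D-closer to soil at every overlap while
    #: its green chromaticity crosses typical index thresholds.
    dry_vegetation_mean: tuple[float, float, float] = (115.0, 100.0, 65.0)
    litter_green: float = 0.62
    litter_offset: tuple[float, float, float] = (25.0, 15.0, -8.0)
    shadow_fraction: float = 0.0
    fvc_tolerance: float = 2.0
    seed: int = 0


@dataclass(frozen=True)
class SyntheticScene:
    """A generated scene: image, truth mask and achieved coverage."""

    image: np.ndarray       # H x W x 3 uint8
    truth_mask: np.ndarray  # H x W uint8, 1 = vegetation
    achieved_fvc: float
    intended_grade: str
    spec: SceneSpec


def _fill_ellipse(mask: np.ndarray, cy, cx, a, b, theta, rng) -> np.ndarray:
    """Paint one rotated ellipse into a boolean mask (in place) and return it."""
    h, w = mask.shape
    r = max(a, b)
    y0, y1 = int(max(0, np.floor(cy - r))), int(min(h, np.ceil(cy + r) + 1))
    x0, x1 = int(max(0, np.floor(cx - r))), int(min(w, np.ceil(cx + r) + 1))
    if y0 >= y1 or x0 >= x1:
        return mask
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    mask[y0:y1, x0:x1] |= inside
    return mask


def _patch_mask(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    """Ellipse-union mask hitting the target coverage within tolerance.

    For targets above 50% the complement is generated (soil gaps punched
    into full vegetation), which keeps patch counts modest at high cover.
    """
    h, w = spec.height, spec.width
    n = h * w
    target = spec.target_fvc
    invert = target > 50.0
    tol = spec.fvc_tolerance
    # Patch cover is laid down in [stop, cap]; for inverted (high-cover)
    # scenes the band sits below 100 - target so that the vegetation FVC
    # never lands under the target — symmetric with the low-cover case,
    # where it never lands under it either.
    if invert:
        cap = 100.0 - target
        stop = max(cap - 0.9 * tol, 0.0)
    else:
        stop = target
        cap = target + 0.9 * tol
    mask = np.zeros((h, w), dtype=bool)
    if stop > 0:
        rmin, rmax = spec.patch_radius
        max_iter = 200_000
        it = 0
        while 100.0 * mask.sum() / n < stop:
            it += 1
            if it > max_iter:
                raise RuntimeError(
                    f"unreachable target FVC {target}% with patch radii {spec.patch_radius}"
                )
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
            a = rng.uniform(rmin, rmax)
            b = rng.uniform(rmin, rmax)
            theta = rng.uniform(0, np.pi)
            # Shrink the patch rather than overshoot past the cap.
            for _ in range(40):
                candidate = _fill_ellipse(mask.copy(), cy, cx, a, b, theta, rng)
                if 100.0 * candidate.sum() / n <= cap:
                    mask = candidate
                    break
                a *= 0.7
                b *= 0.7
                if max(a, b) < 0.7:
                    break
    return ~mask if invert else mask


def _render(spec: SceneSpec, truth: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    veg = np.asarray(spec.vegetation_mean, dtype=np.float64)
    soil = np.asarray(spec.soil_mean, dtype=np.float64)
    ov = float(spec.spectral_overlap)
    if not 0.0 <= ov <= 1.0:
        raise ValueError("spectral_overlap must lie in [0, 1]")
    veg_eff = veg + ov * (soil - veg)
    h, w = truth.shape
    means = np.where(truth[..., None].astype(bool), veg_eff, soil)
    veg_px = truth.astype(bool)
    dry = np.asarray(spec.dry_vegetation_mean, dtype=np.float64)
    litter = (soil + spec.litter_green * (veg_eff - soil)
              + np.asarray(spec.litter_offset, dtype=np.float64))
    if spec.mixed_fraction > 0:
        mixed = rng.random((h, w)) < spec.mixed_fraction
        beta = rng.uniform(*spec.mixed_beta, size=(h, w, 1))
        confuser = np.where(veg_px[..., None], dry, litter)
        means = np.where(mixed[..., None], means + beta * (confuser - means), means)
    n_veg = int(veg_px.sum())
    if n_veg > 0:
        # Fully dry vegetation pixels (index thresholds miss them).
        n_dry = int(round(rng.uniform(0, spec.dry_cross_max) * n_veg))
        # Green litter over the soil; its amount scales with vegetation area
        # (capped at half the soil so soil never vanishes under litter).
        n_litter = min(int(round(rng.uniform(0, spec.litter_cross_max) * n_veg)),
                       int((~veg_px).sum()) // 2)
        flat = means.reshape(-1, 3)
        for n_sel, pool, colour in ((n_dry, veg_px, dry), (n_litter, ~veg_px, litter)):
            if n_sel > 0:
                idx = rng.choice(np.flatnonzero(pool.ravel()), size=n_sel, replace=False)
                beta_c = rng.uniform(*spec.cross_beta, size=(n_sel, 1))
                flat[idx] = flat[idx] + beta_c * (colour - flat[idx])
        means = flat.reshape(h, w, 3)
    img = means + rng.normal(0.0, spec.palette_sd, size=(h, w, 3))
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(h, w, 3))
    if spec.shadow_fraction > 0:
        shade = truth.astype(bool) & (rng.random((h, w)) < spec.shadow_fraction)
        img[shade] *= 0.5
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate one scene; the truth-mask FVC lands within the spec tolerance
    of ``target_fvc`` and on the same side of every grade boundary."""
    if not 0.0 <= spec.target_fvc <= 100.0:
        raise ValueError("target_fvc must lie in [0, 100]")
    intended = assign_grade(spec.target_fvc)
    for attempt in range(8):
        rng = np.random.default_rng((spec.seed, attempt))
        truth = _patch_mask(spec, rng).astype(np.uint8)
        achieved = 100.0 * truth.sum() / truth.size
        if (
            abs(achieved - spec.target_fvc) <= spec.fvc_tolerance
            and assign_grade(achieved) == intended
        ):
            image = _render(spec, truth, rng)
            return SyntheticScene(
                image=image, truth_mask=truth, achieved_fvc=float(achieved),
                intended_grade=intended, spec=spec,
            )
    raise RuntimeError(
        f"could not reach target FVC {spec.target_fvc}% within "
        f"±{spec.fvc_tolerance} points inside grade {intended!r}"
    )


def generate_grade_panel(
    n_per_grade: int = 6,
    base_spec: SceneSpec | None = None,
    seed: int = 0,
    non_desertification_overlap: float = NON_DESERTIFICATION_OVERLAP,
) -> list[SyntheticScene]:
    """A balanced panel of scenes spanning all five grades (default 30).

    Target FVCs are the per-grade base values of :data:`PANEL_FVC_TARGETS`
    with seeded jitter (cycled when ``n_per_grade`` exceeds 6); the
    non-desertification grade uses a raised spectral overlap so the dense-
    cover regime is genuinely harder for colour-based indices.
    """
    if base_spec is None:
        base_spec = SceneSpec(target_fvc=30.0)
    rng = np.random.default_rng(seed)
    scenes: list[SyntheticScene] = []
    for grade, (bases, jitter) in PANEL_FVC_TARGETS.items():
        lo, hi = _band_floor(grade), _band_ceil(grade)
        for i in range(n_per_grade):
            target = bases[i % len(bases)] + float(rng.uniform(-jitter, jitter))
            target = float(np.clip(target, lo + 0.7, hi - 0.5 if hi < 100 else 100.0))
            overlap = (
                non_desertification_overlap
                if grade == "Non-desertification"
                else base_spec.spectral_overlap
            )
            # Keep the achieved FVC strictly inside the grade band.
            margin = min(target - _band_floor(grade), _band_ceil(grade) - target)
            tol = float(np.clip(min(base_spec.fvc_tolerance, margin), 0.25, None))
            scene_seed = int(rng.integers(0, 2**31 - 1))
            spec = replace(
                base_spec,
                target_fvc=target,
                spectral_overlap=overlap,
                fvc_tolerance=tol,
                seed=scene_seed,
            )
            scenes.append(generate_scene(spec))
    return scenes


def _band_floor(grade: str) -> float:
    from .fvc import GRADES

    return next(g.lower for g in GRADES if g.label == grade)


def _band_ceil(grade: str) -> float:
    from .fvc import GRADES

    return next(g.upper for g in GRADES if g.label == grade)


# ---------------------------------------------------------------------------
# ROI sampling from the truth mask
# ---------------------------------------------------------------------------

def _window_pure(integral: np.ndarray, r: int, c: int, h: int, w: int) -> bool:
    s = integral[r + h, c + w] - integral[r, c + w] - integral[r + h, c] + integral[r, c]
    return s == h * w


def _place_patches(
    pure: np.ndarray,
    occupied: np.ndarray,
    n: int,
    side: int,
    rng: np.random.Generator,
    tries_per_patch: int = 4000,
) -> list[tuple[int, int, int]]:
    """Place n non-overlapping side x side patches in pure-class area.

    Returns (row, col, side) triples; shrinks the side (down to 1) when
    placement stalls.  Raises if even 1 x 1 patches cannot be placed.
    """
    h, w = pure.shape
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(pure.astype(np.int64), axis=0), axis=1)
    placed: list[tuple[int, int, int]] = []
    s = side
    while len(placed) < n:
        ok = False
        for _ in range(tries_per_patch):
            if h - s < 0 or w - s < 0:
                break
            r = int(rng.integers(0, h - s + 1))
            c = int(rng.integers(0, w - s + 1))
            if not _window_pure(integral, r, c, s, s):
                continue
            if occupied[r:r + s, c:c + s].any():
                continue
            occupied[r:r + s, c:c + s] = True
            placed.append((r, c, s))
            ok = True
            break
        if not ok:
            if s > 1:
                s -= 1
                continue
            raise ValueError(
                "insufficient pure-class area to place the requested ROIs"
            )
    return placed


def sample_rois(
    scene: SyntheticScene,
    counts: dict[str, tuple[int, int]] | None = None,
    seed: int = 0,
    validation_fraction: float = 0.12,
) -> ROISet:
    """Sample disjoint rectangular ROIs from pure-class truth-mask areas.

    Training and test ROIs are small fixed-size patches; validation ROIs
    are sized so their total area is ``validation_fraction`` of the image
    (split between classes in proportion to class prevalence, so scarce
    vegetation gets proportionally small reference regions).
    """
    if counts is None:
        counts = DEFAULT_ROI_COUNTS
    truth = scene.truth_mask.astype(bool)
    h, w = truth.shape
    n_pixels = h * w
    rng = np.random.default_rng((seed, scene.spec.seed))
    occupied = np.zeros((h, w), dtype=bool)
    pure = {"vegetation": truth, "non_vegetation": ~truth}
    rois: list[ROI] = []

    def add(cls: str, role: str, n: int, side: int) -> int:
        if n == 0:
            return 0
        if not pure[cls].any():
            raise ValueError(f"scene has no {cls} pixels: cannot sample {role} ROIs")
        total = 0
        for r, c, s in _place_patches(pure[cls], occupied, n, side, rng):
            rois.append(ROI.rect(r, c, s, s, cls, role))
            total += s * s
        return total

    # Train and test: compact patches, shrunk automatically in scarce classes.
    for role, default_side in (("train", 4), ("test", 8)):
        n_veg, n_soil = counts.get(role, (0, 0))
        for cls, n in (("vegetation", n_veg), ("non_vegetation", n_soil)):
            if n == 0:
                continue
            avail = int(pure[cls].sum())
            side = int(np.clip(np.sqrt(0.25 * avail / max(n, 1)), 1, default_side))
            add(cls, role, n, side)

    # Validation: total area ~ validation_fraction of the image, stratified
    # by class prevalence.
    n_veg, n_soil = counts.get("validation", (0, 0))
    if n_veg or n_soil:
        total_target = validation_fraction * n_pixels
        frac_veg = truth.mean()
        placed_veg = 0
        if n_veg:
            area_veg = max(n_veg, total_target * frac_veg)
            side = max(1, int(round(np.sqrt(area_veg / n_veg))))
            placed_veg = add("vegetation", "validation", n_veg, side)
        if n_soil:
            area_soil = max(n_soil, total_target - placed_veg)
            side = max(1, int(round(np.sqrt(area_soil / n_soil))))
            add("non_vegetation", "validation", n_soil, side)

    return ROISet(rois, (h, w))


# ---------------------------------------------------------------------------
# Artifact output
# ---------------------------------------------------------------------------

def write_scene(scene: SyntheticScene, directory, stem: str) -> None:
    """Write the scene image and its truth mask as PNGs."""
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    iio.imwrite(directory / f"{stem}.png", scene.image, extension=".png")
    iio.imwrite(directory / f"{stem}_truth.png",
                (scene.truth_mask * 255).astype(np.uint8), extension=".png")


def panel_manifest(scenes: list[SyntheticScene]) -> pd.DataFrame:
    """Per-scene manifest (id, seed, target/achieved FVC, grade, overlap)."""
    return pd.DataFrame(
        [
            dict(
                scene_id=i + 1,
                seed=s.spec.seed,
                target_fvc=s.spec.target_fvc,
                achieved_fvc=s.achieved_fvc,
                grade=s.intended_grade,
                spectral_overlap=s.spec.spectral_overlap,
            )
            for i, s in enumerate(scenes)
        ]
    )
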