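"""Supervised reference classification of RGB scenes.

The reference vegetation mask — whose FVC serves as the "true" value V_sup
against which index-derived FVC is scored — is produced by a per-pixel
radial-basis-function SVM trained on vegetation / non-vegetation regions of
interest (ROIs).  ROIs come in three disjoint roles: ``train`` (default
60 + 60 regions), ``test`` (15 + 15, for OA/kappa of the reference itself)
and ``validation`` (80 + 80, reserved for scoring the index pipeline).

The classifier scales raw (R, G, B) intensities to [0, 1] before the RBF
kernel, where the configured kernel width gamma = 0.333 (one over the
number of features) is meaningful; every pixel receives the argmax label
(no rejection class).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .indices import validate_rgb_image

__all__ = [
    "ROLES",
    "CLASS_LABELS",
    "ROI",
    "ROISet",
    "PixelClassifier",
    "extract_training_samples",
    "write_roi_masks",
    "read_roi_masks",
    "write_roi_polygons",
    "read_roi_polygons",
]

ROLES = ("train", "test", "validation")
CLASS_LABELS = ("vegetation", "non_vegetation")

#: Per-role region counts (vegetation, non-vegetation) of the study design.
DEFAULT_ROI_COUNTS = {"train": (60, 60), "test": (15, 15), "validation": (80, 80)}


@dataclass(frozen=True)
class ROI:
    """One labelled region: a pixel mask anchored at (row, col)."""

    label: str
    role: str
    row: int
    col: int
    mask: np.ndarray  # bool (h, w) within the bounding box

    def __post_init__(self):
        if self.label not in CLASS_LABELS:
            raise ValueError(f"ROI label must be one of {CLASS_LABELS}")
        if self.role not in ROLES:
            raise ValueError(f"ROI role must be one of {ROLES}")
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2 or not m.any():
            raise ValueError("ROI mask must be a non-empty 2-D boolean array")
        object.__setattr__(self, "mask", m)

    @classmethod
    def rect(cls, row: int, col: int, height: int, width: int, label: str, role: str) -> "ROI":
        return cls(label=label, role=role, row=row, col=col,
                   mask=np.ones((height, width), dtype=bool))

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


class ROISet:
    """A collection of ROIs with disjoint roles over one image."""

    def __init__(self, rois: Iterable[ROI], image_shape: tuple[int, int]):
        self.rois: tuple[ROI, ...] = tuple(rois)
        self.image_shape = (int(image_shape[0]), int(image_shape[1]))
        self._validate()

    def _validate(self) -> None:
        h, w = self.image_shape
        painted = np.zeros((h, w), dtype=np.uint8)  # bitmask of roles per pixel
        role_bit = {r: 1 << i for i, r in enumerate(ROLES)}
        for roi in self.rois:
            rh, rw = roi.mask.shape
            if roi.row < 0 or roi.col < 0 or roi.row + rh > h or roi.col + rw > w:
                raise ValueError("ROI outside image bounds")
            window = painted[roi.row:roi.row + rh, roi.col:roi.col + rw]
            other = window[roi.mask] & np.uint8(0xFF ^ role_bit[roi.role])
            if other.any():
                raise ValueError(
                    f"ROI roles must not overlap (a {roi.role} region touches another role)"
                )
            window[roi.mask] |= role_bit[roi.role]

    def select(self, role: str | None = None, label: str | None = None) -> tuple[ROI, ...]:
        return tuple(
            r for r in self.rois
            if (role is None or r.role == role) and (label is None or r.label == label)
        )

    def counts(self, role: str) -> tuple[int, int]:
        """(n vegetation regions, n non-vegetation regions) for a role."""
        return (len(self.select(role, "vegetation")),
                len(self.select(role, "non_vegetation")))

    def n_pixels(self, role: str) -> int:
        return sum(r.n_pixels for r in self.select(role))

    def label_array(self, role: str) -> np.ndarray:
        """Per-pixel labels for one role: 0 unassigned, 1 vegetation, 2 non-veg."""
        out = np.zeros(self.image_shape, dtype=np.uint8)
        for roi in self.select(role):
            code = 1 if roi.label == "vegetation" else 2
            window = out[roi.row:roi.row + roi.mask.shape[0],
                         roi.col:roi.col + roi.mask.shape[1]]
            window[roi.mask] = code
        return out


def extract_training_samples(
    image: np.ndarray, rois: ROISet, role: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel (R, G, B) feature vectors and binary labels for one ROI role.

    Returns ``(X, y)`` with X float64 of shape (n, 3) holding raw intensities
    and y in {1 = vegetation, 0 = non-vegetation}.
    """
    arr = validate_rgb_image(image)
    if role not in ROLES:
        raise ValueError(f"role must be one of {ROLES}")
    labels = rois.label_array(role)
    if labels.shape != arr.shape[:2]:
        raise ValueError("ROI set does not match image shape")
    if not (labels > 0).any():
        raise ValueError(f"no ROIs with role {role!r}")
    sel = labels > 0
    X = arr[sel].astype(np.float64)
    y = (labels[sel] == 1).astype(np.int64)
    return X, y


class PixelClassifier:
    """RBF-SVM pixel classifier (vegetation vs non-vegetation).

    Parameters mirror the reference study design: radial-basis kernel with
    gamma = 0.333 and no rejection class.  Features are raw 8-bit (R, G, B)
    scaled to [0, 1]; set ``chromatic_features=True`` to append the
    brightness-normalised (r, g, b) coordinates.  Training pixels are capped
    at ``max_samples_per_class`` by seeded subsampling.
    """

    def __init__(
        self,
        gamma: float = 0.333,
        c: float = 1.0,
        chromatic_features: bool = False,
        max_samples_per_class: int = 10_000,
        seed: int = 0,
    ):
        self.gamma = gamma
        self.c = c
        self.chromatic_features = chromatic_features
        self.max_samples_per_class = max_samples_per_class
        self.seed = seed
        self._svc = None

    @property
    def fitted(self) -> bool:
        return self._svc is not None

    def _features(self, X_raw: np.ndarray) -> np.ndarray:
        feats = np.asarray(X_raw, dtype=np.float64) / 255.0
        if self.chromatic_features:
            total = feats.sum(axis=1, keepdims=True)
            chrom = np.where(total > 0, feats / total, 1.0 / 3.0)
            feats = np.hstack([feats, chrom])
        return feats

    def fit(self, X_raw: np.ndarray, y: np.ndarray) -> "PixelClassifier":
        from sklearn.svm import SVC

        X_raw = np.asarray(X_raw, dtype=np.float64)
        y = np.asarray(y).astype(np.int64)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training set must contain both classes")
        rng = np.random.default_rng(self.seed)
        keep = []
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            if len(idx) > self.max_samples_per_class:
                idx = rng.choice(idx, self.max_samples_per_class, replace=False)
            keep.append(idx)
        idx = np.sort(np.concatenate(keep))
        self._svc = SVC(kernel="rbf", gamma=self.gamma, C=self.c)
        self._svc.fit(self._features(X_raw[idx]), y[idx])
        return self

    def predict(self, X_raw: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("classifier is not fitted")
        return self._svc.predict(self._features(X_raw)).astype(np.uint8)

    def classify_image(self, image: np.ndarray, chunk: int = 262_144) -> np.ndarray:
        """Per-pixel binary vegetation mask of a whole RGB image."""
        arr = validate_rgb_image(image)
        flat = arr.reshape(-1, 3).astype(np.float64)
        out = np.empty(flat.shape[0], dtype=np.uint8)
        for start in range(0, flat.shape[0], chunk):
            out[start:start + chunk] = self.predict(flat[start:start + chunk])
        return out.reshape(arr.shape[:2])


# ---------------------------------------------------------------------------
# ROI file formats: labelled-mask PNGs (one per role) and a polygon text file.
# ---------------------------------------------------------------------------

def write_roi_masks(rois: ROISet, directory) -> None:
    """Write one labelled-mask PNG per role (0 unassigned, 1 veg, 2 non-veg)."""
    import imageio.v3 as iio
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for role in ROLES:
        if rois.select(role):
            iio.imwrite(directory / f"roi_{role}.png", rois.label_array(role),
                        extension=".png")


def read_roi_masks(directory, image_shape: tuple[int, int]) -> ROISet:
    """Read labelled-mask PNGs back; each connected region becomes one ROI."""
    import imageio.v3 as iio
    from pathlib import Path
    from scipy import ndimage

    directory = Path(directory)
    rois: list[ROI] = []
    for role in ROLES:
        path = directory / f"roi_{role}.png"
        if not path.exists():
            continue
        labels = iio.imread(path)
        if labels.ndim == 3:
            labels = labels[..., 0]
        for code, cls in ((1, "vegetation"), (2, "non_vegetation")):
            comp, n = ndimage.label(labels == code)
            for obj in ndimage.find_objects(comp):
                sub = comp[obj] > 0
                rois.append(ROI(label=cls, role=role,
                                row=obj[0].start, col=obj[1].start, mask=sub))
    return ROISet(rois, image_shape)


def write_roi_polygons(rois: ROISet, path, image_id: str = "image") -> None:
    """Write ROIs as a polygon text file (rectangular ROIs only).

    Format: one line per region,
    ``image_id,role,class,x1 y1;x2 y2;...`` with x = column, y = row,
    vertices listed clockwise and the polygon closed implicitly.
    """
    lines = []
    for roi in rois.rois:
        h, w = roi.mask.shape
        if not roi.mask.all():
            raise ValueError("polygon export supports rectangular ROIs only")
        r, c = roi.row, roi.col
        verts = [(c, r), (c + w - 1, r), (c + w - 1, r + h - 1), (c, r + h - 1)]
        vtxt = ";".join(f"{x} {y}" for x, y in verts)
        lines.append(f"{image_id},{roi.role},{roi.label},{vtxt}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_roi_polygons(path, image_shape: tuple[int, int]) -> ROISet:
    """Read a polygon text file into a ROISet (polygons rasterised inclusively)."""
    from PIL import Image, ImageDraw

    h, w = image_shape
    rois: list[ROI] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            _, role, label, vtxt = line.split(",", 3)
            verts = [tuple(float(v) for v in pair.split()) for pair in vtxt.split(";")]
            img = Image.new("1", (w, h), 0)
            ImageDraw.Draw(img).polygon([(x, y) for x, y in verts], outline=1, fill=1)
            full = np.asarray(img, dtype=bool)
            rows, cols = np.nonzero(full)
            r0, c0 = rows.min(), cols.min()
            sub = full[r0:rows.max() + 1, c0:cols.max() + 1]
            rois.append(ROI(label=label, role=role, row=int(r0), col=int(c0), mask=sub))
    return ROISet(rois, image_shape)
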