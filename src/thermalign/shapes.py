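"""Shape vectors, similarity alignment, bbox initialization and flip augmentation.

A face shape is an ``(M, 2)`` float array of landmark ``(x, y)`` coordinates
in image pixels. The coordinate convention throughout the package is 0-based
with ``x`` the column index and ``y`` the row index, pixel centers at integer
coordinates. The equivalent vector form ``S = [x1, y1, ..., xM, yM]`` is used
inside the regressor.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import SimilarityTransform as _SkSimilarity

from .errors import DegenerateShapeError, ValidationError
from .thermal_io import ThermalImage

__all__ = [
    "BBox",
    "AnnotatedSample",
    "SimilarityTransform",
    "MirrorMap",
    "as_shape",
    "mean_shape",
    "init_shape",
    "align_similarity",
    "flip_sample",
    "flip_dataset",
    "default_mirror_map_68",
    "shape_extent",
]


@dataclass(frozen=True)
class BBox:
    """Axis-aligned face box: top-left corner ``(x, y)`` and extent ``(w, h)``."""

    x: float
    y: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValidationError(f"bbox extent must be positive, got w={self.w}, h={self.h}")


@dataclass
class AnnotatedSample:
    """One image with its ground-truth annotation and acquisition labels."""

    image: ThermalImage
    shape: np.ndarray  # (M, 2) ground-truth landmarks
    bbox: BBox
    subject: str
    distance: int  # camera distance condition in cm
    section: str  # recording interval label (Small / Large / Random)
    sample_id: str = ""
    flipped: bool = False

    @property
    def M(self) -> int:
        return int(self.shape.shape[0])


@dataclass(frozen=True)
class SimilarityTransform:
    """Similarity map ``p -> scale * R(rotation) @ p + (tx, ty)`` (no reflection)."""

    scale: float
    rotation: float  # radians, counter-clockwise in (x, y)
    tx: float
    ty: float

    @property
    def matrix(self) -> np.ndarray:
        """The 2x2 linear part ``scale * R``."""
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + np.array([self.tx, self.ty])

    def inverse(self) -> "SimilarityTransform":
        inv_lin = self.matrix.T / (self.scale**2)  # R^T / s
        t = -inv_lin @ np.array([self.tx, self.ty])
        return SimilarityTransform(1.0 / self.scale, -self.rotation, t[0], t[1])


@dataclass(frozen=True)
class MirrorMap:
    """Left/right landmark pairing used by horizontal flips; an involution."""

    perm: tuple

    def __post_init__(self) -> None:
        perm = np.asarray(self.perm, dtype=int)
        if not np.array_equal(perm[perm], np.arange(perm.size)):
            raise ValidationError("mirror permutation must be an involution")

    def __len__(self) -> int:
        return len(self.perm)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.perm, dtype=int)


def as_shape(coords: Sequence, M: int | None = None) -> np.ndarray:
    """Validate and return landmark coordinates as an ``(M, 2)`` float array."""
    arr = np.asarray(coords, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 2)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValidationError(f"shape must be (M>=2, 2), got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("shape contains non-finite coordinates")
    if M is not None and arr.shape[0] != M:
        raise ValidationError(f"expected {M} landmarks, got {arr.shape[0]}")
    return arr


def shape_extent(shape: np.ndarray) -> tuple[float, float]:
    """Width and height of the landmark cloud (max - min per axis)."""
    s = as_shape(shape)
    w = float(s[:, 0].max() - s[:, 0].min())
    h = float(s[:, 1].max() - s[:, 1].min())
    return w, h


def normalize_to_bbox(shape: np.ndarray, bbox: BBox) -> np.ndarray:
    """Map a shape into the unit reference frame of its bounding box."""
    s = as_shape(shape)
    return (s - np.array([bbox.x, bbox.y])) / np.array([bbox.w, bbox.h])


def mean_shape(shapes: Sequence[np.ndarray], bboxes: Sequence[BBox]) -> np.ndarray:
    """Per-landmark average of training shapes in the bbox-normalized unit frame.

    Each shape is translated and (anisotropically) scaled so that its bounding
    box becomes the unit square, then coordinates are averaged per landmark.
    The result lives in the unit frame and is the cascade's initial shape
    template.
    """
    if len(shapes) == 0:
        raise ValidationError("mean_shape requires at least one shape")
    if len(shapes) != len(bboxes):
        raise ValidationError("shapes and bboxes must have equal length")
    M = as_shape(shapes[0]).shape[0]
    acc = np.zeros((M, 2))
    for s, b in zip(shapes, bboxes):
        acc += normalize_to_bbox(as_shape(s, M=M), b)
    return acc / len(shapes)


def init_shape(bbox: BBox, mean: np.ndarray) -> np.ndarray:
    """Place the unit-frame mean shape into a bounding box (the cascade's S0)."""
    m = as_shape(mean)
    return m * np.array([bbox.w, bbox.h]) + np.array([bbox.x, bbox.y])


def align_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform taking ``src`` onto ``dst``.

    Returns the scale/rotation/translation minimizing
    ``sum_i || T(src_i) - dst_i ||^2`` with no reflection component
    (Umeyama closed form).
    """
    s = as_shape(src)
    d = as_shape(dst)
    if s.shape != d.shape:
        raise ValidationError(f"shape size mismatch: {s.shape} vs {d.shape}")
    if np.allclose(s, s[0], atol=1e-12):
        raise DegenerateShapeError("all source points coincide; similarity is undefined")
    if hasattr(_SkSimilarity, "from_estimate"):
        t = _SkSimilarity.from_estimate(s, d)
        ok = bool(t)
    else:  # skimage < 0.26
        t = _SkSimilarity()
        ok = t.estimate(s, d)
    if not ok or not np.isfinite(t.scale) or t.scale <= 0:
        raise DegenerateShapeError("similarity estimation failed (degenerate configuration)")
    return SimilarityTransform(float(t.scale), float(t.rotation), float(t.translation[0]), float(t.translation[1]))


# Standard 68-point left/right pairing (iBUG ordering): jaw 0..16, brows
# 17..26, nose bridge 27..30 + base 31..35, eyes 36..47, mouth 48..67.
def default_mirror_map_68() -> MirrorMap:
    perm = np.arange(68)

    def pair(a: int, b: int) -> None:
        perm[a], perm[b] = b, a

    for i in range(8):  # jaw
        pair(i, 16 - i)
    for k in range(5):  # brows
        pair(17 + k, 26 - k)
    for k in range(2):  # nostril line (33 is the midline fixed point)
        pair(31 + k, 35 - k)
    eye_pairs = [(36, 45), (37, 44), (38, 43), (39, 42), (40, 47), (41, 46)]
    mouth_pairs = [(48, 54), (49, 53), (50, 52), (55, 59), (56, 58), (60, 64), (61, 63), (65, 67)]
    for a, b in eye_pairs + mouth_pairs:
        pair(a, b)
    return MirrorMap(tuple(int(i) for i in perm))


def flip_sample(sample: AnnotatedSample, mirror: MirrorMap | None = None) -> AnnotatedSample:
    """Mirror a sample about the image's vertical axis.

    The image is flipped left-right, landmark ``x`` becomes ``W - 1 - x``
    (pixel-center convention, so a double flip is exact), landmark order is
    reindexed by the mirror map, and the bbox is reflected. Subject and
    condition labels are preserved; the flip-provenance flag is toggled.
    """
    if mirror is None:
        mirror = default_mirror_map_68()
    if len(mirror) != sample.M:
        raise ValidationError(f"mirror map length {len(mirror)} != landmark count {sample.M}")
    W = sample.image.width
    pixels = np.ascontiguousarray(sample.image.pixels[:, ::-1])
    image = dataclasses.replace(sample.image, pixels=pixels, meta=dict(sample.image.meta))
    shape = sample.shape.copy()
    shape[:, 0] = (W - 1) - shape[:, 0]
    shape = shape[mirror.as_array()]
    bbox = BBox(W - sample.bbox.x - sample.bbox.w, sample.bbox.y, sample.bbox.w, sample.bbox.h)
    return AnnotatedSample(
        image=image,
        shape=shape,
        bbox=bbox,
        subject=sample.subject,
        distance=sample.distance,
        section=sample.section,
        sample_id=sample.sample_id,
        flipped=not sample.flipped,
    )


def flip_dataset(samples: Sequence[AnnotatedSample], mirror: MirrorMap | None = None) -> list[AnnotatedSample]:
    """Return originals followed by their mirrored copies (flip augmentation)."""
    if mirror is None:
        mirror = default_mirror_map_68()
    return list(samples) + [flip_sample(s, mirror) for s in samples]
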