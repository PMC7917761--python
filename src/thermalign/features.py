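"""Shape-indexed two-pixel difference features.

A feature probe is an (anchor landmark, offset) pair expressed in the
mean-shape reference frame. To read probes from an image, the similarity
transform from the mean shape to the current shape estimate is applied to the
offsets, anchoring each probe at its landmark's current position — this makes
the features covariant with pose and scale. The scalar used at a tree split
node is the intensity difference between two probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ValidationError
from .shapes import align_similarity, as_shape
from .thermal_io import ThermalImage


@dataclass
class IntensityImage:
    """Normalized image with values in [0, 1] plus normalization provenance."""

    pixels: np.ndarray  # (H, W) float32 in [0, 1]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.size and (self.pixels.min() < 0 or self.pixels.max() > 1):
            raise ValidationError("intensity values must lie in [0, 1]")


@dataclass
class FeaturePool:
    """Per-stage pool of P probe points in the mean-shape frame."""

    anchors: np.ndarray  # (P,) landmark indices
    offsets: np.ndarray  # (P, 2) offsets in mean-shape reference units
    stage: int = 0

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=np.int32)
        self.offsets = np.asarray(self.offsets, dtype=np.float64)
        if self.anchors.shape[0] != self.offsets.shape[0]:
            raise ValidationError("anchors and offsets must have equal length")

    @property
    def P(self) -> int:
        return int(self.anchors.shape[0])

    def positions_in(self, shape: np.ndarray) -> np.ndarray:
        """Probe coordinates when the offsets are laid out on ``shape`` directly."""
        return as_shape(shape)[self.anchors] + self.offsets


def normalize_to_intensity(
    img: ThermalImage,
    mode: str = "minmax",
    fixed_range: tuple[float, float] = (20.0, 40.0),
) -> IntensityImage:
    """Map a thermal (or raw-intensity) image to [0, 1].

    ``minmax`` rescales the per-image [min, max] onto [0, 1] (a constant image
    maps to all zeros); ``fixed`` maps a configured Celsius window with
    clipping, which keeps absolute temperature contrasts comparable across
    images. Both maps are monotone non-decreasing.
    """
    px = img.pixels.astype(np.float64)
    if mode == "minmax":
        lo, hi = float(px.min()), float(px.max())
        if hi > lo:
            out = (px - lo) / (hi - lo)
        else:
            out = np.zeros_like(px)
        prov = {"mode": "minmax", "lo": lo, "hi": hi}
    elif mode == "fixed":
        lo, hi = float(fixed_range[0]), float(fixed_range[1])
        if lo >= hi:
            raise ConfigError(f"fixed range must satisfy lo < hi, got [{lo}, {hi}]")
        out = np.clip((px - lo) / (hi - lo), 0.0, 1.0)
        prov = {"mode": "fixed", "lo": lo, "hi": hi}
    else:
        raise ConfigError(f"unknown normalization mode {mode!r}")
    return IntensityImage(out.astype(np.float32), provenance=prov)


def sample_feature_pool(
    mean: np.ndarray,
    P: int = 400,
    spread: float = 0.15,
    rng: np.random.Generator | None = None,
    stage: int = 0,
) -> FeaturePool:
    """Draw P probe points uniformly around uniformly chosen anchor landmarks.

    Offsets are uniform in the square [-spread, +spread]^2 in mean-shape
    reference units. Deterministic under a fixed generator state; a fresh pool
    is drawn for each cascade stage.
    """
    if P < 2:
        raise ConfigError(f"feature pool needs P >= 2 points, got {P}")
    if not spread > 0:
        raise ConfigError(f"spread must be positive, got {spread}")
    if rng is None:
        rng = np.random.default_rng()
    m = as_shape(mean)
    anchors = rng.integers(0, m.shape[0], size=P)
    offsets = rng.uniform(-spread, spread, size=(P, 2))
    return FeaturePool(anchors=anchors, offsets=offsets, stage=stage)


def warp_points(pool: FeaturePool, mean: np.ndarray, current: np.ndarray) -> np.ndarray:
    """Map pool probes from the mean-shape frame onto the current shape estimate.

    The rotation/scale of the mean-to-current similarity fit is applied to the
    offsets; each probe stays anchored at its landmark's current position, so
    probe geometry follows the face through translation, scaling and in-plane
    rotation.
    """
    cur = as_shape(current)
    t = align_similarity(as_shape(mean), cur)
    rotated = pool.offsets @ t.matrix.T
    return cur[pool.anchors] + rotated


def extract_features(img: IntensityImage, positions: np.ndarray) -> np.ndarray:
    """Nearest-pixel intensity lookup; out-of-image probes clamp to the border."""
    H, W = img.pixels.shape
    pos = np.asarray(positions, dtype=float)
    ix = np.clip(np.rint(pos[:, 0]).astype(np.intp), 0, W - 1)
    iy = np.clip(np.rint(pos[:, 1]).astype(np.intp), 0, H - 1)
    return img.pixels[iy, ix].astype(np.float64)
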