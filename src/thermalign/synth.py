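"""Synthetic annotated thermal-face generator.

Emulates the study acquisition protocol so that training and evaluation run
end-to-end with no external data: 7 subjects x 87 images by default, three
camera distances (60/90/120 cm, face widths about 184/126/97 px in a
640x480 frame), nine head directions at two amplitudes (20 deg "Small",
45 deg "Large") plus a free "Random" interval, and facial skin temperatures
inside the observed envelope (min 29.2-31.4, max 33.7-34.3, mean
31.9-33.0 degC over about 24 degC ambient).

Faces are rendered as a smooth temperature field over an elliptical face
region: warm inner canthi, forehead and mouth, a cool nose, a radially
cooling periphery, and Gaussian sensor noise (sigma 0.05 degC, the camera's
temperature resolution). Out-of-plane pose is approximated by anisotropic
cos-compression rather than 3-D projection, which keeps the landmark ground
truth exactly invertible. The generator stores the transform it applied, so
it is its own oracle: rendered landmarks equal the stored annotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, ValidationError
from .shapes import AnnotatedSample, BBox, default_mirror_map_68
from .thermal_io import (
    DatasetManifest,
    ManifestRecord,
    ThermalImage,
    write_landmarks,
    write_manifest,
    write_thermal_image,
)

TARGET_WIDTHS = {60: 184.0, 90: 126.0, 120: 97.0}

# nine head directions in protocol order: center, then clockwise from top
_DIRECTIONS = [
    (0, 0), (0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1)
]


def canonical_template_68() -> np.ndarray:
    """Fixed, bilaterally symmetric 68-point face layout in the unit frame.

    iBUG ordering: jaw 0-16, brows 17-26, nose bridge 27-30, nostril line
    31-35, eyes 36-47, outer mouth 48-59, inner mouth 60-67. The layout is
    exactly symmetric under the standard mirror map combined with x -> 1 - x.
    """
    pts = np.full((68, 2), np.nan)
    alpha = np.linspace(0.0, math.pi, 17)
    pts[0:17, 0] = 0.5 - 0.42 * np.cos(alpha)  # jaw arc, left temple to right
    pts[0:17, 1] = 0.40 + 0.52 * np.sin(alpha)
    pts[17:22] = np.column_stack(
        [[0.16, 0.22, 0.28, 0.34, 0.40], 0.30 - np.array([0.000, 0.025, 0.035, 0.030, 0.015])]
    )
    pts[27:31] = [[0.5, 0.32], [0.5, 0.39], [0.5, 0.46], [0.5, 0.53]]  # nose bridge
    pts[31:34] = [[0.41, 0.600], [0.455, 0.615], [0.5, 0.625]]  # nostril line
    pts[36:42] = [  # left eye
        [0.20, 0.355], [0.26, 0.330], [0.33, 0.330], [0.39, 0.355], [0.33, 0.380], [0.26, 0.380]
    ]
    pts[48] = [0.32, 0.760]  # mouth
    pts[49] = [0.385, 0.735]
    pts[50] = [0.45, 0.725]
    pts[51] = [0.5, 0.730]
    pts[55] = [0.615, 0.800]
    pts[56] = [0.555, 0.815]
    pts[57] = [0.5, 0.825]
    pts[60] = [0.36, 0.760]
    pts[61] = [0.435, 0.750]
    pts[62] = [0.5, 0.755]
    pts[65] = [0.565, 0.775]
    pts[66] = [0.5, 0.785]
    perm = default_mirror_map_68().as_array()
    for i in range(68):
        j = perm[i]
        if j > i:
            pts[j] = [1.0 - pts[i, 0], pts[i, 1]]
    assert np.all(np.isfinite(pts))
    return pts


@dataclass
class SubjectProfile:
    """Per-subject face geometry and skin-temperature parameters."""

    deformation: np.ndarray  # (68, 2) landmark offsets in the unit frame
    aspect: float = 1.0  # vertical stretch of the face
    t_min: float = 30.0  # coolest facial temperature, degC
    t_max: float = 34.0
    t_mean: float = 32.4
    ambient: float = 24.3

    def __post_init__(self) -> None:
        self.deformation = np.asarray(self.deformation, dtype=np.float64)
        if self.deformation.shape != (68, 2):
            raise ValidationError(f"deformation must be (68, 2), got {self.deformation.shape}")
        if not (self.t_min < self.t_mean < self.t_max):
            raise ValidationError(
                f"need t_min < t_mean < t_max, got {self.t_min}, {self.t_mean}, {self.t_max}"
            )

    @classmethod
    def default(cls) -> "SubjectProfile":
        return cls(deformation=np.zeros((68, 2)))


def sample_subject_profile(rng: np.random.Generator) -> SubjectProfile:
    """Draw a subject: small landmark deformations plus temperatures inside
    the study's observed envelope."""
    deform = rng.normal(0.0, 0.010, size=(68, 2))
    aspect = rng.uniform(0.95, 1.05)
    t_min = rng.uniform(29.2, 31.4)
    t_max = rng.uniform(33.7, 34.3)
    t_mean = rng.uniform(max(31.9, t_min + 0.3), min(33.0, t_max - 0.3))
    ambient = rng.uniform(24.0, 24.5)
    return SubjectProfile(deform, aspect, t_min, t_max, t_mean, ambient)


@dataclass
class ProtocolSpec:
    """Study layout: subjects, images, distances, sections, frame size, seed."""

    n_subjects: int = 7
    images_per_subject: int = 87
    distances: tuple = (60, 90, 120)
    target_widths: dict = field(default_factory=lambda: dict(TARGET_WIDTHS))
    small_amp: float = 20.0  # degrees
    large_amp: float = 45.0
    image_size: tuple = (640, 480)  # (width, height)
    noise_sd: float = 0.05  # camera temperature resolution, degC
    width_jitter: float = 0.08  # relative SD of the face-width draw
    seed: int = 0

    def validate(self) -> "ProtocolSpec":
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.images_per_subject < 1:
            raise ConfigError("images_per_subject must be >= 1")
        widths = [self.target_widths[d] for d in self.distances]
        if any(w <= 0 for w in widths):
            raise ConfigError("target widths must be positive")
        if any(widths[i] <= widths[i + 1] for i in range(len(widths) - 1)):
            raise ConfigError("target widths must decrease with distance")
        return self


@dataclass
class SynthFace:
    """A rendered sample plus its generation ground truth."""

    sample: AnnotatedSample
    pose: tuple  # (yaw, pitch, roll) degrees
    unit_shape: np.ndarray  # deformed template before pose/scale/placement
    scale: float
    translation: np.ndarray  # (2,)
    width_target: float

    def expected_landmarks(self) -> np.ndarray:
        """Recompute landmarks from the stored transform (the self-oracle)."""
        return _apply_pose(self.unit_shape, self.pose) * self.scale + self.translation


def _apply_pose(unit_shape: np.ndarray, pose: tuple) -> np.ndarray:
    yaw, pitch, roll = (math.radians(a) for a in pose)
    c = unit_shape.mean(axis=0)
    p = unit_shape - c
    p = p * np.array([math.cos(yaw), math.cos(pitch)])
    cr, sr = math.cos(roll), math.sin(roll)
    p = p @ np.array([[cr, sr], [-sr, cr]])
    return p


def render_face(
    profile: SubjectProfile,
    pose: tuple,
    distance_cm: int,
    image_size: tuple = (640, 480),
    rng: np.random.Generator | None = None,
    *,
    target_widths: dict | None = None,
    width_jitter: float = 0.08,
    noise_sd: float = 0.05,
    expression_sd: float = 0.0,
    center: tuple | None = None,
) -> SynthFace:
    """Render one annotated synthetic thermal face.

    The unit-frame template is deformed by the subject profile (plus optional
    expression jitter on mouth and brows), pose-compressed, scaled so the
    landmark x-extent hits the distance's target width (with relative
    jitter), and placed in the frame; the identical transform produces the
    stored ground-truth landmarks. The bbox is the landmark extent padded 10%.
    """
    yaw, pitch, roll = pose
    if abs(yaw) > 60 or abs(pitch) > 60:
        raise ValidationError(f"pose beyond +/-60 degrees: yaw={yaw}, pitch={pitch}")
    widths = dict(TARGET_WIDTHS if target_widths is None else target_widths)
    if distance_cm not in widths:
        raise ValidationError(f"unknown distance condition {distance_cm} cm")
    if rng is None:
        rng = np.random.default_rng()
    W, H = int(image_size[0]), int(image_size[1])

    template = canonical_template_68()
    unit = template + profile.deformation
    if expression_sd > 0:
        unit = unit.copy()
        unit[17:27] += rng.normal(0, expression_sd, (10, 2))  # brows
        unit[48:68] += rng.normal(0, expression_sd, (20, 2))  # mouth
    cy = unit[:, 1].mean()
    unit = unit.copy()
    unit[:, 1] = cy + (unit[:, 1] - cy) * profile.aspect

    posed = _apply_pose(unit, pose)
    width_target = widths[distance_cm]
    if width_jitter > 0:
        width_target *= 1.0 + float(np.clip(rng.normal(0, width_jitter), -0.25, 0.25))
    extent_x = posed[:, 0].max() - posed[:, 0].min()
    scale = width_target / extent_x
    lm = posed * scale

    if center is None:
        cx = W / 2 + rng.uniform(-0.05, 0.05) * W - 0.12 * width_target * math.sin(math.radians(yaw))
        cyp = H / 2 + rng.uniform(-0.05, 0.05) * H - 0.12 * width_target * math.sin(math.radians(pitch))
    else:
        cx, cyp = center
    translation = np.array([cx, cyp]) - lm.mean(axis=0)
    # keep the whole face (with bbox padding margin) inside the frame
    lo = lm.min(axis=0) + translation
    hi = lm.max(axis=0) + translation
    pad = 0.06 * (hi - lo)
    translation += np.maximum(0, (pad + 2) - lo) - np.maximum(0, hi - (np.array([W - 3, H - 3]) - pad))
    lm = lm + translation

    pixels = _render_temperature(lm, profile, pose, (H, W), rng, noise_sd)

    x0, y0 = lm.min(axis=0)
    x1, y1 = lm.max(axis=0)
    w, h = x1 - x0, y1 - y0
    bbox = BBox(x0 - 0.05 * w, y0 - 0.05 * h, 1.1 * w, 1.1 * h)
    image = ThermalImage(
        pixels,
        unit="celsius",
        meta={
            "subject": "", "distance": distance_cm, "pose": list(pose),
            "emissivity": 0.98, "ambient": profile.ambient,
        },
    )
    sample = AnnotatedSample(
        image=image, shape=lm, bbox=bbox, subject="", distance=int(distance_cm), section=""
    )
    return SynthFace(
        sample=sample, pose=tuple(pose), unit_shape=unit, scale=scale,
        translation=translation, width_target=width_target,
    )


def _solve_gamma(v: np.ndarray, target: float) -> float:
    """Monotone power remap exponent so that mean(v**gamma) == target."""
    lo, hi = 1e-3, 1e3
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        if float(np.mean(v**mid)) > target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def _render_temperature(
    lm: np.ndarray,
    profile: SubjectProfile,
    pose: tuple,
    hw: tuple,
    rng: np.random.Generator,
    noise_sd: float,
) -> np.ndarray:
    H, W = hw
    x0, y0 = lm.min(axis=0)
    x1, y1 = lm.max(axis=0)
    w, h = x1 - x0, y1 - y0
    cx, cyl = lm.mean(axis=0)

    # elliptical face region (forehead extends above the brow landmarks)
    ec = np.array([cx, cyl - 0.10 * h])
    a, b = 0.60 * w, 0.72 * h
    roll = math.radians(pose[2])
    cr, sr = math.cos(roll), math.sin(roll)

    ex0 = max(int(ec[0] - 1.3 * max(a, b)), 0)
    ex1 = min(int(ec[0] + 1.3 * max(a, b)) + 1, W)
    ey0 = max(int(ec[1] - 1.3 * max(a, b)), 0)
    ey1 = min(int(ec[1] + 1.3 * max(a, b)) + 1, H)
    yy, xx = np.mgrid[ey0:ey1, ex0:ex1]
    dx = xx - ec[0]
    dy = yy - ec[1]
    xr = cr * dx + sr * dy
    yr = -sr * dx + cr * dy
    mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    brows = lm[17:27].mean(axis=0)
    bumps = [  # (position, amplitude, sigma): warm canthi/forehead, cool nose
        (np.array([cx, cyl]), +0.50, 0.50 * w),
        (brows + np.array([0.0, -0.35 * h]), +0.90, 0.40 * w),
        (lm[39], +0.90, 0.07 * w),
        (lm[42], +0.90, 0.07 * w),
        (lm[30], -1.20, 0.11 * w),
        (lm[33], -0.60, 0.08 * w),
        ((lm[2] + lm[31]) / 2, +0.35, 0.18 * w),
        ((lm[14] + lm[35]) / 2, +0.35, 0.18 * w),
        ((lm[51] + lm[57]) / 2, +0.45, 0.09 * w),
        (lm[8], -0.30, 0.12 * w),
    ]
    g = np.zeros(mask.shape)
    for pos, amp, sig in bumps:
        r2 = (xx - pos[0]) ** 2 + (yy - pos[1]) ** 2
        g += amp * np.exp(-r2 / (2.0 * sig**2))

    pixels = np.full((H, W), profile.ambient)
    if mask.any():
        gm = g[mask]
        lo, hi = gm.min(), gm.max()
        v = (gm - lo) / (hi - lo) if hi > lo else np.zeros_like(gm)
        frac = (profile.t_mean - profile.t_min) / (profile.t_max - profile.t_min)
        gamma = _solve_gamma(v[::7] if v.size > 7000 else v, frac)
        temps = profile.t_min + (profile.t_max - profile.t_min) * v**gamma
        window = pixels[ey0:ey1, ex0:ex1]
        window[mask] = temps
    pixels += rng.normal(0.0, noise_sd, size=(H, W))
    return pixels.astype(np.float32)


def _allocate_sections(m: int) -> tuple[int, int, int]:
    """Split a per-distance image budget into Small/Large/Random counts.

    The study's 87 images per subject decompose as 3 distances x 29 with
    9 Small + 9 Large + 11 Random at each distance; the rule generalizes that
    allocation to other budgets (directions first, Random takes the rest).
    """
    small = min(9, m)
    large = min(9, m - small)
    return small, large, m - small - large


def generate_study(spec: ProtocolSpec | None = None, out_dir=None) -> list[AnnotatedSample]:
    """Generate the full synthetic study, optionally writing it to disk.

    Per subject, images are allocated across the three distances as evenly as
    possible; at each distance the Small and Large sections cycle the nine
    head directions at 20/45 degree amplitude and the Random section draws
    uniform poses within +/-45 degrees with expression jitter. A fixed seed
    yields a byte-identical dataset.
    """
    if spec is None:
        spec = ProtocolSpec()
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    subject_seeds = root.spawn(spec.n_subjects)

    samples: list[AnnotatedSample] = []
    for si in range(spec.n_subjects):
        subject = f"S{si + 1}"
        srng = np.random.default_rng(subject_seeds[si])
        profile = sample_subject_profile(srng)
        nd = len(spec.distances)
        base, rem = divmod(spec.images_per_subject, nd)
        per_distance = [base + (1 if i < rem else 0) for i in range(nd)]
        for distance, m in zip(spec.distances, per_distance):
            n_small, n_large, n_random = _allocate_sections(m)
            plan = (
                [("Small", _DIRECTIONS[i % 9], spec.small_amp) for i in range(n_small)]
                + [("Large", _DIRECTIONS[i % 9], spec.large_amp) for i in range(n_large)]
                + [("Random", None, None)] * n_random
            )
            for idx, (section, direction, amp) in enumerate(plan):
                if direction is not None:
                    pose = (direction[0] * amp, direction[1] * amp, 0.0)
                    expr = 0.0
                else:
                    pose = (srng.uniform(-45, 45), srng.uniform(-45, 45), srng.uniform(-10, 10))
                    expr = 0.01
                face = render_face(
                    profile, pose, distance, spec.image_size, srng,
                    target_widths=spec.target_widths, width_jitter=spec.width_jitter,
                    noise_sd=spec.noise_sd, expression_sd=expr,
                )
                s = face.sample
                s.subject = subject
                s.section = section
                s.sample_id = f"{subject}_{distance}_{section}_{idx:03d}"
                s.image.meta["subject"] = subject
                s.image.meta["section"] = section
                samples.append(s)

    if out_dir is not None:
        write_study(samples, out_dir)
    return samples


def write_study(samples, out_dir, image_format: str = "tiff16") -> DatasetManifest:
    """Write images, pts files and a manifest CSV for a generated study."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ext = {"csv": ".csv", "tiff16": ".tif", "png8": ".png"}[image_format]
    records = []
    for s in samples:
        stem = s.sample_id or f"img{len(records):05d}"
        img_name, pts_name = stem + ext, stem + ".pts"
        write_thermal_image(s.image, out / img_name, image_format)
        write_landmarks(s.shape, out / pts_name)
        records.append(
            ManifestRecord(
                image=img_name, pts=pts_name,
                bx=s.bbox.x, by=s.bbox.y, bw=s.bbox.w, bh=s.bbox.h,
                subject=s.subject, distance=s.distance, section=s.section,
            )
        )
    manifest = DatasetManifest(records)
    write_manifest(manifest, out / "manifest.csv")
    return manifest
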