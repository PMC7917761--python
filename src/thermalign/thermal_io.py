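"""File I/O: thermal images, pts landmark files, dataset manifests, model archives.

Supported image carriers
------------------------
``csv``
    Plain matrix of comma-separated reals, one row per pixel row, values in
    degrees Celsius.
``tiff16``
    16-bit grayscale TIFF holding raw counts; temperature is recovered as
    ``raw * scale + offset`` with the linear map stored in the TIFF
    description tag (defaults: scale 0.01, offset 0).
``png8``
    8-bit grayscale PNG treated as pre-normalized intensity in [0, 255].

Landmarks use the iBUG pts dialect (1-based coordinates on disk, converted to
the package's 0-based pixel-center convention on read/write). Manifests are
CSV with named columns ``image,pts,bx,by,bw,bh,subject,distance,section``.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ModelIOError, ValidationError, DataError

if TYPE_CHECKING:  # pragma: no cover
    from .regressor import CSRModel
    from .shapes import AnnotatedSample

MODEL_FORMAT_VERSION = "thermalign-csr-1"

_CELSIUS_SANITY = (-20.0, 60.0)

MANIFEST_COLUMNS = ["image", "pts", "bx", "by", "bw", "bh", "subject", "distance", "section"]


@dataclass
class ThermalImage:
    """A 2-D temperature (or pre-normalized intensity) matrix with metadata."""

    pixels: np.ndarray  # (H, W) float32
    unit: str = "celsius"  # "celsius" | "intensity"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValidationError(f"pixels must be a 2-D matrix, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            bad = np.argwhere(~np.isfinite(self.pixels))[0]
            raise ValidationError(f"non-finite pixel at row {bad[0]}, col {bad[1]}")
        if self.unit not in ("celsius", "intensity"):
            raise ValidationError(f"unknown unit {self.unit!r}")
        if self.unit == "celsius":
            lo, hi = _CELSIUS_SANITY
            mn, mx = float(self.pixels.min()), float(self.pixels.max())
            if mn < lo or mx > hi:
                raise ValidationError(
                    f"temperature out of sanity range [{lo}, {hi}] degC: min={mn}, max={mx}"
                )

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class ManifestRecord:
    image: str
    pts: str
    bx: float
    by: float
    bw: float
    bh: float
    subject: str
    distance: int
    section: str

    def __post_init__(self) -> None:
        if not (self.bw > 0 and self.bh > 0):
            raise ValidationError(f"manifest bbox extent must be positive: {self}")
        if not str(self.subject):
            raise ValidationError("manifest subject id must be non-empty")


@dataclass
class DatasetManifest:
    """Ordered list of dataset records, round-tripped as a named-column CSV."""

    records: list[ManifestRecord]

    def __len__(self) -> int:
        return len(self.records)


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        if format not in ("csv", "tiff16", "png8"):
            raise FormatError(f"unknown image format {format!r}")
        return format
    suffix = path.suffix.lower()
    table = {".csv": "csv", ".tif": "tiff16", ".tiff": "tiff16", ".png": "png8"}
    if suffix not in table:
        raise FormatError(f"cannot infer image format from extension {suffix!r}")
    return table[suffix]


def read_thermal_image(path, format: str | None = None) -> ThermalImage:
    """Read a thermal image from csv / tiff16 / png8.

    CSV is parsed as rows of comma-separated reals in degrees Celsius; tiff16
    is decoded through its declared linear scale/offset to Celsius; png8 is
    loaded as intensity in [0, 255].
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"image file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "csv":
        try:
            rows = [line.split(",") for line in path.read_text().strip().splitlines()]
            widths = {len(r) for r in rows}
            if len(widths) != 1:
                raise FormatError(f"ragged CSV rows in {path}: widths {sorted(widths)}")
            arr = np.array([[float(tok) for tok in r] for r in rows], dtype=np.float64)
        except FormatError:
            raise
        except ValueError as exc:
            raise FormatError(f"non-numeric cell in {path}: {exc}") from exc
        except OSError as exc:
            raise DataError(f"cannot read {path}: {exc}") from exc
        nan = np.argwhere(np.isnan(arr))
        if nan.size:
            raise ValidationError(f"NaN cell in {path} at row {nan[0][0]}, col {nan[0][1]}")
        return ThermalImage(arr, unit="celsius", meta={"source": str(path), "format": "csv"})
    if fmt == "tiff16":
        try:
            with tifffile.TiffFile(path) as tif:
                raw = tif.asarray()
                desc = tif.pages[0].description or ""
        except (tifffile.TiffFileError, OSError, ValueError) as exc:
            raise DataError(f"cannot read TIFF {path}: {exc}") from exc
        scale, offset = 0.01, 0.0
        try:
            info = json.loads(desc) if desc else {}
            scale = float(info.get("scale", scale))
            offset = float(info.get("offset", offset))
        except (json.JSONDecodeError, TypeError, ValueError):
            pass  # absent/foreign description -> defaults
        celsius = raw.astype(np.float64) * scale + offset
        return ThermalImage(
            celsius,
            unit="celsius",
            meta={"source": str(path), "format": "tiff16", "scale": scale, "offset": offset},
        )
    # png8
    try:
        arr = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise DataError(f"cannot read PNG {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    return ThermalImage(arr.astype(np.float64), unit="intensity", meta={"source": str(path), "format": "png8"})


def write_thermal_image(
    img: ThermalImage,
    path,
    format: str | None = None,
    *,
    scale: float = 0.01,
    offset: float = 0.0,
    decimals: int = 6,
) -> None:
    """Write a thermal image; inverse of :func:`read_thermal_image` within quantization."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        fmtstr = f"%.{decimals}f"
        with open(path, "w") as fh:
            for row in img.pixels:
                fh.write(",".join(fmtstr % v for v in row) + "\n")
    elif fmt == "tiff16":
        raw = np.rint((img.pixels.astype(np.float64) - offset) / scale)
        raw = np.clip(raw, 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, raw, description=json.dumps({"scale": scale, "offset": offset}))
    else:  # png8
        if img.unit == "intensity":
            arr = np.clip(np.rint(img.pixels), 0, 255).astype(np.uint8)
        else:
            lo, hi = float(img.pixels.min()), float(img.pixels.max())
            span = hi - lo if hi > lo else 1.0
            arr = np.rint((img.pixels - lo) / span * 255).astype(np.uint8)
        iio.imwrite(path, arr)


def read_landmarks(path) -> np.ndarray:
    """Read an iBUG-style pts file, returning (M, 2) 0-based coordinates."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"pts file not found: {path}")
    lines = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    try:
        if not lines[0].startswith("version"):
            raise FormatError(f"{path}: missing 'version' header")
        n_points = int(lines[1].split(":")[1])
        if lines[2] != "{" or lines[-1] != "}":
            raise FormatError(f"{path}: missing braces around point block")
        body = lines[3:-1]
    except (IndexError, ValueError) as exc:
        raise FormatError(f"{path}: malformed pts header: {exc}") from exc
    if len(body) != n_points:
        raise FormatError(f"{path}: header declares {n_points} points but file has {len(body)}")
    coords = np.empty((n_points, 2), dtype=np.float64)
    for i, ln in enumerate(body):
        toks = ln.split()
        if len(toks) != 2:
            raise FormatError(f"{path}: line {i + 4} is not 'x y': {ln!r}")
        try:
            coords[i] = [float(toks[0]), float(toks[1])]
        except ValueError as exc:
            raise FormatError(f"{path}: non-numeric token on line {i + 4}: {ln!r}") from exc
    return coords - 1.0  # pts dialect is 1-based


def write_landmarks(shape: np.ndarray, path) -> None:
    """Write landmarks as a pts file (converted to the dialect's 1-based origin)."""
    coords = np.asarray(shape, dtype=float) + 1.0
    with open(path, "w") as fh:
        fh.write("version: 1\n")
        fh.write(f"n_points: {coords.shape[0]}\n")
        fh.write("{\n")
        for x, y in coords:
            fh.write(f"{x:.6f} {y:.6f}\n")
        fh.write("}\n")


def read_manifest(path) -> DatasetManifest:
    path = Path(path)
    if not path.exists():
        raise DataError(f"manifest not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"subject": str, "section": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise FormatError(f"cannot parse manifest {path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {path} missing columns: {missing}")
    records = [
        ManifestRecord(
            image=str(r.image), pts=str(r.pts),
            bx=float(r.bx), by=float(r.by), bw=float(r.bw), bh=float(r.bh),
            subject=str(r.subject), distance=int(r.distance), section=str(r.section),
        )
        for r in df.itertuples(index=False)
    ]
    return DatasetManifest(records)


def write_manifest(manifest: DatasetManifest, path) -> None:
    df = pd.DataFrame([vars(r) for r in manifest.records], columns=MANIFEST_COLUMNS)
    df.to_csv(path, index=False)


def load_dataset(manifest: DatasetManifest, base_dir=None) -> "list[AnnotatedSample]":
    """Materialize one AnnotatedSample per manifest record, preserving order."""
    from .shapes import AnnotatedSample, BBox  # local import avoids a cycle

    base = Path(base_dir) if base_dir is not None else Path(".")
    samples: list[AnnotatedSample] = []
    for i, rec in enumerate(manifest.records):
        try:
            img = read_thermal_image(base / rec.image)
            shape = read_landmarks(base / rec.pts)
            bbox = BBox(rec.bx, rec.by, rec.bw, rec.bh)
        except (DataError, FormatError, ValidationError) as exc:
            raise DataError(f"manifest record {i} ({rec.image}): {exc}") from exc
        samples.append(
            AnnotatedSample(
                image=img, shape=shape, bbox=bbox, subject=rec.subject,
                distance=rec.distance, section=rec.section,
                sample_id=f"{rec.subject}:{Path(rec.image).stem}",
            )
        )
    return samples


def save_model(model: "CSRModel", path) -> None:
    """Serialize a trained cascade to a single self-describing .npz archive."""
    arrays: dict[str, np.ndarray] = {
        "format_version": np.array(MODEL_FORMAT_VERSION),
        "config": np.array(json.dumps(model.config)),
        "mean": model.mean,
        "n_stages": np.array(len(model.stages)),
        "M": np.array(model.M),
    }
    for t, stage in enumerate(model.stages):
        arrays[f"stage{t}_anchors"] = stage.pool.anchors
        arrays[f"stage{t}_offsets"] = stage.pool.offsets
        arrays[f"stage{t}_u"] = np.stack([tr.u for tr in stage.trees])
        arrays[f"stage{t}_v"] = np.stack([tr.v for tr in stage.trees])
        arrays[f"stage{t}_theta"] = np.stack([tr.theta for tr in stage.trees])
        arrays[f"stage{t}_leaves"] = np.stack([tr.leaves for tr in stage.trees])
        arrays[f"stage{t}_shrinkage"] = np.array(stage.shrinkage)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> "CSRModel":
    """Load a model archive; predictions are bitwise-identical after a round trip."""
    from .features import FeaturePool
    from .regressor import CascadeStage, CSRModel, RegressionTree

    path = Path(path)
    if not path.exists():
        raise ModelIOError(f"model file not found: {path}")
    try:
        with np.load(path, allow_pickle=False) as z:
            version = str(z["format_version"])
            if version != MODEL_FORMAT_VERSION:
                raise ModelIOError(
                    f"incompatible model format {version!r}; expected {MODEL_FORMAT_VERSION!r}"
                )
            config = json.loads(str(z["config"]))
            mean = z["mean"]
            n_stages = int(z["n_stages"])
            stages = []
            for t in range(n_stages):
                pool = FeaturePool(anchors=z[f"stage{t}_anchors"], offsets=z[f"stage{t}_offsets"], stage=t)
                u, v = z[f"stage{t}_u"], z[f"stage{t}_v"]
                theta, leaves = z[f"stage{t}_theta"], z[f"stage{t}_leaves"]
                trees = [
                    RegressionTree(u=u[k], v=v[k], theta=theta[k], leaves=leaves[k])
                    for k in range(u.shape[0])
                ]
                stages.append(CascadeStage(pool=pool, trees=trees, shrinkage=float(z[f"stage{t}_shrinkage"])))
    except ModelIOError:
        raise
    except (zipfile.BadZipFile, KeyError, OSError, ValueError) as exc:
        raise ModelIOError(f"cannot load model {path}: {exc}") from exc
    return CSRModel(mean=mean, stages=stages, config=config)
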