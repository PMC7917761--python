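"""Alignment evaluation: NPPE, CED curves, subject-wise CV, FPS benchmarking.

The normalized point-to-point error of an image is the mean Euclidean
distance between predicted and ground-truth landmarks divided by the mean of
the face's width and height,

    NPPE = (1/N) * sum_n ||p_n - g_n||  /  ((w + h) / 2),

which makes errors comparable across camera distances. 0.05 is the
conventional acceptability threshold. Face extent is taken from the
ground-truth landmark cloud by default (annotation-tool independent), with an
option to use the manifest bounding box instead.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .config import TrainConfig
from .errors import ValidationError
from .shapes import AnnotatedSample, as_shape, flip_dataset, shape_extent
from .regressor import CSRModel, predict, predict_trace, train_csr

__all__ = [
    "nppe",
    "ced",
    "CEDCurve",
    "FoldPlan",
    "NPPEReport",
    "subject_kfold",
    "pixels_per_face_width",
    "evaluate_fold",
    "evaluate_cv",
    "benchmark_fps",
]


def nppe(pred: np.ndarray, gt: np.ndarray, face_w: float, face_h: float) -> float:
    """Normalized point-to-point error of one image (a fraction of face size)."""
    p = as_shape(pred)
    g = as_shape(gt)
    if p.shape != g.shape:
        raise ValidationError(f"landmark count mismatch: {p.shape} vs {g.shape}")
    if not (face_w > 0 and face_h > 0):
        raise ValidationError(f"face extent must be positive, got w={face_w}, h={face_h}")
    dists = np.linalg.norm(p - g, axis=1)
    return float(dists.mean() / (0.5 * (face_w + face_h)))


@dataclass(frozen=True)
class CEDCurve:
    """Cumulative error distribution: fraction of images at or below each threshold."""

    thresholds: np.ndarray
    fractions: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fraction": self.fractions})


def ced(errors: Sequence[float], thresholds: Sequence[float]) -> CEDCurve:
    """Fraction of per-image errors <= tau for each threshold tau."""
    errs = np.asarray(errors, dtype=float)
    if errs.size == 0:
        raise ValidationError("ced needs at least one error value")
    taus = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(taus) < 0):
        raise ValidationError("thresholds must be sorted ascending")
    fracs = np.array([(errs <= t).mean() for t in taus])
    return CEDCurve(thresholds=taus, fractions=fracs)


@dataclass(frozen=True)
class FoldPlan:
    """Leave-one-subject-out folds: (train subject ids, test subject id) pairs."""

    folds: tuple

    def __len__(self) -> int:
        return len(self.folds)


def subject_kfold(dataset: Sequence[AnnotatedSample]) -> FoldPlan:
    """One fold per subject; train and test sets are subject-disjoint.

    Flipped copies carry their original subject id, so augmentation can never
    leak a subject across the train/test boundary.
    """
    subjects = sorted({s.subject for s in dataset})
    if len(subjects) < 2:
        raise ValidationError("subject-wise CV needs at least two subjects")
    folds = tuple(
        (tuple(sub for sub in subjects if sub != test), test) for test in subjects
    )
    return FoldPlan(folds=folds)


def pixels_per_face_width(sample: AnnotatedSample) -> int:
    """Face width in pixels: x-extent of the ground-truth landmarks, rounded."""
    w, _ = shape_extent(sample.shape)
    return int(round(w))


@dataclass
class NPPEReport:
    """Per-image NPPE values with overall and per-distance summaries."""

    per_image: pd.DataFrame  # sample_id, subject, distance, section, nppe, face_width_px, fold
    stage_curves: pd.DataFrame | None = None  # fold, stage, mean_nppe
    meta: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(self.per_image["nppe"].mean())

    @property
    def sd(self) -> float:
        return float(self.per_image["nppe"].std(ddof=1)) if len(self.per_image) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "n_images": int(len(self.per_image)),
            "mean_nppe": self.mean,
            "sd_nppe": self.sd,
            "mean_nppe_percent": 100.0 * self.mean,
        }

    def by_distance(self) -> pd.DataFrame:
        """Per-distance mean +/- SD of NPPE and mean pixels per face width."""
        g = self.per_image.groupby("distance")
        out = g.agg(
            n=("nppe", "size"),
            face_width_px=("face_width_px", "mean"),
            mean_nppe=("nppe", "mean"),
            sd_nppe=("nppe", "std"),
        ).reset_index()
        out["mean_nppe_percent"] = 100.0 * out["mean_nppe"]
        return out

    def ced(self, thresholds: Sequence[float] | None = None) -> CEDCurve:
        if thresholds is None:
            thresholds = np.linspace(0.0, 0.2, 81)
        return ced(self.per_image["nppe"].to_numpy(), thresholds)


def _face_norm(sample: AnnotatedSample, use_bbox: bool) -> tuple[float, float]:
    if use_bbox:
        return sample.bbox.w, sample.bbox.h
    return shape_extent(sample.shape)


def evaluate_fold(
    model: CSRModel | None,
    test: Sequence[AnnotatedSample],
    *,
    predictor: Callable[[AnnotatedSample], np.ndarray] | None = None,
    use_bbox_norm: bool = False,
    fold: str = "",
    collect_stage_curves: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Score one test split, optionally with an externally supplied predictor."""
    if model is None and predictor is None:
        raise ValidationError("either a model or a predictor is required")
    rows = []
    stage_errs: list[np.ndarray] | None = [] if collect_stage_curves else None
    for s in test:
        w, h = _face_norm(s, use_bbox_norm)
        if predictor is not None:
            pred = predictor(s)
        elif collect_stage_curves:
            trace = predict_trace(model, s.image, s.bbox)
            pred = trace[-1]
            stage_errs.append(np.array([nppe(p, s.shape, w, h) for p in trace]))
        else:
            pred = predict(model, s.image, s.bbox)
        rows.append(
            {
                "sample_id": s.sample_id,
                "subject": s.subject,
                "distance": s.distance,
                "section": s.section,
                "nppe": nppe(pred, s.shape, w, h),
                "face_width_px": pixels_per_face_width(s),
                "fold": fold,
            }
        )
    per_image = pd.DataFrame(rows)
    stage_df = None
    if collect_stage_curves and stage_errs:
        means = np.stack(stage_errs).mean(axis=0)
        stage_df = pd.DataFrame(
            {"fold": fold, "stage": np.arange(means.size), "mean_nppe": means}
        )
    return per_image, stage_df


def evaluate_cv(
    dataset: Sequence[AnnotatedSample],
    config: TrainConfig | dict | None = None,
    *,
    augment_flip: bool = True,
    include_flipped_tests: bool = False,
    use_bbox_norm: bool = False,
    predictor: Callable[[AnnotatedSample], np.ndarray] | None = None,
    collect_stage_curves: bool = False,
    return_models: bool = False,
):
    """Subject-wise k-fold cross-validation of the full train/evaluate protocol.

    For each fold, a model is trained on all other subjects (with flip
    augmentation by default) and scored on the held-out subject. By default
    the test set contains original images only, so mirrored duplicates are
    not double-counted. An injected ``predictor`` bypasses training (used for
    harness checks).
    """
    originals = [s for s in dataset if not s.flipped]
    plan = subject_kfold(originals)
    frames, stage_frames, models = [], [], {}
    for train_subjects, test_subject in plan.folds:
        train = [s for s in dataset if s.subject != test_subject]
        if augment_flip:
            train = flip_dataset([s for s in train if not s.flipped])
        test = [s for s in dataset if s.subject == test_subject]
        if not include_flipped_tests:
            test = [s for s in test if not s.flipped]
        model = None
        if predictor is None:
            model = train_csr(train, config)
            if return_models:
                models[test_subject] = model
        per_image, stage_df = evaluate_fold(
            model, test, predictor=predictor, use_bbox_norm=use_bbox_norm,
            fold=test_subject, collect_stage_curves=collect_stage_curves,
        )
        frames.append(per_image)
        if stage_df is not None:
            stage_frames.append(stage_df)
    report = NPPEReport(
        per_image=pd.concat(frames, ignore_index=True),
        stage_curves=pd.concat(stage_frames, ignore_index=True) if stage_frames else None,
        meta={"k": len(plan), "augment_flip": augment_flip,
              "include_flipped_tests": include_flipped_tests},
    )
    if return_models:
        return report, models
    return report


def benchmark_fps(model: CSRModel, samples: Sequence[AnnotatedSample], repetitions: int = 3) -> dict:
    """Wall-clock prediction throughput (predictions per second).

    Timing covers :func:`thermalign.regressor.predict` only — model loading
    and dataset I/O are excluded. Hardware-dependent; reported, never gated.
    """
    if len(samples) == 0:
        raise ValidationError("benchmark needs at least one sample")
    # warm-up outside the timed region
    predict(model, samples[0].image, samples[0].bbox)
    t0 = time.perf_counter()
    n = 0
    for _ in range(repetitions):
        for s in samples:
            predict(model, s.image, s.bbox)
            n += 1
    elapsed = time.perf_counter() - t0
    return {
        "fps": n / elapsed if elapsed > 0 else float("inf"),
        "n_predictions": n,
        "elapsed_s": elapsed,
        "repetitions": repetitions,
    }
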