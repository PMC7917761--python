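"""NPPE metric, CED curves, subject-wise CV, stratified summaries, FPS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thermalign as ta
from thermalign.errors import ValidationError


class TestNPPE:
    def test_perfect_prediction_is_zero(self, rng):
        s = rng.uniform(0, 100, (68, 2))
        assert ta.nppe(s, s, 100, 120) == 0.0

    def test_uniform_offset_hand_value(self, rng):
        # every landmark off by (3, 4): mean point error 5; face 100x100 -> 0.05
        gt = rng.uniform(0, 100, (68, 2))
        assert ta.nppe(gt + [3, 4], gt, 100, 100) == pytest.approx(0.05, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), factor=st.floats(0.1, 10.0))
    def test_scale_invariance(self, seed, factor):
        """Rescaling shapes and face extents together leaves NPPE unchanged."""
        r = np.random.default_rng(seed)
        gt = r.uniform(0, 100, (20, 2))
        pred = gt + r.normal(0, 2, (20, 2))
        a = ta.nppe(pred, gt, 80, 90)
        b = ta.nppe(pred * factor, gt * factor, 80 * factor, 90 * factor)
        assert a == pytest.approx(b, rel=1e-9)

    def test_translation_invariance(self, rng):
        gt = rng.uniform(0, 100, (68, 2))
        pred = gt + rng.normal(0, 1, (68, 2))
        assert ta.nppe(pred, gt, 90, 95) == pytest.approx(
            ta.nppe(pred + [40, -17], gt + [40, -17], 90, 95), rel=1e-12
        )

    def test_invalid_inputs(self, rng):
        s = rng.uniform(0, 1, (68, 2))
        with pytest.raises(ValidationError):
            ta.nppe(s[:60], s, 10, 10)
        with pytest.raises(ValidationError):
            ta.nppe(s, s, 0, 10)


class TestCED:
    def test_hand_values(self):
        assert ta.ced([0.01] * 5, [0.05]).fractions[0] == 1.0
        assert ta.ced([0.01, 0.10], [0.05]).fractions[0] == 0.5
        assert ta.ced([0.02, 0.03], [0.001]).fractions[0] == 0.0

    def test_curve_is_nondecreasing_and_reaches_one(self, rng):
        errs = rng.uniform(0, 0.2, 100)
        curve = ta.ced(errs, np.linspace(0, 1, 50))
        assert np.all(np.diff(curve.fractions) >= 0)
        assert curve.fractions[-1] == 1.0

    def test_empty_errors_rejected(self):
        with pytest.raises(ValidationError):
            ta.ced([], [0.05])


class TestSubjectKFold:
    def test_one_fold_per_subject_and_partition(self, tiny_study):
        plan = ta.subject_kfold(tiny_study)
        subjects = sorted({s.subject for s in tiny_study})
        assert len(plan) == len(subjects)
        assert sorted(test for _, test in plan.folds) == subjects
        for train_subjects, test_subject in plan.folds:
            assert test_subject not in train_subjects
            assert set(train_subjects) | {test_subject} == set(subjects)

    def test_no_leakage_with_flips(self, tiny_study):
        augmented = ta.flip_dataset(tiny_study)
        plan = ta.subject_kfold(augmented)
        for train_subjects, test_subject in plan.folds:
            train = [s for s in augmented if s.subject in train_subjects]
            test = [s for s in augmented if s.subject == test_subject]
            assert {s.subject for s in train}.isdisjoint({s.subject for s in test})

    def test_single_subject_rejected(self, tiny_study):
        only = [s for s in tiny_study if s.subject == "S1"]
        with pytest.raises(ValidationError):
            ta.subject_kfold(only)


class TestPixelsPerFaceWidth:
    def test_span_convention(self, tiny_study):
        s = tiny_study[0]
        shape = s.shape.copy()
        shape[:, 0] = np.linspace(100, 284, 68)
        sample = ta.AnnotatedSample(s.image, shape, s.bbox, s.subject, s.distance, s.section)
        assert ta.pixels_per_face_width(sample) == 184

    def test_halving_scale_halves_width(self, tiny_study):
        s = tiny_study[0]
        w = ta.pixels_per_face_width(s)
        half = ta.AnnotatedSample(s.image, s.shape * 0.5, s.bbox, s.subject, s.distance, s.section)
        assert abs(ta.pixels_per_face_width(half) - w / 2) <= 1


class TestEvaluateCV:
    def test_perfect_oracle_gives_all_zeros(self, tiny_study):
        report = ta.evaluate_cv(tiny_study, predictor=lambda s: s.shape.copy())
        assert (report.per_image["nppe"] == 0).all()
        assert report.mean == 0.0 and report.sd == 0.0

    def test_per_image_count_covers_all_originals(self, tiny_study):
        report = ta.evaluate_cv(tiny_study, predictor=lambda s: s.shape.copy())
        assert len(report.per_image) == len([s for s in tiny_study if not s.flipped])
        assert report.meta["k"] == len({s.subject for s in tiny_study})

    def test_summary_matches_per_image_column(self, tiny_study):
        report = ta.evaluate_cv(
            tiny_study, predictor=lambda s: s.shape + [1.0, 0.0]
        )
        assert report.mean == pytest.approx(report.per_image["nppe"].mean())
        by_d = report.by_distance()
        assert set(by_d["distance"]) == {60, 90, 120}
        assert by_d["n"].sum() == len(report.per_image)

    def test_trained_cv_at_tiny_config(self, tiny_study):
        """The full train/evaluate loop runs per fold and beats initialization."""
        cfg = ta.TrainConfig(T=2, K=10, F=3, P=40, n_candidates=40, seed=2)
        report = ta.evaluate_cv(tiny_study, cfg, collect_stage_curves=True)
        assert len(report.per_image) == len(tiny_study)
        assert report.stage_curves is not None
        # stage 0 of each curve is the mean-shape initialization
        for _, grp in report.stage_curves.groupby("fold"):
            assert len(grp) == cfg.T + 1
            assert (grp["mean_nppe"] >= 0).all()
        # with bbox-driven initialization the held-out error stays moderate
        # even at this deliberately tiny configuration
        assert report.mean < 0.2


class TestBenchmark:
    def test_reports_positive_throughput(self, tiny_model, tiny_study):
        result = ta.benchmark_fps(tiny_model, tiny_study[:3], repetitions=2)
        assert result["fps"] > 0
        assert result["n_predictions"] == 6

    def test_needs_samples(self, tiny_model):
        with pytest.raises(ValidationError):
            ta.benchmark_fps(tiny_model, [])
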