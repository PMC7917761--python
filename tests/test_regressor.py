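"""Tree fitting, stage boosting, cascade training and prediction."""

import numpy as np
import pytest

import thermalign as ta
from thermalign.errors import ConfigError, ValidationError
from thermalign.regressor import fit_tree, midpoint_candidate_grid, tree_apply


def _sse(res):
    if len(res) == 0:
        return 0.0
    m = res.mean(axis=0)
    return float(((res - m) ** 2).sum())


def brute_force_tree_loss(res, fv, depth):
    """Independent oracle: greedy exhaustive best-split search.

    At each node every probe pair is crossed with every midpoint threshold
    and the split minimizing the children's within-node sum of squares is
    taken; returns the total squared error after fitting leaf means.
    """

    def best_split(idx):
        best = None
        d_all = fv[idx]
        for u in range(fv.shape[1]):
            for v in range(u + 1, fv.shape[1]):
                d = d_all[:, u] - d_all[:, v]
                vals = np.unique(d)
                for th in (vals[:-1] + vals[1:]) / 2.0:
                    left, right = idx[d <= th], idx[d > th]
                    sse = _sse(res[left]) + _sse(res[right])
                    if best is None or sse < best[0]:
                        best = (sse, left, right)
        return best

    def grow(idx, level):
        if level == depth or idx.size == 0:
            return _sse(res[idx]) if idx.size else 0.0
        found = best_split(idx)
        if found is None:  # nothing separates the node
            return _sse(res[idx])
        _, left, right = found
        return grow(left, level + 1) + grow(right, level + 1)

    return grow(np.arange(len(res)), 0)


class TestFitTree:
    def test_single_sample_leaf_is_shrunk_residual(self, rng):
        res = rng.normal(size=(1, 6))
        fv = rng.uniform(size=(1, 4))
        tree = fit_tree(res, fv, depth=3, n_candidates=10, shrinkage=0.1, rng=rng)
        out = tree_apply(tree, fv)
        assert np.allclose(out, 0.1 * res)

    def test_two_separable_samples_depth_one(self, rng):
        r = np.array([1.0, -2.0, 0.5])
        res = np.stack([r, -r])
        fv = np.array([[0.0, 0.0], [1.0, 0.0]])
        tree = fit_tree(res, fv, depth=1, n_candidates=200, shrinkage=0.5, rng=rng)
        out = tree_apply(tree, fv)
        assert np.allclose(out, 0.5 * res)  # leaves are +nu*r and -nu*r

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_exhaustive_grid_matches_brute_force(self, seed):
        """Forcing the candidate set to the full pair x midpoint grid reproduces
        the loss of an independent exhaustive best-split search."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        res = rng.normal(size=(n, 4))
        fv = rng.uniform(size=(n, 6))
        tree = fit_tree(
            res, fv, depth=2, shrinkage=1.0, rng=np.random.default_rng(0),
            candidates=midpoint_candidate_grid,
        )
        loss = float(((res - tree_apply(tree, fv)) ** 2).sum())
        assert loss == pytest.approx(brute_force_tree_loss(res, fv, depth=2), abs=1e-9)

    def test_invalid_inputs(self, rng):
        with pytest.raises(ValidationError):
            fit_tree(np.empty((0, 4)), np.empty((0, 3)), rng=rng)
        with pytest.raises(ConfigError):
            fit_tree(rng.normal(size=(3, 4)), rng.uniform(size=(3, 3)), depth=0, rng=rng)


class TestFitStage:
    @pytest.fixture()
    def stage_inputs(self, tiny_study):
        samples = tiny_study[:12]
        mean = ta.mean_shape([s.shape for s in samples], [s.bbox for s in samples])
        cur = np.stack([ta.init_shape(s.bbox, mean) for s in samples])
        intensities = [ta.normalize_to_intensity(s.image) for s in samples]
        pool = ta.sample_feature_pool(mean, P=80, rng=np.random.default_rng(1))
        return samples, cur, pool, mean, intensities

    def test_zero_residual_fixed_point(self, stage_inputs):
        samples, cur, pool, mean, intensities = stage_inputs
        frozen = [
            ta.AnnotatedSample(s.image, cur[i].copy(), s.bbox, s.subject, s.distance, s.section)
            for i, s in enumerate(samples)
        ]
        stage, out, losses = ta.fit_stage(
            frozen, cur, pool, mean, intensities, K=10, F=3,
            rng=np.random.default_rng(0),
        )
        assert np.allclose(out.reshape(len(samples), -1),
                           cur.reshape(len(samples), -1), atol=1e-9)
        assert np.allclose(losses, 0, atol=1e-18)

    def test_training_loss_non_increasing(self, stage_inputs):
        samples, cur, pool, mean, intensities = stage_inputs
        _, _, losses = ta.fit_stage(
            samples, cur, pool, mean, intensities, K=30, F=3,
            rng=np.random.default_rng(2),
        )
        assert np.all(np.diff(losses) <= 1e-15)

    def test_loss_sequence_reproducible(self, stage_inputs):
        samples, cur, pool, mean, intensities = stage_inputs
        runs = [
            ta.fit_stage(samples, cur.copy(), pool, mean, intensities, K=15, F=3,
                         rng=np.random.default_rng(9))[2]
            for _ in range(2)
        ]
        assert np.array_equal(runs[0], runs[1])


class TestTrainPredict:
    def test_ground_truth_at_init_yields_init(self, tiny_study):
        samples = tiny_study[:10]
        mean = ta.mean_shape([s.shape for s in samples], [s.bbox for s in samples])
        frozen = [
            ta.AnnotatedSample(s.image, ta.init_shape(s.bbox, mean), s.bbox,
                               s.subject, s.distance, s.section)
            for s in samples
        ]
        cfg = ta.TrainConfig(T=2, K=5, F=2, P=30, n_candidates=30, seed=0)
        model = ta.train_csr(frozen, cfg)
        for s in frozen:
            pred = ta.predict(model, s.image, s.bbox)
            assert np.allclose(pred, ta.init_shape(s.bbox, model.mean), atol=1e-9)

    def test_predict_deterministic_bitwise(self, tiny_model, tiny_study):
        s = tiny_study[0]
        a = ta.predict(tiny_model, s.image, s.bbox)
        b = ta.predict(tiny_model, s.image, s.bbox)
        assert np.array_equal(a, b)

    def test_training_byte_identical_across_runs(self, tiny_study):
        cfg = ta.TrainConfig(T=2, K=8, F=3, P=40, n_candidates=40, seed=123)
        m1 = ta.train_csr(tiny_study[:10], cfg)
        m2 = ta.train_csr(tiny_study[:10], cfg)
        for s1, s2 in zip(m1.stages, m2.stages):
            for t1, t2 in zip(s1.trees, s2.trees):
                assert np.array_equal(t1.theta, t2.theta)
                assert np.array_equal(t1.leaves, t2.leaves)

    def test_trace_structure(self, tiny_model, tiny_study):
        s = tiny_study[3]
        trace = ta.predict_trace(tiny_model, s.image, s.bbox)
        assert len(trace) == tiny_model.T + 1
        assert np.allclose(trace[0], ta.init_shape(s.bbox, tiny_model.mean))
        assert np.array_equal(trace[-1], ta.predict(tiny_model, s.image, s.bbox))

    def test_stage_diagnostics_recorded(self, tiny_model, tiny_config):
        diag = tiny_model.diagnostics
        assert len(diag["stage_losses"]) == tiny_config.T
        assert len(diag["stage_train_nppe"]) == tiny_config.T + 1

    def test_config_validation_happens_before_training(self, tiny_study):
        with pytest.raises(ConfigError):
            ta.train_csr(tiny_study[:4], ta.TrainConfig(T=0))
        with pytest.raises(ConfigError):
            ta.train_csr(tiny_study[:4], {"T": 2, "bogus_key": 1})

    def test_default_config_matches_protocol(self):
        cfg = ta.TrainConfig()
        assert (cfg.T, cfg.F, cfg.K, cfg.P) == (10, 4, 500, 400)
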