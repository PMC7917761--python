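"""Gradient-boosted regression-tree cascade for shape alignment.

The model is a cascade of T stages. Each stage holds a pool of shape-indexed
probe pixels and K shallow regression trees fitted by gradient boosting: tree
k regresses the current shape residual of every training sample, and the
running estimate is updated by a shrunk version of each tree's output,

    S(t) = S(t-1) + dS(t),    dS(t) = r_t(I, S(t-1)),

so that the summed squared residual over the training set is non-increasing
tree by tree and stage by stage. Split nodes threshold the intensity
difference of two probe pixels; each leaf stores a full 2M shape-update
vector.

Residuals are regressed in a per-sample scale-normalized frame (divided by
the mean of the bounding-box width and height) so that samples imaged at
different camera distances contribute comparably and the learned updates
transfer across face sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np

from .config import TrainConfig
from .errors import ConfigError, ValidationError
from .features import (
    FeaturePool,
    IntensityImage,
    extract_features,
    normalize_to_intensity,
    sample_feature_pool,
    warp_points,
)
from .shapes import AnnotatedSample, BBox, as_shape, init_shape, mean_shape, shape_extent
from .thermal_io import ThermalImage


class SplitNode(NamedTuple):
    """Decision rule at an internal node: value[u] - value[v] <= theta goes left."""

    u: int
    v: int
    theta: float


@dataclass
class RegressionTree:
    """Complete binary tree of depth F in heap layout.

    ``u``, ``v``, ``theta`` have length ``2**F - 1`` (internal nodes);
    ``leaves`` is ``(2**F, 2M)``. Unsplit nodes are pass-through splits with
    ``theta = +inf`` (all samples routed left) and zero-vector empty leaves.
    """

    u: np.ndarray
    v: np.ndarray
    theta: np.ndarray
    leaves: np.ndarray

    @property
    def depth(self) -> int:
        return int(np.log2(self.u.shape[0] + 1))

    def split_node(self, i: int) -> SplitNode:
        return SplitNode(int(self.u[i]), int(self.v[i]), float(self.theta[i]))


@dataclass
class CascadeStage:
    pool: FeaturePool
    trees: list
    shrinkage: float


@dataclass
class CSRModel:
    """Trained cascade: unit-frame mean shape plus T boosted-tree stages."""

    mean: np.ndarray  # (M, 2) in the unit bbox frame
    stages: list
    config: dict
    diagnostics: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return int(self.mean.shape[0])

    @property
    def T(self) -> int:
        return len(self.stages)


def _row_sq(a: np.ndarray) -> np.ndarray:
    return np.einsum("ij,ij->i", a, a)


def pair_closeness_cdf(pool: FeaturePool, mean: np.ndarray, lambda_prior: float) -> np.ndarray | None:
    """Row-wise sampling CDF for partner probes under exp(-lambda * distance).

    Returns None for lambda == 0 (uniform pairing, the default protocol).
    """
    if lambda_prior == 0.0:
        return None
    pos = pool.positions_in(as_shape(mean))
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
    w = np.exp(-lambda_prior * d)
    np.fill_diagonal(w, 0.0)
    cdf = np.cumsum(w, axis=1)
    return cdf / cdf[:, -1:]


def _sample_candidates(
    vals: np.ndarray, n_candidates: int, rng: np.random.Generator, pair_cdf: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random (u, v, theta) split candidates for one node.

    theta is drawn uniformly between the observed min and max of each
    candidate's feature at the node, so every candidate is realizable there.
    """
    P = vals.shape[1]
    uc = rng.integers(0, P, size=n_candidates)
    if pair_cdf is None:
        vc = rng.integers(0, P - 1, size=n_candidates)
        vc = vc + (vc >= uc)  # distinct partner, uniform over the rest
    else:
        r = rng.uniform(size=n_candidates)
        vc = np.array([np.searchsorted(pair_cdf[u], x) for u, x in zip(uc, r)], dtype=np.intp)
        vc = np.minimum(vc, P - 1)
    diffs = vals[:, uc] - vals[:, vc]
    lo = diffs.min(axis=0)
    hi = diffs.max(axis=0)
    th = lo + rng.uniform(size=n_candidates) * (hi - lo)
    return uc, vc, th


def midpoint_candidate_grid(vals: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exhaustive candidate set: every probe pair crossed with every midpoint threshold.

    For each unordered pair (u, v) the thresholds are the midpoints between
    consecutive distinct values of value[u] - value[v] observed at the node,
    which enumerate all distinct binary partitions the pair can induce.
    """
    P = vals.shape[1]
    us, vs, ths = [], [], []
    for u in range(P):
        for v in range(u + 1, P):
            d = np.unique(vals[:, u] - vals[:, v])
            if d.size < 2:
                continue
            mids = (d[:-1] + d[1:]) / 2.0
            us.append(np.full(mids.size, u))
            vs.append(np.full(mids.size, v))
            ths.append(mids)
    if not us:
        return (np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0))
    return np.concatenate(us), np.concatenate(vs), np.concatenate(ths)


def fit_tree(
    residuals: np.ndarray,
    feature_values: np.ndarray,
    depth: int = 4,
    n_candidates: int = 400,
    shrinkage: float = 0.1,
    rng: np.random.Generator | None = None,
    *,
    candidates: Callable[[np.ndarray], tuple] | None = None,
    pair_cdf: np.ndarray | None = None,
    min_samples_leaf: int = 1,
) -> RegressionTree:
    """Fit one regression tree on boosted residuals by greedy top-down search.

    At each node, candidate (u, v, theta) triples are scored by the reduction
    in residual sum of squares (equivalently, the between-child sum
    |sum_L|^2 / n_L + |sum_R|^2 / n_R is maximized); ties are broken in favor
    of the first-seen candidate under the seeded stream. Leaves store
    ``shrinkage`` times the mean residual of the samples that reach them;
    empty leaves store the zero vector.

    ``candidates`` overrides random sampling with a deterministic candidate
    generator (e.g. :func:`midpoint_candidate_grid`), used for exhaustive
    cross-checks.
    """
    res = np.asarray(residuals, dtype=np.float64)
    fv = np.asarray(feature_values, dtype=np.float64)
    if res.ndim != 2 or fv.ndim != 2 or res.shape[0] != fv.shape[0]:
        raise ValidationError("residuals and feature_values must be 2-D with matching rows")
    n, dim = res.shape
    if n == 0:
        raise ValidationError("fit_tree needs at least one sample")
    if depth < 1:
        raise ConfigError(f"tree depth must be >= 1, got {depth}")
    if rng is None:
        rng = np.random.default_rng()

    n_internal = 2**depth - 1
    n_leaves = 2**depth
    u = np.zeros(n_internal, dtype=np.int32)
    v = np.ones(n_internal, dtype=np.int32)
    theta = np.full(n_internal, np.inf)
    assign: list = [None] * (n_internal + n_leaves)
    assign[0] = np.arange(n)

    for node in range(n_internal):
        idx = assign[node]
        left, right = 2 * node + 1, 2 * node + 2
        if idx.size == 0:
            assign[left] = idx
            assign[right] = idx
            continue
        vals = fv[idx]
        if candidates is not None:
            uc, vc, th = candidates(vals)
        else:
            uc, vc, th = _sample_candidates(vals, n_candidates, rng, pair_cdf)
        if uc.size == 0:  # nothing can split this node
            assign[left] = idx
            assign[right] = idx[:0]
            continue
        diffs = vals[:, uc] - vals[:, vc]
        go_left = diffs <= th
        nl = go_left.sum(axis=0)
        nr = idx.size - nl
        node_res = res[idx]
        total = node_res.sum(axis=0)
        left_sums = go_left.T.astype(np.float64) @ node_res
        right_sums = total - left_sums
        with np.errstate(divide="ignore", invalid="ignore"):
            score = np.where(nl > 0, _row_sq(left_sums) / np.maximum(nl, 1), 0.0)
            score = score + np.where(nr > 0, _row_sq(right_sums) / np.maximum(nr, 1), 0.0)
        if min_samples_leaf > 1:
            invalid = (nl > 0) & (nl < min_samples_leaf) | (nr > 0) & (nr < min_samples_leaf)
            score = np.where(invalid, -np.inf, score)
        best = int(np.argmax(score))  # first occurrence wins on ties
        if not np.isfinite(score[best]):
            assign[left] = idx
            assign[right] = idx[:0]
            continue
        u[node], v[node], theta[node] = uc[best], vc[best], th[best]
        mask = go_left[:, best]
        assign[left] = idx[mask]
        assign[right] = idx[~mask]

    leaves = np.zeros((n_leaves, dim))
    for j in range(n_leaves):
        idx = assign[n_internal + j]
        if idx.size:
            leaves[j] = shrinkage * res[idx].mean(axis=0)
    return RegressionTree(u=u, v=v, theta=theta, leaves=leaves)


def tree_apply(tree: RegressionTree, feature_values: np.ndarray) -> np.ndarray:
    """Route samples to leaves and return their update vectors; (n, 2M)."""
    fv = np.atleast_2d(np.asarray(feature_values, dtype=np.float64))
    n = fv.shape[0]
    rows = np.arange(n)
    node = np.zeros(n, dtype=np.intp)
    depth = tree.depth
    for _ in range(depth):
        d = fv[rows, tree.u[node]] - fv[rows, tree.v[node]]
        node = 2 * node + 1 + (d > tree.theta[node])
    leaf = node - (2**depth - 1)
    return tree.leaves[leaf]


def _sample_scale(bbox: BBox) -> float:
    return 0.5 * (bbox.w + bbox.h)


def fit_stage(
    samples: Sequence[AnnotatedSample],
    current_shapes: np.ndarray,
    pool: FeaturePool,
    mean: np.ndarray,
    intensities: Sequence[IntensityImage],
    K: int = 500,
    F: int = 4,
    shrinkage: float = 0.1,
    n_candidates: int = 400,
    rng: np.random.Generator | None = None,
    *,
    pair_cdf: np.ndarray | None = None,
    min_samples_leaf: int = 1,
    sample_scales: np.ndarray | None = None,
    gt_shapes: np.ndarray | None = None,
) -> tuple[CascadeStage, np.ndarray, np.ndarray]:
    """Fit one cascade stage of K boosted trees.

    Probe features are extracted once per sample at the stage-entry shapes;
    the K trees are then fitted sequentially on the running scale-normalized
    residual. Returns the stage, the updated shape estimates ``(n, M, 2)``,
    and the training-loss curve (mean squared normalized residual after each
    tree), which is non-increasing.
    """
    n = len(samples)
    if n == 0:
        raise ValidationError("fit_stage needs a non-empty training set")
    if rng is None:
        rng = np.random.default_rng()
    M = as_shape(mean).shape[0]
    cur = np.asarray(current_shapes, dtype=np.float64).reshape(n, M, 2).copy()
    if gt_shapes is None:
        gt = np.stack([s.shape for s in samples]).astype(np.float64)
    else:
        gt = np.asarray(gt_shapes, dtype=np.float64).reshape(n, M, 2)
    if sample_scales is None:
        scales = np.array([_sample_scale(s.bbox) for s in samples])
    else:
        scales = np.asarray(sample_scales, dtype=np.float64)

    fv = np.empty((n, pool.P))
    for i in range(n):
        pos = warp_points(pool, mean, cur[i])
        fv[i] = extract_features(intensities[i], pos)

    gt_flat = gt.reshape(n, 2 * M)
    cur_flat = cur.reshape(n, 2 * M)
    trees: list[RegressionTree] = []
    losses = np.empty(K)
    tree_rngs = rng.spawn(K)
    for k in range(K):
        res = (gt_flat - cur_flat) / scales[:, None]
        tree = fit_tree(
            res, fv, depth=F, n_candidates=n_candidates, shrinkage=shrinkage,
            rng=tree_rngs[k], pair_cdf=pair_cdf, min_samples_leaf=min_samples_leaf,
        )
        cur_flat += tree_apply(tree, fv) * scales[:, None]
        trees.append(tree)
        r = (gt_flat - cur_flat) / scales[:, None]
        losses[k] = float(np.mean(_row_sq(r)))
    stage = CascadeStage(pool=pool, trees=trees, shrinkage=shrinkage)
    return stage, cur_flat.reshape(n, M, 2), losses


def _mean_train_nppe(gt: np.ndarray, cur: np.ndarray) -> float:
    from .evaluation import nppe  # local import avoids a cycle

    vals = []
    for g, c in zip(gt, cur):
        w, h = shape_extent(g)
        vals.append(nppe(c, g, w, h))
    return float(np.mean(vals))


def train_csr(train: Sequence[AnnotatedSample], config: TrainConfig | dict | None = None) -> CSRModel:
    """Train a full cascaded shape regressor on annotated samples.

    Computes the bbox-normalized mean shape, initializes every sample from
    its bounding box, and fits T stages; each stage draws a fresh probe pool
    and K boosted trees. Per-stage training loss and mean training NPPE are
    recorded in ``model.diagnostics``.
    """
    if config is None:
        config = TrainConfig()
    elif isinstance(config, dict):
        config = TrainConfig.from_dict(config)
    config.validate()
    if len(train) == 0:
        raise ValidationError("train_csr needs a non-empty training set")
    M = train[0].M
    for s in train:
        if s.M != M:
            raise ValidationError("inconsistent landmark count across training samples")

    mean = mean_shape([s.shape for s in train], [s.bbox for s in train])
    intensities = [
        normalize_to_intensity(s.image, config.normalization, config.fixed_range) for s in train
    ]

    samples = list(train)
    cur = np.stack([init_shape(s.bbox, mean) for s in samples])
    if config.oversample_inits > 1:
        rng0 = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA5]))
        extra_samples, extra_inits, extra_int = [], [], []
        for i, s in enumerate(samples):
            for _ in range(config.oversample_inits - 1):
                jitter_scale = rng0.uniform(0.9, 1.1)
                jitter_t = rng0.uniform(-0.05, 0.05, size=2) * np.array([s.bbox.w, s.bbox.h])
                c = cur[i].mean(axis=0)
                extra_inits.append((cur[i] - c) * jitter_scale + c + jitter_t)
                extra_samples.append(s)
                extra_int.append(intensities[i])
        samples = samples + extra_samples
        intensities = intensities + extra_int
        cur = np.concatenate([cur, np.stack(extra_inits)], axis=0)

    gt = np.stack([s.shape for s in samples]).astype(np.float64)
    scales = np.array([_sample_scale(s.bbox) for s in samples])

    root = np.random.SeedSequence(config.seed)
    stage_seeds = root.spawn(config.T)
    stages: list[CascadeStage] = []
    stage_losses: list[np.ndarray] = []
    stage_nppe: list[float] = [_mean_train_nppe(gt, cur)]
    for t in range(config.T):
        srng = np.random.default_rng(stage_seeds[t])
        pool = sample_feature_pool(mean, P=config.P, spread=config.spread, rng=srng, stage=t)
        cdf = pair_closeness_cdf(pool, mean, config.lambda_prior)
        stage, cur, losses = fit_stage(
            samples, cur, pool, mean, intensities,
            K=config.K, F=config.F, shrinkage=config.shrinkage,
            n_candidates=config.n_candidates, rng=srng,
            pair_cdf=cdf, min_samples_leaf=config.min_samples_leaf,
            sample_scales=scales, gt_shapes=gt,
        )
        stages.append(stage)
        stage_losses.append(losses)
        stage_nppe.append(_mean_train_nppe(gt, cur))

    return CSRModel(
        mean=mean,
        stages=stages,
        config=config.to_dict(),
        diagnostics={
            "stage_losses": [l.tolist() for l in stage_losses],
            "stage_train_nppe": stage_nppe,
        },
    )


def _model_normalize(model: CSRModel, img: ThermalImage) -> IntensityImage:
    cfg = model.config or {}
    return normalize_to_intensity(
        img, cfg.get("normalization", "minmax"), tuple(cfg.get("fixed_range", (20.0, 40.0)))
    )


def predict_trace(model: CSRModel, img: ThermalImage, bbox: BBox) -> list[np.ndarray]:
    """Run the cascade, returning all intermediate shapes S(0)..S(T)."""
    intensity = _model_normalize(model, img)
    M = model.M
    cur = init_shape(bbox, model.mean)
    scale = _sample_scale(bbox)
    trace = [cur.copy()]
    for stage in model.stages:
        pos = warp_points(stage.pool, model.mean, cur)
        fv = extract_features(intensity, pos)[None, :]
        update = np.zeros(2 * M)
        for tree in stage.trees:
            update += tree_apply(tree, fv)[0]
        cur = cur + (update * scale).reshape(M, 2)
        trace.append(cur.copy())
    return trace


def predict(model: CSRModel, img: ThermalImage, bbox: BBox) -> np.ndarray:
    """Predict the 68-point face shape for one image and face box."""
    return predict_trace(model, img, bbox)[-1]
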