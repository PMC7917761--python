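# Methods

## Model

`thermalign` implements cascaded shape regression (CSR) with gradient-boosted
ensembles of regression trees (ERT) for 68-point facial landmark alignment in
thermal infrared images.

A face shape is the vector `S = [x1, y1, ..., xM, yM]` of M = 68 landmark
coordinates. Prediction starts from the mean shape placed in the supplied
face bounding box, `S(0) = init_shape(bbox, mean)`, and proceeds through T
stages:

    S(t) = S(t-1) + r_t(I, S(t-1)),   t = 1..T,

where each stage regressor `r_t` is a sum of K shallow regression trees
fitted by gradient boosting to minimize the summed squared shape residual
over the training set. Tree split nodes threshold the intensity difference
of two *shape-indexed* probe pixels: each probe is an (anchor landmark,
offset) pair defined in the mean-shape frame; at run time the offsets are
rotated/scaled by the similarity transform from the mean shape to the
current estimate and anchored at the landmark's current position, making the
features covariant with pose and scale. Each leaf stores a full 2M update
vector.

### Residual frame

The residual each tree regresses is expressed in a per-sample
scale-normalized frame: `r_i = (S_hat_i - S_i) / d_i` with
`d_i = (bbox_w + bbox_h) / 2`. This is a design choice the method
description leaves open. It makes samples imaged at 60, 90 and 120 cm
(face widths ~184/126/97 px) contribute comparably to every split decision,
lets the learned updates transfer across face sizes, and — because a leaf
adds `nu` times the mean residual of its samples — makes the stage training
loss *exactly* non-increasing tree by tree and stage by stage for any
`0 < nu <= 2`. Rotation is deliberately left out of the residual frame
(faces in this protocol are close to upright); rotation covariance is
handled entirely by the feature indexing.

### Split search

At each node, 400 candidate `(u, v, theta)` triples are drawn: `u` uniform
over the stage's P = 400 probes, `v` uniform over the remaining probes
(optionally weighted by a closeness prior `exp(-lambda * |u - v|)`,
`lambda = 0` by default so the default reproduces the plain protocol), and
`theta` uniform between the min and max of `value[u] - value[v]` among the
samples at that node, so every candidate is realizable. Candidates are
scored by the squared-error reduction of the residuals, computed as the
between-child quantity `|sum_L|^2/n_L + |sum_R|^2/n_R`; ties break toward
the first-seen candidate under the seeded stream. Trees are complete binary
trees of depth F; nodes that cannot be split become pass-through splits
(`theta = +inf`, all samples left) and empty leaves store the zero vector.
A `min_samples_leaf` flag enables the common early-stopping variant; the
default (1) is the plain protocol.

Features are extracted once per stage at the stage-entry shapes, matching
the stage regressor's dependence on `S(t-1)` only. Probe lookups use
nearest-pixel sampling with border clamping (a total function even under
extreme pose), after the thermal image is normalized to [0, 1] — per-image
min/max by default, or a fixed Celsius window (default [20, 40] degC) when
absolute temperature contrast should be preserved across images.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| T | 10 | cascade stages |
| K | 500 | boosted trees per stage |
| F | 4 | tree depth (16 leaves) |
| P | 400 | probe pixels per stage pool |
| n_candidates | 400 | split candidates per node |
| shrinkage (nu) | 0.1 | boosting learning rate |
| spread | 0.15 | probe offset half-width, mean-shape units |
| normalization | minmax | thermal-to-intensity mapping |

T, K, F, P are the study protocol's fixed settings. The protocol does not
state a learning rate; 0.1 is the standard choice in the ERT lineage this
method follows. `spread = 0.15` of the unit face frame keeps probes on or
near the face; larger values add background probes that carry little signal
under min/max normalization. One initialization per training image (the
mean shape) is the default, exactly as the protocol states; oversampled
random initializations are available behind `oversample_inits`.

All randomness flows from one master seed through named `SeedSequence`
substreams (per stage, per tree), so training is bit-reproducible and
independent of evaluation order; models serialize to a self-describing
`.npz` archive whose round trip is prediction-invariant bitwise.

## Evaluation

The normalized point-to-point error of image i is

    NPPE_i = (1/N) * sum_n ||p_n - g_n||  /  ((w_i + h_i) / 2),

the mean Euclidean landmark error divided by the mean of face width and
height; 0.05 is the conventional acceptability level. `w_i, h_i` are taken
from the ground-truth landmark extent by default (annotation-tool
independent), with a flag to use the manifest bbox instead. Results are
reported both as fractions (CED-curve convention, threshold 0.05) and as
percentages (per-distance table convention).

Cross-validation is subject-wise leave-one-subject-out (k = number of
subjects). Flip-augmented copies inherit their subject id, so augmentation
cannot leak a subject across the train/test boundary. By default the test
side contains original images only — mirrored duplicates of the same
physical frame would otherwise be double-counted — with a flag to include
them. FPS is measured around prediction only (no model load, no image I/O)
and is reported for information; it is hardware-dependent and never gated.

## Synthetic study generator

The generator emulates the acquisition protocol so the full pipeline runs
with no external data: 7 subjects x 87 images by default (3 distances x
(9 Small + 9 Large + 11 Random); the per-section split behind 87 images per
subject is not published, this allocation reproduces the printed totals),
640x480 frames, face widths targeted at 184/126/97 px for 60/90/120 cm with
8% relative jitter (matching the reported width SDs of ~10%), nine head
directions as a {-a, 0, +a}^2 grid at amplitude 20 deg (Small) or 45 deg
(Large), and Random poses uniform within +/-45 deg with expression jitter on
mouth and brows.

Faces are a fixed bilaterally symmetric 68-point template deformed per
subject (i.i.d. landmark offsets, sigma 0.01 of the face frame, plus a
vertical-aspect draw), pose-approximated by anisotropic cos(yaw)/cos(pitch)
compression plus in-plane roll — not 3-D projection — so the landmark ground
truth is exactly the transform the renderer applied (the generator is its
own oracle). Appearance is a smooth temperature field on an elliptical face
region: Gaussian bumps anchored at landmark-derived points (warm inner
canthi, forehead and mouth; cool nose and chin; radially cooling periphery),
affinely rescaled so the facial min/max equal the subject's drawn
`t_min`/`t_max` and power-remapped so the facial mean hits `t_mean`, over a
~24 degC ambient background, plus Gaussian sensor noise with sigma 0.05 degC
(the camera's stated temperature resolution). Subject temperature parameters
are drawn inside the observed study envelope (min 29.2-31.4, max 33.7-34.3,
mean 31.9-33.0 degC).

What the generator does *not* emulate: real inter-subject anatomy (hair,
glasses, facial hair), occlusions, emissivity and radiometric effects,
perspective foreshortening, and annotation noise. Bounding boxes are the
landmark extent padded 10%, i.e. tighter and more consistent than manual
boxes. Consequently, synthetic results demonstrate that the training
pipeline, feature machinery and evaluation protocol work and that the
cascade recovers landmarks under pose/scale/temperature variation; absolute
synthetic error levels are easier than real thermal data and are not
comparable to errors on human images.

## Problem sizes used in the checks

The bundled end-to-end checks run a reduced study replica — 7 subjects x 30
images, training on six subjects with flips (360 samples) at T=10, F=4,
K=200, P=400 — and reduced-size unit datasets (3 subjects, 200x150 frames,
scaled-down face widths) for the plumbing tests. These sizes were chosen so
the whole suite runs comfortably on a laptop-class single core while keeping
every protocol property (counts, monotonicity, recovery below the 0.05
level) intact at full parameter dimensionality where it matters (F, P,
n_candidates).

## Numerical notes and edge cases

- Constant images normalize to all zeros under min/max (degenerate-case
  convention); fixed-range normalization clips.
- `align_similarity` uses the closed-form least-squares (Umeyama) solution
  without reflection and raises on all-coincident source points.
- Horizontal flips use `x -> W - 1 - x` under the pixel-center convention,
  so a double flip is exact; pts files are converted between the 1-based
  on-disk dialect and the package's 0-based convention on read/write.
- TIFF temperature encoding is an explicit linear map (`degC = raw * scale +
  offset`, default scale 0.01) stored in the file, with worst-case
  quantization error `scale / 2`.
- Empty tree nodes are pass-through; thresholds at a node with a constant
  candidate feature degenerate to an all-left split with zero gain.

## Known limitations

- Out-of-plane pose is a 2-D approximation; profile-range yaw (> ~50 deg)
  is outside the generator's and the aligner's intended regime.
- The aligner requires a face bounding box as input (the protocol uses
  annotated boxes); no face detector is included.
- Mean-shape initialization anchors the cascade to the bbox frame; poorly
  scaled boxes at test time degrade accuracy more than pose does.
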