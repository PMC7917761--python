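# thermalign

Facial landmark alignment in **thermal infrared images** using **cascaded
shape regression** (CSR) with gradient-boosted ensembles of regression trees.

Physiological and psychological state estimation from facial thermography —
respiratory rate, stress, sleepiness, emotion — reads skin temperature from
regions of interest such as the nose, cheeks and mouth. That requires
locating facial landmarks in the thermal image first. Classical Active
Appearance Models do this at seconds per frame and generalize poorly to
unseen subjects; cascaded regression does it in milliseconds. `thermalign`
provides the full pipeline for researchers working with thermal face data:
training, prediction, flip augmentation, subject-wise cross-validation, the
NPPE evaluation protocol, and a synthetic thermal-face study generator so
everything runs end-to-end without access to human data.

## Model

With `S = [x1, y1, ..., xM, yM]` the vector of M = 68 landmarks, prediction
starts from the mean shape placed in the face bounding box and applies T
cascaded corrections

    S(t) = S(t-1) + r_t(I, S(t-1)),    t = 1..T,

where each stage regressor `r_t` is an ensemble of K depth-F regression
trees fitted by gradient boosting to the shape residuals. Split nodes
threshold the intensity difference of two shape-indexed probe pixels (anchor
landmark + offset, warped by the mean-to-current similarity transform), and
each leaf carries a full 2M shape update. Defaults follow the study
protocol: **T=10, F=4, K=500, P=400** probes per stage, 400 split candidates
per node. Accuracy is measured as the normalized point-to-point error

    NPPE = mean landmark distance / mean(face width, face height),

with 0.05 the conventional acceptability level. See `docs/methods.md` for
the complete model description and design rationale.

## Worked example

Generate a small synthetic study, train, and cross-validate — all from the
shell:

```sh
thermalign synth --out study --subjects 3 --per-subject 12 --seed 7
# wrote 36 images (3 subjects x 12) to study

thermalign train --manifest study/manifest.csv --out model.npz -T 10 -K 100 --seed 7
# trained T=10 stages on 72 samples -> model.npz

thermalign evaluate --manifest study/manifest.csv --out report -T 10 -K 100 --seed 7
# mean NPPE 0.0238 (2.38%) over 36 images
```

The evaluate step ran 3-fold leave-one-subject-out cross-validation (one
fold per subject, flip-augmented training, originals-only testing) and wrote
`report/per_image.csv`, `report/by_distance.csv`, `report/ced.csv` and
`report/summary.json`:

```json
{
  "n_images": 36,
  "mean_nppe": 0.023845250136006982,
  "sd_nppe": 0.001207922519133837,
  "mean_nppe_percent": 2.3845250136006984,
  "k_folds": 3
}
```

A mean NPPE of 0.024 means predicted landmarks on held-out subjects are off
by about 2.4% of the face size on average — well under the 0.05
acceptability level. `thermalign bench --model model.npz --manifest
study/manifest.csv` reports prediction throughput (FPS; informational,
hardware-dependent). The same pipeline is available as a library:

```python
import thermalign as ta

samples = ta.generate_study(ta.ProtocolSpec(n_subjects=7, seed=0))  # 609 images
model = ta.train_csr(ta.flip_dataset(samples), ta.TrainConfig(seed=0))
shape = ta.predict(model, samples[0].image, samples[0].bbox)        # (68, 2)
```

## Data formats

- **Images**: plain-matrix CSV (°C), 16-bit grayscale TIFF with a declared
  linear `raw → °C` map (default scale 0.01), or 8-bit grayscale PNG for
  pre-normalized input.
- **Landmarks**: iBUG-style pts files (1-based on disk, converted to the
  package's 0-based pixel-center convention).
- **Datasets**: CSV manifest with columns
  `image,pts,bx,by,bw,bh,subject,distance,section`.
- **Models**: a single self-describing `.npz` archive; save/load round
  trips are prediction-invariant bitwise.
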