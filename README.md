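# petbpnn

Two-stage classification of 2D amyloid-PET brain slices into normal control
(NC) versus a disease group (SMC, EMCI, LMCI or AD):

1. **Image preparation** — autocrop the black frame, bilinear-resize to a
   200×200 grid, then reduce to 400 normalized features by averaging
   non-overlapping 10×10 pixel segments ("average pixel per node", APPN).
2. **Classification** — a from-scratch 3-layer back-propagation network
   (400–45–2, logistic sigmoid, bias weights) trained by per-pattern gradient
   descent with momentum (learning rate 0.00079, momentum 0.90) until the
   root-mean-square output error drops to 0.003.

Evaluation follows a stratified hold-out protocol: 30% of each class trains
the network, the remaining 70% is scored into a confusion matrix with the
disease group as the positive class, reported as sensitivity / specificity /
accuracy in percent (one decimal, rounded half away from zero).

Because real amyloid-PET data require credentialed access, the package ships
a synthetic phantom generator: elliptical brain slices with a high-uptake
core and a cortical rim whose uptake rises with disease class, Gaussian
smoothing, additive noise and a surrounding black frame. The whole pipeline
is exercisable end to end on phantoms alone.

## Layout

| module                 | role                                                        |
|------------------------|-------------------------------------------------------------|
| `petbpnn.image_io`     | PNG/TIFF/NIfTI reading, manifest CSV handling               |
| `petbpnn.preprocess`   | autocrop, bilinear resize, APPN block averaging             |
| `petbpnn.bpnn`         | the back-propagation network (train / predict / persist)    |
| `petbpnn.evaluation`   | hold-out split, confusion counts, metrics, experiment runner|
| `petbpnn.synthetic`    | phantom slice and dataset generation                        |
| `petbpnn.cli`          | `petbpnn` command-line interface                            |

## CLI

```bash
# generate a 500-image phantom dataset (100 per class)
petbpnn simulate --out data/ --n-per-class 100 --seed 7

# prepare features: 200x200 grid, 10x10 segments -> 400 values per image
petbpnn prepare --manifest data/manifest.csv --out features.csv

# one hold-out experiment (NC vs AD)
petbpnn evaluate --features features.csv --experiment NC/AD \
    --split-seed 17 --report report.json

# everything from a YAML config: simulate -> prepare -> 4 experiments
petbpnn run-all --config run.yaml --out results/
```

Minimal `run.yaml`:

```yaml
phantom: {n_per_class: 100, seed: 7}
prep: {target_size: 200, segment_size: 10}
network: {n_hidden: 45, learning_rate: 0.00079, momentum: 0.9,
          min_rms: 0.003, max_epochs: 50000, seed: 0}
split_seed: 5
```

## Conventions worth knowing

* **Volumes**: for 3D NIfTI input, the last two axes are the in-plane axes
  and `slice_index` selects a plane along the first axis (default: middle).
* **Resize**: corner-aligned bilinear sampling (output pixel *i* samples
  source coordinate *i*·(n−1)/(target−1)).
* **APPN order**: blocks are row-major, top-left first.
* **Normalization**: block means are divided by the nominal bit-depth
  maximum when known (255 for 8-bit rasters), else by a dataset-wide
  intensity maximum — never the per-image maximum, which would erase
  between-image uptake differences.
* **Targets**: one-hot {1, 0}; predictions by argmax, ties to the lower
  index. Output neuron 0 is NC, neuron 1 the disease group.
* **RMS error**: `sqrt(sum_p sum_k (t - o)^2 / (P*K))`, evaluated with
  weights frozen at the end of each epoch.

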