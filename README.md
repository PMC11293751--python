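# tumorseg

Two-phase analysis of 2-D T2-like brain MR slices:

1. **Classification** — percentile contrast stretching, geometric data
   augmentation, and a lightweight block-structured CNN (stem +
   inception / identity / convolution blocks) that separates normal from
   abnormal slices. The network is implemented in pure NumPy (im2col
   convolutions with manual backpropagation) together with the seven
   first-order optimizers the training protocol compares (SGDM, Adam,
   Adamax, Adagrad, Adadelta, RMSprop, Nadam).
2. **Localization** — multi-level histogram thresholding driven by a
   non-extensive (Tsallis) entropy criterion maximized with a
   DE/rand/1/bin differential-evolution search, aggregation of the three
   largest thresholds into a single binarization level, and morphological
   opening with a radius-10 disk.

A seeded synthetic phantom generator (elliptical head, layered tissue
strata, 0–3 hyperintense lesions with exact ground-truth masks) makes the
whole pipeline testable offline; no clinical download is required.

The full-size classifier configuration is frozen in
`src/tumorseg/resources/network_default.yaml` and resolves to exactly
553,794 parameters (549,890 trainable + 3,904 non-trainable batch-norm
running statistics); the test suite asserts these counts.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(augmentation bookkeeping, architecture parameter fidelity, optimizer
oracle equivalence against exhaustive search, the Shannon entropy limit,
a brute-force morphology oracle, metric identities, phantom segmentation
recovery, and a scaled-down cross-validated classifier run).

## CLI

```bash
tumorseg simulate --abnormal 194 --normal 70 --seed 17 --out data/
tumorseg enhance  --in data/images --out data/enhanced
tumorseg augment  --manifest data/manifest.csv --out data/aug --factor 9 --seed 17
tumorseg train    --manifest data/manifest.csv --optimizer adam --folds 5 \
                  --width-scale 0.25 --seed 17 --out runs/train
tumorseg segment  --in data/enhanced --out runs/seg --thresholds 6 --gamma 0.5 --seed 17
tumorseg evaluate --pred runs/seg --truth data/masks --out runs/report
tumorseg run      --manifest data/manifest.csv --out runs/full --seed 17
```

`segment` writes a raw and a refined (`_refined`) mask per image plus a
JSON sidecar with the threshold vector, objective value, aggregate
threshold and the DE convergence trace. `run` executes
enhance → (classify) → threshold → refine → evaluate, segmenting only
abnormal-classified slices, and echoes the resolved configuration into the
run directory.

Training the full 256×256 network is intentionally out of scope for desk
hardware; `--width-scale` builds reduced-filter instances of the same
topology for experimentation (the default acceptance run trains a
quarter-width model on 64×64 phantoms).

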