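# phenonet

Convolutional networks for image-based plant phenotyping from single
top-down rosette images: **leaf counting** (regression), **mutant
classification** (five morphology classes) and **age regression** (hours
after germination). The package provides the full experimental pipeline —
dataset loaders, the standard augmentation envelope, seeded training with
plateau stopping, evaluation reports and a lighting-robustness protocol —
plus a procedural rosette generator so everything can be exercised end to
end without downloading any external benchmark.

## The tasks and the model

Each task maps a raw n×m×3 RGB image of one rosette to a scalar or a class.
The networks are plain convolutional stacks: same-padded stride-1
convolutions (an n×m×3 input volume becomes n×m×k under k filters),
3×3/stride-2 max pooling, optional fully connected layers, and a linear
output layer — one unit for regression, five log-normalized (softmax) units
for classification. Weights are Xavier-initialized,
`U(±√(6/(fan_in+fan_out)))`, and trained with Adam on mean squared error
(regression) or cross-entropy (classification). The only image
pre-processing is per-image standardization, `(x − mean(x)) / std(x)`.

Five canonical architectures are provided (`phenonet archs list`): three
leaf counters (A1/A2 for Arabidopsis-style data at 256/128 px input, A3 for
tobacco), the mutant classifier (four 5×5 conv stages and a
4096-unit×3 dropout-regularized head) and the age regressor (two 3×3 conv
stages and one 2048-unit layer). Training crops images randomly (25% linear
crop, e.g. 128→96; 10% for the 256-px networks) and also applies random
brightness (max delta 63), contrast (factor 0.2–1.8) and flips; testing
center-crops only.

The headline counting metric is the **mean absolute difference (MAD)**
between unrounded predictions and true counts, reported with its
population standard deviation.

The network engine (forward and analytic backward passes, im2col
convolutions, inverted dropout, Adam) is implemented directly on NumPy
arrays; a nested-loop reference implementation in the test suite pins the
arithmetic.

## The synthetic rosette generator

`phenonet.synthetic` renders single rosettes on a soil-like background with
exact ground truth: leaves placed at successive multiples of the 137.5°
golden phyllotaxis angle, leaf size strictly increasing with age
(392–620 h), counts 5–20 (Arabidopsis-like) or 2–13 (tobacco-like), and
five morphology classes differing in blade aspect ratio, petiole length
and margin serration. Leaf blades are the only green-dominant pixels, so
connected components of the green mask are an exact counting oracle at
moderate density. Datasets persist in an IPPN-style folder layout
(`plant_0000_rgb.png` + `Leaf_counts.csv`/`Ages.csv`/`Classes.csv`) that
the loaders read back unchanged.

## Worked example

```bash
python examples/train_leaf_counter.py
```

generates 120 synthetic rosettes at 64×64, trains the reduced five-stage
counter for 1200 steps and prints:

```
train 96 / test 24 images at 64x64
trained 1200 steps; train loss 3.191 -> 0.015 (x100 counts^2)
clean test MAD: 1.00 (0.83) leaves
out-of-envelope MAD: 1.16 (1.16) leaves
```

i.e. after a one-minute run the counter is off by one leaf on average on
held-out plants, and distorting test images beyond the training envelope
(brightness delta 75, contrast 0.5–2.1) costs only a fraction of a leaf —
per-image standardization absorbs most photometric shift. The longer
benchmark study (400 images, 4000 steps; see below) reaches MAD ≈ 0.73.

Other walkthroughs: `examples/render_rosettes.py` (generator ground
truth), `examples/augmentation_demo.py` (distortion envelopes),
`examples/architecture_tour.py` (shape algebra and parameter counts).

The same pipeline is scriptable from a shell:

```bash
phenonet synth --n 62 --style tobacco_like --out ds/
phenonet train --image-dir ds/ --labels ds/Leaf_counts.csv --arch A2 --out run/
phenonet evaluate --checkpoint run/checkpoint.npz --image-dir ds/ \
    --labels ds/Leaf_counts.csv --robustness
phenonet predict --checkpoint run/checkpoint.npz ds/plant_0000_rgb.png
```

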