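# caeprep

Convolutional-autoencoder compression as a preprocessing step for
classifying noisy, high-dimensional images — plus the nonparametric
statistical machinery for deciding whether a preprocessing approach
actually helps.

## The problem

CNN classifiers are sensitive to pixel noise and redundant high-frequency
detail, especially at large input resolutions: small perturbations can flip
predictions, and with limited or imbalanced training data the network
overfits the clutter instead of the signal. One remedy is to compress and
filter the images *before* classification. `caeprep` implements a pipeline
in which a small symmetric convolutional autoencoder (CAE) is trained to
reconstruct the raw images; its decoder is then discarded and the encoder's
quarter-resolution latent — itself a small RGB image in [0, 1] — is fed to
the classifier in place of the original.

The encoder is two strided convolutions,

```
x (H×W×3) ─ conv 4×4, 32 filters, stride 2, ReLU ─→ H/2×W/2×32
          ─ conv 2×2,  3 filters, stride 2, sigmoid ─→ y (H/4×W/4×3)
```

and the decoder mirrors it with transposed convolutions (2×2 then 4×4,
sigmoid output). Training minimises the mean half-squared reconstruction
error

    J_CAE = (1/M) Σ_k ½ ‖D(E(x⁽ᵏ⁾)) − x⁽ᵏ⁾‖²

with Adam (learning rate 10⁻³), a stratified 10 % validation split and
keep-best early stopping on the validation loss. The classifier stage
minimises mean cross-entropy the same way.

Three preprocessing arms are compared on equal terms as dataset → dataset
transforms: **traditional** (raw images, the identity), **md** (non-local
means denoising) and **cae** (encoder compression). Performance is scored
by accuracy, the geometric mean of per-class recalls (GM) and macro
one-vs-rest ROC AUC, and the arms are compared across dataset × classifier
blocks with the **Friedman aligned-ranks test** and the **Finner step-down
post hoc** against the best-ranked arm.

Because the published benchmark images (plant disease, skin lesions,
deepfake faces) are external downloads, the package ships a synthetic
generator that reproduces the *statistical* setting: class-discriminative
low-frequency structure buried under shared high-frequency clutter and
heavy pixel noise, at any resolution divisible by 4. The published metric
tables themselves are shipped as CSV fixtures for the statistics module.

## Worked example

Statistical comparison of the three arms over the twelve shipped benchmark
blocks (3 datasets × 4 CNN backbones), on the accuracy metric:

```python
from caeprep import FriedmanAlignedRanks
from caeprep.benchmarks import combined_table

print(FriedmanAlignedRanks(combined_table("accuracy")).fit().summary())
```

```
Friedman aligned-ranks comparison — accuracy
blocks n=12, treatments k=3
omnibus T=9.7596 (df=2), p=0.00759841
control (best average rank): CAE

treatment       avg rank     p (raw)  p (Finner)  H0
CAE               9.4167           -           -  -
MD               21.6667    0.004399    0.004399  Rejected
Traditional      24.4167    0.000488    0.000975  Rejected
```

Reading: the 36 accuracy values are centred per block and ranked jointly
(rank 1 = best). The CAE arm's average rank of 9.42 is far better than MD
(21.67) and Traditional (24.42); the omnibus chi-square rejects "all arms
equal" at p ≈ 0.008, and both pairwise Finner-adjusted p-values fall below
α = 0.05, so the hypothesis that either competitor matches the CAE arm is
rejected.

The pipeline itself, at desk scale (one seed shown):

```python
import numpy as np
from caeprep import (SyntheticSpec, generate_dataset, ConvAutoencoder,
                     ClassifierSpec, fit_classifier)

spec = SyntheticSpec(n_classes=3, samples_per_class=200, height=64,
                     width=64, signal_amplitude=0.5, noise_sigma=0.25,
                     clutter_amplitude=0.1, seed=1)
train = generate_dataset(spec, draw=0)
test  = generate_dataset(SyntheticSpec(**{**spec.__dict__,
                         "samples_per_class": 100}), draw=1)

cae = ConvAutoencoder(64, 64, max_epochs=12, early_stop_patience=3,
                      seed=1).fit(train)
clf = fit_classifier(ClassifierSpec(n_classes=3, max_epochs=20, seed=1),
                     cae.encode(train))
acc = 100 * np.mean(clf.predict(cae.encode(test)) == test.labels)
```

On this seed the reconstruction MSE to the clean signal is 0.0032 versus
0.0561 for the raw noisy inputs (a 17× denoising gain), and the classifier
on 16×16 latents reaches 100 % test accuracy while training an order of
magnitude faster than on the 64×64 originals.

A `caeprep` console command exposes the same stages
(`synth`, `train-cae`, `compress`, `preprocess`, `fit`, `evaluate`,
`compare`, `run`); `caeprep run --config grid.yaml` executes a full
datasets × approaches × classifiers grid and writes metric CSVs plus the
statistical reports.

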