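# flowpheno

Self-learning image analysis for brightfield imaging flow cytometry.

Imaging flow cytometry photographs every cell that passes through a
microfluidic channel instead of reducing it to scatter and fluorescence
intensities. That raises two computational problems this package
addresses for single yeast cells and calibration microspheres:

1. **Where is each object along the optical axis?** Defocus blurs the
   image as the distance |z| from the focal plane grows, so z can be
   regressed from a single brightfield crop ("depth from defocus") —
   absolutely for identical rigid beads, and pairwise for heterogeneous
   cells, where a siamese network predicts the signed z-distance between
   two images of the same cell.
2. **What is in the stream?** A variational autoencoder with a
   total-correlation penalty (FactorVAE) embeds single-cell crops into a
   10-dimensional latent space without labels; k-means on that space
   classifies species fully unsupervised, a linear SVM on ten annotated
   examples per species does it few-shot, and the same space supports
   nearest-neighbour and interpolation queries.

The FactorVAE objective is the evidence lower bound plus a penalty
`gamma * TC(q(z))`, where the total correlation
`TC = KL( q(z) || prod_j q(z_j) )` is estimated with the density-ratio
trick: a small discriminator learns to tell encoded latent batches from
batches whose dimensions were permuted independently across the batch,
and its mean logit difference estimates TC. Both depth regressors are
small stride-2 convolutional networks trained with Adam on augmented
z-stacks with 0.25 µm slice spacing.

A synthetic microscopy generator (`flowpheno.synth`) stands in for the
physical device — parametric cell phantoms (round, budding, rod,
lemon-shaped, bead), edge-localised brightfield contrast, defocus-
dependent blur with a signed through-focus asymmetry, Poisson-free
Gaussian noise, and in-flow frame sequences with complete ground truth —
so every stage is testable end to end without downloads. Cell-containing
frames are detected by the maximum-patch-variance rule (max patch
variance >= 2x whole-frame variance) and cropped to 128x128 around the
winning patch. All networks run on a compact numpy engine with
hand-written backward passes; no GPU or deep-learning framework is
required.

## Worked example

```python
import numpy as np
from flowpheno import experiments

# Signed depth-from-defocus on synthetic 6 µm beads:
# 30 training / 10 held-out z-stacks, 41 slices, 0.25 µm spacing.
bead = experiments.bead_recovery_experiment(seed=1)
print(f"bead MAE {bead['mae_um']:.2f} um, "
      f"sign agreement {bead['sign_agreement']:.2f}")

# Unsupervised vs few-shot species classification on 2000 in-flow
# crops of a 50/50 round-vs-rod mixture (reduced 64 px FactorVAE).
cls = experiments.classification_experiment(seed=1)
print(f"k-means {cls['kmeans_accuracy']:.2f}, "
      f"10-shot SVM {cls['fewshot_accuracy']:.2f}")
```

prints

```
bead MAE 0.45 um, sign agreement 1.00
k-means 0.56, 10-shot SVM 0.72
```

The bead regressor recovers the signed displacement to well under two
slice spacings and never confuses above-focus with below-focus — the
synthetic through-focus asymmetry makes the sign learnable, and the
suite's negative control shows it collapse to chance when that cue is
switched off. On the classification study, ten annotated examples per
species beat fully unsupervised k-means, reproducing the supervision
ordering of the platform this package models (74 % unsupervised vs 88 %
few-shot on real data); `docs/methods.md` discusses why full-latent
k-means sits near this level and where the architecture's ceiling is.

The command-line pipeline mirrors the library:

```bash
flowpheno --seed 7 simulate --preset yeast-mixture --n 500 --out runs/sim
flowpheno detect --in runs/sim --out runs/crops
flowpheno --seed 7 run --out runs/full     # end-to-end with manifest
```

Every run writes a JSON manifest (config snapshot, derived per-stage
seeds, artifact paths, timings); repeating a run from the same config is
byte-identical.

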