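# roigan

Cycle-consistent synthesis of **paired** medical images and their
region-of-interest (ROI) masks, with a-priori regional features fused into
the input domain.

## The problem

Medical imaging studies are chronically data-limited, and generative
augmentation usually produces images *without* the aligned lesion masks that
segmentation and radiomics work needs.  `roigan` implements a two-generator,
two-discriminator cycle model that translates between a medical-image domain
X and an ROI-mask domain Y and, from one trained model, synthesizes image
and mask *as a pair*.  The key ingredient is regional feature fusion: before
entering domain X, each image is multiplied by its mask to form the *region
image* (tumor intensities only), a small convolutional block (RFB) extracts
feature maps from it, and those maps are channel-concatenated with the
image.  The generators therefore see the ROI/non-ROI contrast explicitly.

For generators G: X→Y and F: Y→X with discriminators D_y, D_x the training
objective is

```
L = L_GAN(G, D_y) + L_GAN(F, D_x) + λ · L_cyc
L_GAN(G, D_y) = E[log D_y(y)] + E[log(1 − D_y(G(x)))]
L_cyc        = mean|F(G(x)) − x| + mean|G(F(y)) − y|
```

Image synthesis runs x → G(x) → F(G(x)); ROI synthesis runs
y → F(y) → G(F(y)) with the soft output thresholded at 0.5.  The networks
(mirror-pad + strided-conv encoder, instance norm, skip "fusion" layers,
transposed-conv decoder; 4×4 strided-conv discriminators) and their exact
shape contracts are documented in [docs/methods.md](docs/methods.md).  The
whole stack — layers, backprop, Adam — is implemented in NumPy, so nothing
beyond the scientific Python stack is required.

The package also ships the surrounding workflow: preprocessing for
PNG/DICOM/NIfTI pairs (lesion cropping, slice extraction, max normalization,
7:3 splitting), a synthetic phantom generator so everything is testable
without downloads, an evaluation suite (PSNR, SSIM, MS-SSIM, Dice, Hausdorff
distance, grayscale-histogram comparison, paired t-tests), and the
downstream augmentation-benefit experiment (pluggable feature extraction →
RFE with fivefold CV → kernel SVM → Acc/Sen/Spe/AUC).

## Worked example

Train a desk-scale model on noise-free 64×64 phantoms and synthesize a
paired image/ROI from a held-out phantom:

```python
import numpy as np
from roigan import (PhantomConfig, RoiCycleGan, TrainConfig,
                    generate_phantoms, dice)

cfg = PhantomConfig(image_size=64, n_samples=16, noise_sd=0.0,
                    background_level=0.3, tumor_contrast=0.4, seed=7)
model = RoiCycleGan(generate_phantoms(cfg),
                    TrainConfig.desk_scale(seed=0, max_steps=300))
res = model.fit()
print(res.summary())

held_out = generate_phantoms(PhantomConfig(image_size=64, n_samples=1,
                                           noise_sd=0.0, seed=99))[0]
pair = res.synthesize_pair(held_out)
print("Dice(true mask, synthetic ROI):",
      round(dice(held_out.mask, pair.synthetic_roi), 3))
print("MAE(F(G(x)), x):",
      round(float(np.abs(pair.synthetic_image - held_out.image).mean()), 4))
```

prints (≈7 minutes on one CPU):

```
Cycle-consistent paired synthesis (regional feature fusion)
============================================================
optimizer steps: 300   epochs: 19
image size: 64   cycle weight: 10.0
learning rate: 0.002   seed: 0
------------------------------------------------------------
term           first-20 mean    last-20 mean
L_GAN_fwd            -1.7659        -15.9424
L_GAN_bwd            -1.5319        -15.9424
L_cyc                 0.1503          0.0351
total                -1.7947        -31.5336
Dice(true mask, synthetic ROI): 0.994
MAE(F(G(x)), x): 0.0129
```

The cycle loss falls roughly fourfold over 300 steps; the synthesized ROI of
a held-out phantom overlaps the true mask almost perfectly, and the
reconstructed image is within ~0.013 intensity of the original (tumor
contrast is 0.4, so the reconstruction error is ~3% of the signal of
interest).  The adversarial terms drift strongly negative as the
discriminators sharpen faster than the generators can fool them — expected
for the saturating objective at this scale, and harmless here because the
cycle term dominates the generator update.

The same workflow is available from the shell:

```
roigan preprocess --input raw/ --format png --split 0.7 --seed 0 --out prep/
roigan train --data prep/train/manifest.csv --image-size 64 --max-steps 300 --out model.npz
roigan synthesize --ckpt model.npz --data prep/test/manifest.csv --out synthetic/
roigan evaluate --pairs prep/test/manifest.csv synthetic/manifest.csv --region tumor --out report.csv
roigan classify --train prep/train/manifest.csv --test prep/test/manifest.csv --augment synthetic/manifest.csv --out arms.csv
```

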