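# hippofactory

A desk-scale, fully testable **hippocampal subfield segmentation factory**:
an end-to-end pipeline that localizes the hippocampi in a 3D anatomical
volume, segments the subfields (DG, CA1, CA2, CA3, subiculum, plus optional
undifferentiated head/tail caps) with an ensemble of 3D attention-gated
residual U-Nets under test-time augmentation and voxel-wise plurality
voting, scores segmentations with Dice / Hausdorff / volumetric-similarity
metrics, and models lifespan volume trajectories with natural cubic
splines.  Every stage is verifiable offline against a built-in synthetic
hippocampus phantom generator — no image downloads, no pretrained weights,
no GPU.

Who it is for: researchers who want to study, extend or stress-test the
*mechanics* of protocol-aware ensemble subfield segmentation and lifespan
volumetry — loss modulation across incompatible rater protocols, bagging,
TTA fusion, vote-entropy uncertainty, spline/knee-point trajectory
analysis — on controlled synthetic data with known ground truth.

## The method

**ROI localization.** A template scene (with a paired left/right atlas) is
registered to the native volume by multi-resolution optimization of
mean-squared intensity error over rigid or affine parameters.  Atlas ROI
voxels are mapped through the recovered transform; per side, the axis-aligned
hull is expanded by a 16-voxel safety margin, cropped, Z-normalized
(mean 0, SD 1) and zero-padded so each dimension is a multiple of 8.

**Segmentation.** Each crop is augmented into 21 random versions (flips,
affine, elastic).  Every member of a bagged ensemble (default E = 5; each
member trained on an independent bootstrap resample with AdamW, a one-cycle
schedule and stochastic weight averaging) predicts every version; the
aligned stack of `E × 21` label maps is fused by voxel-wise plurality vote.
Per voxel, the vote entropy

&nbsp;&nbsp;&nbsp;&nbsp;`H = − Σₘ p̂ₘ ln p̂ₘ`

over the vote frequencies `p̂ₘ` is reported as an uncertainty map
(0 at unanimity, at most ln M).

**Training loss.** The focal Tversky loss per class,

&nbsp;&nbsp;&nbsp;&nbsp;`L = (1 − TP / (TP + β·FN + α·FP))^γ`,  α = 0.3, β = 0.7, γ = 3/4,

on soft (probability-mass) confusion counts, modulated per observation by
the rater's protocol: undistinguished classes (e.g. CA2-3) are merged by
summing predicted probability channels, and inside undifferentiated
head/tail labels all subfield probability is pooled into the cap's channel
so subfield predictions there are rewarded, not penalized.

**Evaluation.** `DC = 2|A∩B|/(|A|+|B|)`, symmetric Hausdorff distance on
voxel-centre point sets (mm when spacing is known), and
`VS = 1 − ||A|−|B||/(|A|+|B|)`.

**Lifespan analytics.** Per (region, sex), volume is regressed on a natural
cubic spline basis of age with the degrees of freedom chosen by AIC;
inflection ages of the fitted trajectory are detected with the kneedle
knee-point procedure; within each period between inflections, OLS of
`volume ~ age × sex` tests the age slope, sex offset and interaction with
Benjamini–Hochberg FDR correction; and a normalized anteroposterior profile
gives the per-slice subfield composition from head (0 %) to tail (100 %).

## Worked example

```python
import numpy as np
from hippofactory import phantom as ph, io_prep as iop, infer, metrics as mx
from hippofactory.loss import LossConfig
from hippofactory.model import ModelConfig
from hippofactory.train import Observation, TrainConfig, train_ensemble

train_set = []
for s in range(20):
    vol, lab = ph.make_hippocampus_phantom(ph.random_phantom_spec(s))
    train_set.append(Observation(image=iop.z_normalize(vol).data,
                                 target=lab.data))

ensemble = train_ensemble(train_set,
                          ModelConfig(depth=3, base_channels=8, n_classes=8),
                          LossConfig(),
                          TrainConfig(n_models=2, epochs=40, seed=0))
models = ensemble.models()

vol, lab = ph.make_hippocampus_phantom(ph.random_phantom_spec(100))
pred = infer.predict_crop(iop.z_normalize(vol).data, models,
                          infer.TtaConfig(seed=100))
report = mx.evaluate_pair(iop.LabelMap(data=pred.fused), lab,
                          labels=range(1, 8))
print(report.rows.round(3))
print("mean dice: %.3f" % report.rows.dice.mean())
```

Typical output (fresh run, seed 0; ~6 min of CPU training):

```
   label   dice  hausdorff     vs
0      1  0.988      1.000  0.995
1      2  0.984      1.000  0.992
2      3  0.993      1.000  0.997
3      4  0.984      1.414  0.999
4      5  0.977      1.000  0.979
5      6  0.997      1.000  0.997
6      7  0.996      1.414  0.999
mean dice: 0.988
```

Labels 1–7 are DG, CA1, CA2, CA3, SUB, HEAD and TAIL; Hausdorff distances
are in voxels (~1 voxel of boundary disagreement on a 32³ crop).

Per-class Dice near 0.99 on held-out phantoms says the ensemble + TTA
machinery works; on real MRI the absolute numbers would be far lower —
the phantom's class contrasts are cleaner than any scanner's.

A thin CLI mirrors the stages (`hippofactory phantom / extract / train /
segment / evaluate / lifespan`); run `hippofactory --help`.

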