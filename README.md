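# msunet

A multi-arm, dense-connectivity **3D U-Net for T2 lesion segmentation in
multiple sclerosis (MS)**, packaged with everything needed to exercise it
without clinical data: a synthetic multimodal phantom generator, the
composite training loss with its schedules, Monte-Carlo-dropout ensemble
inference, a lesion-wise evaluation protocol, and the longitudinal
clinical-trial endpoint analyses (percent lesion-volume change with ANCOVA,
Cox proportional hazards, Kaplan–Meier/log-rank).

## Who this is for

Researchers working on white-matter lesion quantification in MS trials:
T2-hyperintense lesion volume (TLV) and count are standard secondary
imaging endpoints, and manual annotation at trial scale is expensive and
rater-dependent. The package implements the full computational chain from
co-registered, skull-stripped T1w-pre-contrast (T1p), T2w and T2w-FLAIR
NIfTI volumes at ~1×1×3 mm³ to per-scan lesion masks and cohort-level
endpoint statistics. Because trial MRI is access-restricted, a first-class
phantom module generates data with the statistical structure the method
assumes (small-lesion-skewed size distribution, FLAIR/T2w hyperintensity,
per-arm longitudinal TLV drift, proportional-hazards event times), so every
stage is testable end to end on a laptop.

## The model

**Architecture.** Three encoder arms extract features in parallel: arm 1
from all three channels jointly, arm 2 from FLAIR only, arm 3 from T2w only
— the two contrasts carry partly disjoint lesion evidence. Each arm is four
levels of anisotropic residual blocks (1×3×3 + 3×3×3 convolutions, batch
norm, ReLU); the first downsampling keeps full through-plane resolution
(stride 1×2×2) so the receptive field in millimetres is near-isotropic
despite 3 mm slices. Connectivity is dense in two places: each encoder
block receives the *sum* of strided-1×1×1-downsampled features from all
shallower levels, and the decoder's skip input at each depth is the sum of
all levels' projected skip features resampled to that depth. Arms are
concatenated per level and projected by 1×1×1 convolutions; a single
decoder upsamples trilinearly and refines with residual blocks. Sigmoid
heads at the three finest levels give deep supervision; at the default
widths the multi-arm design has ~40% fewer parameters than a plain 3D U-Net
of the same level widths.

**Loss.** With voxelwise foreground probability `p_i`, label `q_i` and a
truncation threshold `γ`:

```
L = α·L_FG-ST + β·L_BG-ST + L_dice

ST(p) = -log γ + (1 - p²/γ²)/2   if p < γ        (quadratic cap)
ST(p) = -log p                    if p ≥ γ        (C¹ continuation)

L_dice = 1 - 2·Σ p_i q_i / (Σ p_i² + Σ q_i²)
```

`γ` ramps linearly 0.02 → 0.15 over training; `α` decays sigmoidally from
100 toward 1 with the patch lesion volume (small lesions weighted heavily)
while `β` grows toward 1. Level losses are summed unweighted.

**Inference.** Sliding 32×96×96 patches with 20% overlap are stitched by
count-normalised averaging; dropout stays active at inference (Monte-Carlo
dropout, 10 repeats per fold model, 3 cross-validation folds = 30 samples);
the voxelwise mean probability is thresholded at 0.5 and the sample SD is
the uncertainty map.

**Evaluation.** Lesions are 18-connected components of ≥ 3 voxels; a GT
lesion is detected if ≥ 10% of its voxels are predicted foreground, giving
lesion-wise true-positive / false-positive rates (LTPR/LFPR) alongside the
voxel-level dice/PPV/TPR, with size-stratified summaries (3–10, 11–50, 51+
voxels; at 1×1×3 mm³ a 10-voxel lesion is exactly 30 μL).

The network and its training loop run on a compact reverse-mode autodiff
engine over NumPy that ships inside the package (`msunet.nn`), so there is
no deep-learning-framework dependency.

## Worked example

```python
import numpy as np
from msunet.phantom import PhantomParams, generate_subject
from msunet.volume_io import VolumeGrid
from msunet.lesion_metrics import evaluate_scan, find_lesions

vol, mask = generate_subject(PhantomParams(), seed=7)
lesions = find_lesions(mask)
print(len(lesions), round(mask.tlv_uL, 1))
# 6 348.0        <- 6 lesions, 348 μL total on the 32x96x96 grid

report = evaluate_scan(mask, mask)   # self-comparison sanity check
print(report.dc, report.ltpr, report.lfpr)
# 1.0 1.0 0.0
```

Training a small model on phantoms and measuring held-out dice:

```python
from msunet.training import small_lesion_recovery_study
res = small_lesion_recovery_study(seed=11)
print(round(res["held_out_dice"], 3))
# 0.926  (depth-2 model, 200 patches, lesions >= 27 voxels, a few minutes on CPU)
```

The `msunet` command line wires the stages together; the desk-scale demo

```bash
msunet all-tiny --out runs/tiny --seed 0
```

simulates 36 subjects, trains the three cross-validation folds of a small
model, predicts with a 3-fold × 2-repeat MC ensemble, and writes per-scan
metrics (`evaluation.csv`), a cohort summary and endpoint analyses under
`runs/tiny/` with a reproducibility manifest (~2 minutes on one CPU). At
seed 0 the cohort summary reads

```json
{"dc": 0.803, "ppv": 0.701, "tpr": 0.981, "ltpr": 1.0, "lppv": 1.0,
 "lfpr": 0.0, "r_vol": 0.975, "r_count": 1.0}
```

— mean voxel dice 0.80 with every phantom lesion detected and no false
positive lesions, and predicted total lesion volumes correlating at
r = 0.98 with the ground truth across subjects.

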