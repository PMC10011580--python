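# Methods

This note documents the models, numerical choices and limitations of
`msunet` at the level of detail a maintainer or reviewer needs. Empirical
claims here are limited to what the test suite and `scripts/acceptance.py`
themselves compute.

## Coordinate and unit conventions

Arrays are indexed `(z, y, x)` (slices, rows, columns), 0-based; spacing is
quoted `(z, y, x)` in mm with the trial-resolution default `(3, 1, 1)`.
1 mm³ = 1 μL, so one voxel at that resolution is 3 μL and a 10-voxel lesion
is 30 μL. Volumes are assumed co-registered and skull-stripped (background
exactly 0); the NIfTI affine is preserved through I/O but never used for
resampling — registration, bias-field correction and skull stripping are
upstream of this package.

## Intensity normalisation

Per channel and per volume, over nonzero voxels only: min-max rescale to
[0, 1] (the acquisitions carry arbitrary scanner units; the target range is
a package choice), clip to the 1st–99th percentile band, then z-score with
the mean/SD of the in-band voxels. A constant channel raises rather than
silently dividing by a guarded σ (floor 1e-8). Computing statistics per
volume rather than per dataset is a deliberate choice (configurable in
principle, flagged here): it makes subjects independent and inference
stateless, at the cost of ignoring cross-scan intensity structure.

## Patch extraction and augmentation

Sliding 32×96×96 windows (z×y×x) with 20% overlap; stride is
`ceil(patch·(1−overlap))` per axis with the final origin clamped to the
boundary, so the union always covers the (zero-padded, if the volume is
smaller than a patch) grid. Training and validation keep only
lesion-containing patches; negative patches are excluded.

Augmentation applies, with probability 0.5, an in-plane affine (rotation
≤ 10°, scale 0.9–1.1, translation ≤ 5 voxels) followed by an elastic field
(Gaussian-smoothed white noise, σ = 4 voxels, peak-normalised to ≤ 3 voxels
in-plane / ≤ 1 through-plane), the identical warp on image (linear) and
label (nearest neighbour). Magnitudes are conservative by design: the
bounds guarantee a 3×3×3 lesion cannot be annihilated, which the property
tests exercise. All magnitudes are config fields, not literals.

## Network

Three encoder arms: (T1p, T2w, FLAIR) jointly; FLAIR alone; T2w alone.
Residual block = 1×3×3 conv → BN → ReLU → 3×3×3 conv → BN, plus an identity
(or 1×1×1-projected) shortcut, final ReLU; `isotropic_convs=True` switches
the first conv to 3×3×3 for 1 mm³ inputs. Four levels; downsampling strides
(1,2,2) then (2,2,2), (2,2,2) — keeping full z-resolution at the first
transition balances the mm receptive field given 3 mm slices. The analytic
receptive field of the deepest encoder output at the defaults is 17×61×61
voxels = 51×61×61 mm (max/min ratio 1.20), checked in the tests against a
gradient-footprint probe on a built model with all units active.

Design choices where the architecture description leaves freedom:

* **Dense encoder inputs.** The block at level d receives the sum of
  *strided 1×1×1 convolutions* of all shallower levels' features (the
  stride is the cumulative inter-level stride). Summation happens at the
  block input. A 1×1×1 kernel is the lightest faithful reading of
  "downsampled with strided convolutions and summed"; spatial mixing is
  provided by the residual blocks themselves.
* **Arm widths.** Each arm runs at `ceil(F/3)` channels where `F` is the
  level width; the three arms' concatenation (~F channels) is projected
  back to `F` by a 1×1×1 convolution. This is the reading under which the
  multi-arm network has *fewer* parameters than a single-encoder 3D U-Net
  with the same level widths, as the design intends; full-width arms would
  have roughly twice as many. At the default widths (32, 64, 128, 256) the
  counts are ~2.55 M (multi-arm) vs ~4.40 M (plain baseline, same residual
  blocks, plain skips), a 42% reduction. The originally reported counts of
  this architecture family used per-level widths not restated here; the
  comparison's direction and approximate magnitude are what the acceptance
  checks assert, and `scripts/acceptance.py` reports the counts computed
  from the configuration it builds.
* **Dense skips.** Skip features are summed across levels after resampling:
  trilinear interpolation upward, strided 1×1×1 convolutions downward, a
  1×1×1 conv adapting widths in either direction.
* **Decoder.** Trilinear upsampling, concatenation with the fused skip,
  one residual block per level. Only the finest head is used at inference;
  the coarse heads exist for deep supervision.
* **Dropout** (rate 0.2 default) sits immediately before each prediction
  head; placement and rate are not specified by the architecture
  description and are config fields. The same layers drive MC sampling.

The layers run on `msunet.nn`, a tape-based reverse-mode autodiff engine
over NumPy written for this package (conv3d as offset-indexed GEMMs in a
channels-last working layout; trilinear resizing as per-axis interpolation
matrices whose transposes give exact adjoints). Every primitive is verified
against central finite differences in float64.

## Loss

`L = α·L_FG-ST + β·L_BG-ST + L_dice` per supervised level, levels summed
unweighted. The smooth truncated cross-entropy replaces `−log p` below `γ`
by the quadratic `−log γ + (1 − p²/γ²)/2`. For `p ≥ γ` this implementation
uses `−log p`, the unique C¹-continuous completion (both one-sided
derivatives at the knot equal `−1/γ`); the truncation's purpose is to cap
the influence of confidently wrong voxels, and the alternative constant
completion `−log γ` — which has zero gradient wherever the prediction is
already above the threshold — is available as `truncated_variant="printed"`
for comparison. The background term evaluates ST at the predicted
background probability `1 − p`.

Schedules: `γ` linear from 0.02 to 0.15 over the epoch budget (the ramp
shape is a package choice; only the endpoints are prescribed);
`α(v) = 1 + 99·σ(−(v−v₀)/s)` and `β(v) = σ((v−v₀)/s)` with the *patch*
foreground volume `v` (the per-patch reading makes the weight available
online during training), midpoint `v₀ = 100` voxels and steepness `s = 50`
as defaults. Soft dice uses ε = 1e-6 in numerator and denominator so
empty-vs-empty gives loss 0. Targets are max-pooled (not nearest-sampled)
to coarse supervision levels so single-voxel lesions stay present.

## Training

Adam, lr 1e-4, batch 10, 30 epochs, half the patches augmented — the
trial-scale recipe, all configurable. The batch forward is shared; losses
are computed per patch (α/β depend on each patch's lesion volume) on slices
of the batched prediction and averaged. Checkpoint selection is by best
validation soft dice (a selection rule had to be chosen; validation dice is
the quantity reported downstream). Folds are split at the patient level
with sizes differing by ≤ 1; epoch shuffling is seeded by (run seed,
epoch), so a rerun reproduces the history exactly. NaN loss aborts with the
last finite loss breakdown attached.

The desk-scale recovery study (`small_lesion_recovery_study`) trains a
depth-2, filters-(8,16) model (arm widths (3,6)) on 200 single-patch
phantoms of 8×24×24 voxels whose lesions are all ≥ 27 voxels, lr 1e-2,
12 epochs — sizes chosen so the full train/predict/score chain demonstrates
parameter recovery in minutes on one CPU. It reaches held-out mean dice
≈ 0.93 at the tested seed (asserted ≥ 0.80).

## Inference

Patch probabilities are stitched by count-normalised accumulation (exact
partition of unity for constant inputs). MC dropout keeps dropout active in
eval mode with per-layer seeded streams: n = 10 repeats per fold model,
3 folds = 30 samples; voxelwise mean → threshold 0.5 (ties count as
foreground — a direction had to be fixed), voxelwise SD as the uncertainty
map. Only the finest head is used.

## Lesion-wise evaluation

18-connectivity means sharing a face or an edge (≤ 2 nonzero coordinate
offsets), never a corner; components < 3 voxels are excluded — the common
MS convention independent of voxel size. Detection is mask-overlap based:
a GT lesion is detected iff ≥ 10% of its voxels are predicted foreground;
a predicted lesion is a false positive iff < 10% of its voxels overlap GT.
Matching against the opposing *mask* rather than paired components keeps
splits/merges well-defined. Conventions for degenerate scans are explicit
because cohort means shift with them: empty GT and empty prediction give
DC = PPV = TPR = 1; rates whose denominator is empty (LTPR with no GT
lesions, LFPR/LPPV with no predictions, PPV with an empty prediction) are
NaN and excluded from cohort means. Per-lesion dice for the size-stratified
summary is computed on the GT lesion's bounding box dilated by one voxel
(capturing the overlapping prediction). Size bins: 3–10, 11–50, 51+ voxels.

## Phantoms

Subjects: an ellipsoidal brain support on a 32×96×96 grid at (3,1,1) mm;
lesions are volume-preserving randomly deformed ellipsoids, near-spherical
in mm, placed without overlap and with a one-voxel exclusion margin so the
component count is exactly the placed count under 18-connectivity. Sizes
follow a log-normal over voxels (median 12, σ_log 1.1) truncated at ≥ 3,
giving ~40% of lesions ≤ 10 voxels and ~90% ≤ 50 — the small-lesion-skewed
regime of MS trial cohorts (where roughly 41–46% of lesions are ≤ 10 voxels
and ~83–84% ≤ 50). Contrast is expressed in units of a reference intensity
scale: FLAIR +3, T2w +2.5, T1p −1, with independent Gaussian noise; lesions
are crisp (no partial-volume modelling) so detection oracles stay exact.
What phantoms deliberately lack: MR physics, bias fields, texture,
anatomical structure, annotation noise — passing tests demonstrate that the
mechanisms work, not that clinical-grade accuracy transfers to real MRI.

Cohorts: baseline TLV log-normal (median 6 mL, σ_log 1, mean ≈ 10 mL, the
scale of RMS/PPMS trial populations); per-week multiplicative drift
defaults −0.025%/week (treatment) and +0.085%/week (control), i.e. ≈ −3%
and ≈ +11% at week 120 with log-normal visit noise; event times exponential
with hazard `λ₀·exp(b·log TLV_mL + c·arm)`, λ₀ = 0.0012/week (≈ 14% events
by week 120), b = ln 1.2 by default; censoring at end of follow-up.

## Endpoint analyses

* Percent TLV change: per patient `100·(TLV_w − TLV_0)/TLV_0`, averaged per
  arm/week; zero-baseline patients excluded and counted.
* ANCOVA at the final week: `pct_change ~ arm + baseline_TLV + region +
  age_group` (region US/ROW, age dichotomised at 45). Baseline TLV enters
  as a covariate — the analysis description is ambiguous on this point and
  the choice is stated here; single-level covariates are dropped with a
  warning. OLS via statsmodels; arm contrast with two-sided p.
* Cox PH (lifelines): univariable `outcome ~ metric` with metric either
  log TLV (mL) or lesion count; multivariable adds arm, sex, region, EDSS
  group, age and the arm×metric interaction, guarded to ≥ 10 events.
* KM/log-rank (lifelines): dichotomisation at the *whole-cohort* median
  applied within each arm stratum; Greenwood CIs; strata with an empty
  median side are skipped with a flag.

Because the original endpoint numbers come from access-restricted trial
data, these routines are validated by simulation instead: type-I error of
the ANCOVA within binomial 3σ of 0.05 over 200 null replicates, Cox
recovery of a known log-HR within 3 SE with ≥ 93% CI coverage over 100
replicates, and ≥ 95% log-rank power at a rate ratio of 2 with n = 300.
Significance is two-sided at 0.05 throughout.

## Reproducibility

All randomness descends from one seed through named `SeedSequence`
substreams (phantoms, folds, shuffling, augmentation, dropout). A pipeline
run persists its full config and a manifest with output checksums; a rerun
from the persisted config reproduces the evaluation CSV byte-for-byte
(tested). Checkpoints are single-file npz bundles embedding the network
config and format version.

## Known limitations

* No GPU path; the NumPy engine is single-threaded apart from BLAS, so
  trial-scale training (30 epochs on hundreds of patients) is out of reach
  — the design is validated at reduced problem sizes stated above.
* New/enlarging-lesion (longitudinal difference) segmentation is out of
  scope.
* The exact per-level filter widths of the originally reported 5.9 M-
  parameter configuration are not public; parameter counts here are for
  this package's defaults, with the multi-arm-vs-plain reduction asserted
  directionally.
* Probability calibration of the ensemble output is not attempted; 0.5 is
  the operating threshold throughout.
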