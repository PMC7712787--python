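# Methods

`nacresp` re-implements, as a tested pipeline on synthetic data, an early
response-prediction analysis for advanced breast cancer under neoadjuvant
chemotherapy (NAC): conventional PET/MRI parameters and their percent
changes between a baseline scan and an interim scan after the first
chemotherapy cycle, ROC-based discrimination of histopathologic responders,
and a small convolutional network trained on 64×64 lesion crops. Clinical
cohorts of this kind are private, so the package ships a phantom generator
that emulates the study design with known ground truth; every downstream
claim the tests make is a claim about this synthetic world, made explicit
below.

## The phantom cohort

Each synthetic patient carries four image studies on a common voxel grid
(default 64³ at 2 mm isotropic): baseline and interim PET SUV volumes, and
baseline and interim DWI pairs at b = 0 and b = 800 s/mm². Tumors are
ellipsoids with semi-axes drawn uniformly from 8–20 mm, centered on a voxel
(jittered a few voxels around the grid center so the noiseless peak is
always attained exactly at one voxel center).

**PET model.** The in-tumor SUV profile falls quadratically from the peak at
the center to 40% of the peak at the rim, on a uniform background (default
SUV 0.3). The quadratic profile keeps SUVmax unambiguous and, once the peak
decays below 2.5/0.4, moves the MTV segmentation boundary inside the tumor —
so responder ΔMTV saturates near −100%, the direction the clinical cutoffs
point. Noise is multiplicative Gaussian with relative sd `noise_sigma`
(default 5%), floored at zero.

**DWI model.** A ground-truth ADC field (uniform tumor value on a
fibroglandular-like background of 1.6×10⁻³ mm²/s) generates signals
S(b) = S₀·exp(−b·ADC) with Rician noise of scale `noise_sigma`·S₀, the
standard magnitude-image model. With zero noise the two-point ADC map
inverts this exactly (round-trip asserted to 1e−9 relative error).

**Effect structure.** Responders (Miller–Payne grade 4–5 by construction)
draw large metabolic declines and ADC rises; non-responders small changes.
Defaults (mean ± sd, percent): ΔSUV −70±15 vs −20±15; ΔMTV −85±10 vs
−30±20; ΔADC +40±15 vs +5±15; baseline SUVmax lognormal with mean 8, sd 3
(floored at 3); baseline tumor ADC 1.0±0.15 ×10⁻³ mm²/s. The responder and
non-responder means deliberately straddle the clinically reported optimal
cutoffs (ΔSUV ≈ −56%, ΔADC ≈ +25%) without claiming to match the clinical
cohort's distributions, which are not public. Draws are truncated where
physics demands it (interim peak must stay above background, tumor ADC
below background ADC); the *post-truncation* value is recorded as that
patient's ground truth, so recovery tests compare against the realized
effect. Interim tumors shrink their radii by the cube root of the drawn
volume change and scale their peak by the drawn SUV change, coupling
volumetric and intensity effects.

**Receptor flags** (ER/PR/HER2) are drawn independently per patient with
class-conditional prevalences typical of such cohorts (responders enriched
for receptor-negative disease); they exist to exercise the HER2-negative and
triple-negative subgroup analyses, not to model biology.

**Texture option.** With `texture_flag` on, responder tumors receive a
smoothed multiplicative speckle field (amplitude 0.4, Gaussian smoothing
1.2 voxels, clipped to keep values positive). This creates a class signal
that survives per-image min–max normalization and is invisible to the
conventional parameters — the substrate for testing that the CNN can find
information the scalar parameters miss.

**Randomness.** One top-level seed; patient *i* uses the substream keyed by
`(seed, i)`, so enlarging a cohort never reshuffles earlier patients.
Identical configs are bit-identical.

What the phantoms do **not** model: anatomical background tissue, scanner
point-spread/partial-volume effects, registration error between PET and MR,
multi-focal disease, non-ellipsoidal shapes, and any correlation between
lesion geometry and receptor status. Tests passing on phantoms therefore
validate the *measurement and analysis chain*, not clinical performance;
the clinically reported AUCs are not reproduction targets.

## Conventional parameters

A voxel belongs to an ellipsoid VOI or circular ROI iff its **center**
satisfies the region inequality, and the SUV threshold is **inclusive**
(≥ 2.5); both conventions are pinned by exhaustive-enumeration oracle
tests. SUVmax is the in-VOI maximum; MTV is the qualifying voxel count
times voxel volume (mL); TLG is MTV times the qualifying-voxel mean SUV.
ADC maps use the two-point formula ln(S_b0/S_b800)/800; voxels with signal
below `signal_floor` (default 1.0 in S₀≈1000 units) are invalid and
excluded from ROI means, and noise-induced negative ADC clamps to zero.
ADC is reported in 10⁻³ mm²/s; volumes store raw mm²/s. Percent changes
are (interim − baseline)×100/baseline and are *missing* when the baseline
is zero (a sub-threshold baseline lesion has MTV0 = TLG0 = 0, so ΔMTV and
ΔTLG are undefined and that patient is excluded from those ROCs, with
per-parameter n reported). In the pipeline, VOI/ROI placement uses
generator ground truth (the true tumor ellipsoid; the ADC ROI is a circle
of 60% of the smaller in-plane semi-axis on the center slice); manual
placement is out of scope.

## ROC analysis

AUC via the Mann–Whitney identity with ties counted ½, exact against a
pair-enumeration oracle. The score orientation (responders low vs high) is
chosen so AUC ≥ 0.5 and reported. The 95% CI and the p-value against
AUC = 0.5 use the DeLong variance with a normal approximation; under
perfect separation the variance degenerates to zero and the CI collapses
onto the AUC (reported as such, p = 0). The optimal cutoff maximizes
Youden's J over midpoints between adjacent distinct observed values (plus
sentinels beyond the extremes); ties prefer higher sensitivity, then the
more extreme threshold — a deterministic reporting rule. The pre/post
augmentation comparison uses a two-sided Mann–Whitney U test: exact
enumeration of all label assignments on midranks when both samples have
≤ 8 values (the k = 3 fold-metric comparisons always take this path),
otherwise scipy's tie-corrected normal approximation.

## CNN classifier

Architecture: two 5×5 convolution layers of 32 filters with ReLU and 2×2
max-pooling, then two fully-connected layers (hidden width 256) with
dropout 0.5 at both, softmax cross-entropy loss, Adam. Unstated
hyperparameters are package defaults, all overridable: learning rate 1e−4,
batch size 16, 100 epochs, no early stopping. The network is implemented
directly on numpy (im2col convolutions; gradients verified against finite
differences); at these input sizes and sample counts one fold trains in
seconds to a few minutes on one CPU core, and training is bit-reproducible
for fixed seeds on a fixed platform.

Crops are taken per patient at the axial slice with the largest lesion
cross-section (for PET, voxels ≥ 2.5 inside the VOI, falling back to the
VOI itself when the whole lesion is sub-threshold; for ADC, the VOI area;
ties break to the lowest slice index): a square window of the tight
bounding-box side plus 20% margin, bilinearly resized to 64×64 and min–max
normalized per image. Per-image normalization removes absolute-SUV
shortcuts, so the network must use morphology, contrast structure and
texture. Responder crops are augmented with seven rotations in 45°
increments (90° multiples are exact axis permutations; odd multiples are
bilinear with zero-filled corners; rotation happens after
resize/normalization). Four independent single-channel models are trained
(PET0, PET1, MRI0, MRI1); there is no fusion model.

Splitting is at the **patient** level, stratified by label: 80/20
train/test, then 3 stratified folds of the training patients; every crop
of a patient — including its rotated copies — stays on one side of every
boundary, which the tests assert exhaustively. The design leaves open
whether image-level splitting (which lets rotations of one patient
straddle the boundary) was used in the original clinical analysis;
patient-level is the leakage-safe choice and is what this package does.
Validation metrics are fold means (the fold median AUC is also emitted);
test metrics come from the fold ensemble, whose responder probability is
the mean softmax output of the three models, thresholded at 0.5.

## Pipeline and reproducibility

`nacresp run --config cfg.yaml` executes simulate → quantify → ROC → CNN →
report. Every stated constant of the study design (SUV threshold 2.5, crop
size 64, 45° rotation step, 7 rotations, 80/20 split, 3 folds, b = 0/800)
appears once, named, in defaults. The report embeds the config hash, seeds
and package versions; identical configs reproduce every number exactly
(timestamps excluded), asserted end-to-end in the tests. Stage failures
abort with a stage-labelled error. Subgroup ROC rows that cannot be
computed (e.g. a triple-negative subgroup without responders) are emitted
as null rows with a note; a single-class *full* cohort is an error.

## Problem sizes used in the shipped checks

The test suite and the acceptance script scale the study down to run
comfortably on one CPU core: unit fixtures use 24³–32³ grids; the
effect-recovery check uses a noiseless 100-patient cohort at 48³; the
texture-learnability check uses 200 patients at 48³ with 10 training
epochs; the end-to-end acceptance run uses the full 6+50 cohort at the
default 64³ grid with 12 epochs per fold. These sizes are the package's
own desk-scale defaults for its synthetic world; the epoch budget is a
free parameter and nothing in the analysis depends on wall-clock time.

## Known limitations

* Multi-focal lesions are not handled (one tumor per patient); how the
  original analysis merged multiple lesions is unspecified.
* The DeLong CI is one of several reasonable choices; clinical software
  defaults differ, and no numerical agreement with published CIs is claimed.
* The CNN comparison inherits everything the phantom lacks (see above);
  in particular, the texture-learnability result shows the network can
  exploit intratumoral structure, not that it would on clinical images.
* Three-direction diffusion averaging is collapsed: the generator emits
  trace-weighted signal directly.
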