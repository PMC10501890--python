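# Methods

`pedbrain` re-implements, end to end and at desk scale, a clinical image
analysis pipeline for the four common posterior-fossa-era paediatric brain
tumors (ependymoma, medulloblastoma, pilocytic astrocytoma, brainstem
glioma): cascaded deep-learning segmentation of multi-sequence MRI,
heuristic extraction of radiologist-style semantic features, rule-based
subtype prediction, and the evaluation/statistics layer that such a study
reports.  Because the clinical cohort behind the original study is
private, the package ships a synthetic phantom generator that realizes
known feature profiles in voxel data; every stage is tested against that
ground truth.

## Pipeline

1. **Preprocessing** (`preprocess`).  Intensities live on a fixed absolute
   scale.  The 3D lobe network receives volumes clipped to [0, 2030] and
   standardized as `(v − 730)/361`; the 2D tumor networks receive slices
   clipped to [0, 2030] and min-max normalized with anchors 162 and 2030.
   The min-max anchors leave clipped values in [0, 162) slightly negative,
   so the output is clamped to [0, 1] (logged when it happens).  Both maps
   are monotone and exactly invertible on their non-clipped ranges.
   Resampling uses linear interpolation for intensities and nearest
   neighbour for label maps.  Cohort splitting is a seeded shuffle with
   largest-remainder size allocation (the 94-case reference split
   64/9/21 is expressed as proportions so it generalizes).

2. **Lobe segmentation** (`lobe_net`).  A 3D U-Net (configurable depth and
   base channels; phantom preset: depth 2, 8 base channels, one
   convolution per block) labels each brain voxel forebrain / brainstem /
   cerebellum from T1.  The Dice loss and prediction argmax are restricted
   to brain voxels, with "brain" defined by a fixed raw-intensity
   threshold (200) that cleanly separates tissue from air on phantoms.
   The location of a tumor is later the lobe with maximal overlap.

3. **Tumor cascade** (`tumor_net`).  Stage 1 segments the whole tumor on
   axial post-contrast T1 slices; stage 2 receives the original slice
   stacked with a whole-tumor guide mask (ground truth under teacher
   forcing, the stage-1 probability map at inference) and splits the
   tumor into enhancing and non-enhancing compartments.  Stage-2 labels
   are kept only where stage 1 fires, so the cascade is monotone; final
   connected components smaller than `min_component_vox` (default 5) are
   removed, and a scan is called abnormal iff a component survives.

4. **Semantic features** (`features`).  All rules compare against robust
   grey-matter statistics (median and MAD-derived SD per sequence).
   Intensity classes use a ±10% iso-band around the GM median;
   haemorrhage is a connected focus (≥ 5 voxels) of T1 signal above
   GM + 2 SD; cyst/necrosis candidates are connected non-enhancing
   components clearly T2-bright and T1-dark (±25% margins), flagged cyst
   if more than 75% of their voxels are FLAIR-suppressed (below
   GM − 1 SD) and necrosis if fewer than 25% are, with the 25–75% band
   deliberately setting neither flag; diffusion restriction requires
   tumor DWI above the reference by 2 SD *and*, when ADC is present,
   tumor ADC below 0.8 of the reference (the AND guards against T2
   shine-through); enhancement grade bins the enhancing voxel fraction at
   25% and 75% with both boundaries assigned to "moderate"; enhancement
   pattern is heterogeneous when the coefficient of variation of
   post-contrast T1 inside the enhancing mask exceeds 0.3.  Every
   threshold lives in one `FeatureThresholds` block.

5. **Classification** (`classify`).  The original study never printed its
   decision logic, only that type follows from predicted site and
   features; the default ruleset here is reverse-engineered from the
   cohort's site prevalences and odds ratios and is the package's single
   largest interpolation: (1) brainstem location → brainstem glioma
   (every brainstem tumor in the cohort is one); (2) cerebellar location
   with diffusion restriction → medulloblastoma; (3) necrosis, then
   haemorrhage → ependymoma; (4) default → pilocytic astrocytoma.  Rule
   order follows the strength of the cohort associations.  The ruleset is
   an ordered first-match-wins list, overridable from YAML.

6. **Evaluation and statistics** (`metrics`, `stats`).  Dice, HD95 (max
   of the two directed 95th-percentile boundary distances, exact
   Euclidean distance transform, anisotropic spacing; undefined for empty
   masks, Dice 1 for two empty masks), sensitivity/specificity/PPV/NPV/
   accuracy with undefined denominators reported as missing, Cohen's
   kappa with marginal-product chance agreement, and mean/SD/quartile
   aggregation (linear type-7 quartiles).  The univariate layer is
   Pearson chi-square without continuity correction — the convention that
   reproduces the reference cohort's printed three-decimal p-values from
   its printed counts — plus 2×2 odds ratios with Woolf CIs and optional
   Haldane correction.  The multivariable layer is ordinary
   maximum-likelihood logistic regression (statsmodels backend) with
   explicit separation detection.

## The phantom generator

The generator (`phantom`) is the package's study-condition definition,
not a tuning knob.  A phantom brain is three disjoint solids — a large
forebrain ellipsoid, an inferior-posterior cerebellar ellipsoid and an
inferior-central brainstem cylinder — with a 2-voxel grey-matter rim
inside the forebrain surface serving as the intensity reference
(GM ≈ 730, centring the pipeline's standardization mean on tissue).
Tissue and lesion intensities are constants inside [0, 2030] plus
additive Gaussian noise (default SD 25); noise-free values never clip.

A tumor is a sphere placed at the deepest point of its target lobe
(jittered, never inside the grey-matter rim; the radius shrinks to fit
small lobes).  The requested feature profile is realized exactly in the
voxel data: the enhancing/non-enhancing split is carved to a voxel
fraction inside the requested grade band (0.12 / 0.50 / 0.80); cyst and
necrosis are separate non-enhancing components, T2-bright and T1-dark,
with FLAIR forced far below (480) or above (800) the suppression
threshold so their suppression fractions land beyond the 75%/25% cuts;
haemorrhage appears as 1–3 ~12-voxel foci at T1 ≈ 980 (≈ 10 noise SDs
above GM); diffusion restriction scales DWI ×1.4 and ADC ×0.55 across
the tumor.  Cohorts are sampled either from the reference cohort's
per-class feature prevalences (diverse, used for feature-recovery tests)
or as each class's modal "typical" profile (used for the
generator-plus-ruleset self-consistency check, since the printed tables
give only marginal prevalences and independent sampling of marginals
produces feature combinations — e.g. a restricting cerebellar ependymoma
— that no fixed ruleset can resolve).

What the phantoms deliberately omit: skulls, bias fields, partial-volume
gradients, anatomical variability, k-space artefacts, and any overlap
between tumor and normal-tissue intensity distributions beyond additive
noise.  Passing tests therefore demonstrate the internal consistency of
the pipeline — that each stage recovers what the generator encoded — not
clinical performance; the original study's real-cohort accuracies are
out of reach by construction.

## Training at desk scale

The networks are small U-Nets written directly in numpy (im2col + GEMM
convolutions, hand-derived backprop, Adam), trained with the soft Dice
loss as the sole objective.  Backprop is verified against central finite
differences in float64.

Dice-loss training with ~1% foreground is bistable at this scale: a
sigmoid head that suppresses everything before foreground features form
saturates, its gradient underflows to exactly zero in float32, and the
run freezes in an empty-prediction state.  Three measures keep stage 1
out of that basin, and together they proved stable across every probe
seed tried: (1) balanced slice sampling — all tumor-bearing slices plus
an equal draw of empty ones (normal scans contribute background only);
(2) per-slice rather than per-batch Dice normalisation, so each tumor
slice keeps its own denominator; (3) output-bias initialisation at −2,
starting the head near the background prior instead of p = 0.5.  The
lobe network and cascade stage 2 need none of this because their losses
are masked to regions (brain, whole tumor) where classes are roughly
balanced.

Phantom-preset problem sizes, chosen once as the package's desk-scale
conditions: 64×64×32 phantom voxel grids (the full 240×240×155 /
256×256×24 / 512×512 cohort geometry remains a configuration option),
a 48×48 cascade working resolution (native slices are resampled in and
predictions resampled back; at desk scale this resolution trains
collapse-free where larger working grids are bistable), a 64×64×16 lobe
input grid, depth-2 U-Nets with 8 base channels, ~28 epochs for stage 1
and ~10–12 for stage 2 and the lobe network, Adam at 1e-3.  As a last
safety net, a stage-1 run that still ends in the collapse signature
(training loss above 0.4) is deterministically retrained with a shifted
initialisation seed, at most twice.  The full-scale epoch budgets
(50 lobe with early stopping, 35/40 cascade) are the config defaults.

## Statistics conventions

* Chi-square: Pearson, no continuity correction, zero-margin levels
  dropped with a warning; per-feature row-wise deletion of missing
  values (the reference cohort's clinical rows use per-feature
  denominators).
* Odds-ratio recovery: the logistic layer is validated by simulation —
  independent Bernoulli predictors, outcome from a logistic model with
  known coefficients (true ORs 16 and 5, the magnitudes of the reference
  cohort's strongest multivariable effects).  A single n = 500 cohort
  carries a log-OR standard error near 0.25 for an effect that large, so
  recovery is judged on the geometric-mean estimate over ten replicate
  cohorts, which isolates bias from single-draw noise.
* Kappa: implemented from the closed formula; degenerate marginals
  (chance agreement 1) are reported as undefined rather than raising.

## Known limitations

* The diagnostic ruleset is an interpolation of unpublished logic;
  treat its labels as a demonstration of the architecture, not as a
  validated classifier.
* The stage-1 training recipe is tuned for conspicuous phantom lesions;
  real data would need augmentation, more capacity and far more epochs.
* HD95 is computed between boundary-voxel centres; sub-voxel surface
  models would differ by up to half a voxel spacing.
* The brain mask is a fixed intensity threshold; real scans would need
  skull stripping, which the pipeline deliberately omits.
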