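# Methods

## What is being modelled

The package simulates the measurement chain that turns short-axis cine CMR
segmentations into a 2010 Task Force Criteria (TFC) classification for
subjects evaluated for arrhythmogenic right ventricular cardiomyopathy
(ARVC), and the evaluation chain that compares an automatic-style
segmentation against a manual reference. No real images are consumed;
everything runs on label-volume phantoms whose ground truth is known by
construction, so every estimator in the package can be validated by
parameter recovery.

## Synthetic cohort

**Subjects.** Three groups — controls, at-risk family members, ARVC
patients — drawn by deterministic largest-remainder apportionment of the
configured proportions (default 54/157, 66/157, 37/157; a multinomial draw
is available instead). Per subject: sex (59 % female), age (36.9 ± 17.6 y,
clipped to 16–85), body surface area (1.90 ± 0.20 m², clipped to 1.3–2.6),
a regional wall-motion-abnormality (RWMA) flag, a non-CMR TFC point total,
and per-ventricle EDVI and EF drawn from group-specific normals:

| group | RVEDVI (ml/m²) | RVEF (%) | LVEDVI | LVEF | P(RWMA) |
|---|---|---|---|---|---|
| control | 76 ± 10 | 58 ± 5 | 80 ± 10 | 60 ± 5 | 0.02 |
| at-risk | 80 ± 10 | 54 ± 5 | 82 ± 10 | 58 ± 5 | 0.15 |
| ARVC | 108 ± 16 | 38 ± 7 | 88 ± 12 | 52 ± 6 | 0.90 |

No published per-group distribution tables exist at this granularity; these
values are plausible clinical magnitudes chosen once so that roughly 84 % of
ARVC subjects and a few percent of at-risk subjects meet a minor or major
CMR criterion (RWMA × threshold products: 0.90 × ≈0.93 and 0.15 × ≈0.13).
They are calibration targets, not guarantees, and are fully configurable via
`CohortConfig.group_params`. Non-CMR point totals are small discrete
distributions per group (ARVC centred on 3, at-risk on 1, controls near 0),
giving ARVC subjects realistic pre-imaging scores so that the CMR category
decides marginal diagnoses.

**Cardiac cycle.** Volume over the cycle is a piecewise raised cosine with
the maximum (EDV) fixed at phase 0 and the minimum (ESV) at
`round(f·n_phases)` with `f` ~ N(0.38, 0.03) clipped to (0.25, 0.55);
the curve is strictly monotone on both branches, so argmax/argmin phase
selection has a unique, known answer. Phase counts are drawn from 25–40,
in-plane spacing from 1.11–1.45 mm, slice thickness from 7–10 mm — the
acquisition ranges typical of clinical short-axis stacks.

**Phantom geometry.** On each slice the LV is a disc and the RV the
crescent formed by a second (slightly anisotropic) disc clipped against the
LV; per-slice voxel budgets taper quadratically from base to apex (radius
factor 0.55 at the apex). Rasterization ranks voxels once per grid by
squared distance to each structure's centre and takes exactly the first N,
so per-phase voxel-counted volumes match the target curves to voxel
rounding — far inside the 5 % fidelity contract the tests assert. One slice
is kept empty below the apex and above the base so that "outside the
heart" errors have somewhere to live. The geometry is deliberately crude
(no trabeculation, papillary muscles, or outflow tract): it exists to
exercise the downstream operators, not to look like an MR image.

**Degradation model.** The "automatic-like" segmentation flips a budget of
`error_fraction` (default 0.05) × foreground voxels per structure at the ED
and ES phases (the phases measurements use; a flag extends this to all
phases). The budget is split multinomially over four slice categories —
most basal, mid-ventricular, most apical, outside the extent — with
defaults RV (0.307, 0.61, 0.054, 0.029) and LV (0.183, 0.70, 0.075, 0.042).
Within basal/mid/apical the flips are balanced between deletions (structure
→ background) and additions (background adjacent to the structure, found by
a 2-step in-plane dilation); "outside" errors are additions only, in the
slice just beyond the base or apex, because a false negative is impossible
where the structure does not exist. Balanced flips keep the net volume
perturbation near zero, which is what makes automatic ED/ES phase selection
recover the generator's phases (a net-deleting model would systematically
push the argmax off the true ED, because the cyclic curve is nearly maximal
at the last phase too). Infeasible category demands (e.g. no interior
slice) reallocate to the nearest feasible category with a warning, and the
symmetric difference to the reference equals the budget exactly whenever
candidate pools suffice — a conservation law the tests check.

What passing these tests does *not* show: performance on real CMR. The
phantoms have no intensity ambiguity, no observer variability, no
through-plane motion of the valve plane, and their errors are injected
rather than produced by a segmentation model, so recovered agreement
statistics characterize the *pipeline*, not any segmentation method.

## Measurements

Volumes are voxel counts × voxel volume (ml); ED/ES are selected per
ventricle independently as argmax/argmin of the volume curve (earliest
index on ties; a volume-wide shared phase pair is available). SV = EDV −
ESV, EF = 100·SV/EDV, EDVI = EDV/BSA; these identities hold exactly by
construction and are asserted on every measurement set. BSA uses Mosteller
(√(h·w/3600)) by default with DuBois available. Intensity normalization for
the network maps each scan's 1st–99th percentile range to [0, 1] with
clamping; a constant image maps to zeros with a warning.

The simulated expert correction replaces, per phase, the most basal slice —
defined on the union of both structures in both segmentations, so reference
and automatic share one basal index — with the reference slice. This can
only remove disagreements in that slice, hence Dice against the reference
is non-decreasing on every fixture; the strict mean improvement and the
shrinking of measurement bias are empirical properties of the degradation
model that the tests verify, not theorems.

## TFC engine

The CMR criterion is a pure threshold rule (see README for the cutoffs),
conditional on the RWMA flag, with major taking precedence and volumes
compared at full floating precision. The female major RVEDVI cutoff is
implemented as ≥ 100 ml/m² with a configuration switch for the strict
> 100 reading, since published wordings differ and the two only disagree
exactly at 100. The diagnosis rule is the plain point sum (≥ 4 of the six
categories, minor = 1, major = 2); the full 2010 category-combination rules
(e.g. "two major from different categories") are out of scope, and non-CMR
categories are consumed as a given point total.

## Toy segmentation network

A small dilated-residual 2D conv net (3×3 conv → ReLU → 3×3 dilated-2 conv
→ ReLU → identity residual → inverted dropout → 1×1 head → softmax over
background/LV/RV), written in numpy with hand-derived backpropagation
(im2col convolutions, Adam, weight decay 5·10⁻⁴, learning rate 10⁻³ with
staged ×0.1 decay). Normalized coordinate channels are appended to the
input so the tiny receptive field can separate left from right.
The loss is the unweighted sum of mean cross-entropy and 1 − mean
foreground soft-Dice; both the conventional soft-Dice (factor 2, maximum 1)
and a variant without the factor 2 (maximum ½) are provided, the
conventional form being the default loss term. Inference is Monte-Carlo
dropout: the mean softmax over n stochastic passes (default 15), argmaxed
to labels, then filtered to the largest 3D connected component per class
(26-connectivity by default; ties break to the first-labelled component).
Training at clinical scale (160×160 patches, 160 000 iterations) is not the
point; the defaults are a CPU-scale recipe (64×64, a few hundred
iterations) whose only promise — asserted by test — is that a short run
improves phantom Dice over the random initialization and that the MC mean's
variance shrinks like 1/n.

## Agreement statistics

Dice on binarized masks (both empty ⇒ 1, agreement on absence; one empty ⇒
0); Hausdorff as the exact symmetric maximum of boundary-voxel distances in
physical mm with anisotropic spacing (KD-tree nearest neighbours; the tests
cross-check an all-pairs brute force). Error attribution pools the
symmetric difference over ED and ES and categorizes each voxel against the
reference structure's slice extent at its phase. Phase differences are
wrapped circularly to (−n/2, n/2] and expressed as % of the cycle.
Bland–Altman uses bias ± 1.96·sample SD; Pearson CIs use the Fisher z
transform; Cohen's κ is unweighted with the large-sample standard error
√(p₀(1−p₀)/(n(1−p_e)²)), reported as estimate ± SE; McNemar is the exact
binomial test when the discordant count is below 25 and the
continuity-corrected chi-square otherwise (via statsmodels). Sensitivity
and specificity are computed separately for the "≥ minor" and "major"
readings of the CMR criterion against the definite-diagnosis label derived
from the manual measurements.

## Numerical and degenerate-input decisions

* Phase-selection ties break to the earliest index; a fully empty structure
  raises rather than returning a phantom phase.
* Log probabilities are clamped at 10⁻⁷; softmax is computed with max
  subtraction.
* κ with a single shared category is reported as 1 (perfect agreement) with
  a warning; zero discordant pairs give McNemar p = 1; undefined
  sensitivity/specificity are NaN, never silently 0.
* All randomness flows through `numpy.random.Generator` seeded from the
  configuration; per-subject streams are spawned from a `SeedSequence` so a
  subject's data does not depend on how many draws earlier subjects used.
  Identical configuration ⇒ bit-identical cohorts, reports and files.

## Problem sizes

The default experiment sizes used throughout the documentation and the
reproduction script — cohorts of 40–200 subjects on 160×160×12 grids with
25 phases, and network runs on 64×64 phantoms — were chosen as the smallest
sizes at which the stochastic recovery checks have comfortable statistical
power; all complete in minutes on a single CPU. The test suite uses smaller
96×96 grids with 12–16 phases for speed.

## Known limitations

* Phantom anatomy is schematic; absolute Dice/Hausdorff magnitudes on the
  phantoms are not comparable to clinical values.
* The degradation model perturbs label volumes directly; it reproduces the
  *location* statistics of automatic-segmentation errors, not their shapes
  or intensity-driven causes.
* At the default 5 % error level the TFC category rarely changes, so κ on
  synthetic cohorts is typically 1; raising `error_fraction` or using an
  imbalanced `deletion_fraction` produces threshold crossings for studying
  classification disagreement.
* The network module is a functional miniature: it demonstrates the losses,
  MC-dropout averaging and post-processing, not competitive segmentation.
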