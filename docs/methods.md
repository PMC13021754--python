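# Methods

`amystage` implements a spatiotemporal subtyping-and-staging analysis for
amyloid PET: tracer harmonization to the Centiloid scale, data-driven ROI
discovery by spatial ICA, control-anchored z-scoring, a z-score
event-based subtype-and-stage mixture model fitted by greedy search and
EM with MCMC uncertainty, cross-validated selection of the number of
subtypes, and longitudinal stability evaluation. This note records the
model, its assumptions, the defaults, and the design choices made where
the design was genuinely open.

## Harmonization and z-scoring

Tracer-specific SUVR (whole-cerebellum reference) is converted to
Centiloid by the published linear equations

    FBP: CL = 188.22 * SUVR - 189.16
    FBB: CL = 157.15 * SUVR - 151.87

and amyloid positivity is called on the cortical summary SUVR at 1.11
(FBP) and 1.08 (FBB). The boundary is treated as positive
(`>= threshold`); this convention is configurable because the published
cut-points are quoted without a boundary rule.

Controls are cognitively normal, APOE-e4-negative, amyloid-negative
subjects. Each region is regressed on age and sex by ordinary least
squares on controls only; the whole cohort is then expressed as

    z = (measured - predicted(age, sex)) / SD(control residuals).

Scaling by the control residual SD is a declared convention: the model
phrases events as "standard deviations away from the control mean", which
presupposes control-SD units, but the scaling is not spelled out in
descriptions of this pipeline family. Records with missing covariates
are excluded, not imputed. Regions whose control residual SD is
numerically zero are rejected as degenerate rather than silently scaled.

## ROI discovery by spatial ICA

The analysis mask keeps voxels where any tissue probability (GM, WM or
CSF) exceeds 20% for a participant, intersected across participants by a
strict majority (> 50%) rule. Within the mask, the subjects-by-voxels
Centiloid matrix is decomposed by FastICA in its spatial orientation:
voxels are the samples, so components are spatial maps and subjects index
the mixing matrix. Data are centred and whitened to exactly the requested
number of principal components (20 by default, mirroring common practice;
configurable). Each map's sign is fixed so its skewness is positive,
because amyloid loading is nonnegative; the threshold is then one-sided.
Maps are standardized to mean 0 / SD 1 across mask voxels and thresholded
at z > 1.96, and the supra-threshold set is intersected with a gray-matter
mask (GM probability > 0.5 by default).

Component selection, done visually in practice, is made algorithmic here:
a component is gray-matter-dominant if the mean GM probability over its
supra-threshold voxels exceeds both the mean WM and mean CSF
probabilities. This is a deliberate, documented surrogate for visual
inspection; the rule's inputs (tissue maps) and threshold are
configurable. ROI values are plain arithmetic means of Centiloid over
each ROI. FastICA non-convergence triggers seeded retries and then a hard
error; a `require_convergence=False` escape hatch exists for null
simulations on unstructured data, where the fixed-point iteration has no
stable target.

## The progression model

Events are threshold crossings: with K biomarkers and z-thresholds
{1, 2, 3}, there are N = 3K events and stages 0..N. A subtype is a
permutation of the events. The expected z of biomarker i at stage k under
ordering S is piecewise linear through (0, 0), the (position, threshold)
points of i's events in S, and (N, z_max) with z_max = 5. If an event
occupies the final position, the plateau value z_max takes precedence at
stage N (the two conventions collide only there). Orderings are not
constrained to cross a biomarker's thresholds in increasing order during
search — matching reference practice — but violations are reported as
diagnostics, and the generative simulator only uses valid
(threshold-monotone) orderings.

The subject likelihood is Gaussian around the trajectory with a fixed SD
of 1 on the z-scale (configurable per biomarker), a uniform prior over
stages 0..N, and mixture fractions over subtypes:

    L(z) = sum_c f_c * (1/(N+1)) * sum_k prod_i N(z_i | g_i(k; S_c), sd_i)

Stage and subtype posteriors follow by normalization. Ties in argmax
operations resolve to the lowest index.

### Fitting

Single-subtype maximum likelihood uses iterated single-event relocation:
each event is tried at every position and the best strict improvement is
kept, sweeping until no event moves; 25 random restarts by default.
Multi-subtype models are grown hierarchically: the (C-1)-subtype
solution's worst-fitting cluster (largest summed squared residual at the
members' ML cells) is split, and the C orderings are refined by
alternating (a) an EM fraction update from the subtype responsibilities
and (b) per-subtype greedy re-optimization of the ordering against the
*total mixture* log-likelihood with the other subtypes held fixed. Both
steps are monotone, and the total log-likelihood is asserted
non-decreasing at every iteration.

The two-cluster split initialization is the one genuinely open design
point. Random bisections refined by soft EM cannot break the symmetry of
two near-identical compromise orderings, so the split runs a hard
classification-EM (fit an ordering per cluster, reassign each subject to
the ordering that explains it better, iterate), seeded once by k-means on
direction-normalized z-vectors of the above-median-burden subjects —
progression *patterns*, discounting stage — plus random-bisection tries;
the best two-cluster likelihood wins. Because this initializer draws
per-subject randomness, refits on resized copies of the same empirical
distribution can land in different local optima; only the single-subtype
search is an exact function of the empirical distribution.

### MCMC

Ordering uncertainty is quantified by Metropolis–Hastings: proposals swap
two random event positions within one random subtype, or (with
probability 0.2 when C > 1) perturb the fractions with symmetric Gaussian
noise and renormalize. The renormalized fraction proposal is treated as
symmetric in the acceptance ratio — an approximation shared with
reference implementations of this model family. Default 100,000
iterations with 10% burn-in and no thinning; burn-in and proposal scales
are declared defaults, not published values. Positional variance diagrams
(PVDs) tally, per subtype, how often each event occupies each position
across post-burn-in samples; each event's row sums to 1 by construction.
Pattern similarity between PVDs is the Pearson correlation of the
flattened frequency matrices.

### Model selection

CVIC(C) = -2 times the total out-of-fold log-likelihood over a seeded
ten-fold split, minimized over C. The out-of-fold likelihood is averaged
over MCMC posterior samples of the fold model by default (so every C
enjoys the same hedging over ordering uncertainty); with ``mcmc_iter=0``
the maximum-likelihood fold fit is used instead. A parsimony margin
(default 6, about one AIC-style parameter) surfaces the smallest C within
the margin of the minimum; choosing it over the argmin is a user
decision, mirroring the practice of preferring a smaller model when the
gain is marginal.

A property of this criterion worth knowing: a C=2 mixture can match or
beat even the *true* single-subtype model predictively, because averaging
over two plausible orderings hedges the estimation uncertainty of a
single fitted ordering (with N = 30 events, a few hundred subjects leave
real ordering uncertainty). In our experiments at n = 400 the C=1-vs-C=2
out-of-fold comparison on homogeneous data is a near-exact tie -- argmin
selection hovers around chance regardless of noise level, restart count,
or whether the out-of-fold likelihood is posterior-averaged -- while a
genuine second subtype is detected essentially always. This is consistent
with published CVIC curves that decrease monotonically in C until a
manual parsimony override, and it is why the parsimony rule exists:
prefer the smallest C unless CVIC improves decisively.

## Synthetic data

The generator is the model run forwards and defines the study conditions:

- ages Normal(72, 8), sex Bernoulli(0.5), tracers assigned FBP/FBB with
  equal probability;
- stages uniform on {0..N} (stage prevalence is not modelled; the uniform
  choice is an assumption, configurable);
- progressor values: baseline(age, sex) + control_scale * (g(stage) + e),
  e ~ N(0, noise_sd), in Centiloid, mapped to SUVR by the exact inverse
  tracer equations; controls sit at stage 0;
- noise_sd defaults to 1 (one control SD — the scale on which z-scores
  are defined, making downstream z-scoring self-consistent);
  control_scale defaults to 8 CL per control SD; the age slope (0.3
  CL/year) and sex offset (2 CL) are small, cosmetic covariate effects;
- subjects at stage 0 carry no observable subtype; a latent subtype is
  retained so follow-up progression out of stage 0 is well defined;
- follow-up stages add a Poisson increment (capped at N), the simplest
  nonnegative integer law; intervals default to 2 years;
- generative orderings always cross each biomarker's thresholds in
  increasing order (the only orderings that are monotone progressions);
  multi-subtype experiments use mutually distinct patterns — either a
  pattern and its region-reversal, or independent random valid orderings,
  mirroring subtypes with different onset regions;
- voxel volumes are sums of isotropic Gaussian blob components whose
  per-subject weights solve a small linear system so that, at zero noise,
  the mean over each blob's half-maximum mask equals the subject's
  regional Centiloid value; blob territory is solid gray matter in the
  tissue fields.

What the generator does not emulate: scanner point-spread, partial-volume
effects, spatial autocorrelation of noise, registration error, realistic
stage prevalence, tau or MRI modalities, or dropout. Passing tests
therefore demonstrate internal consistency and statistical recovery under
the model's own assumptions, not robustness to real-data artifacts.

## Numerical choices

The likelihood over the subject-by-stage grid is evaluated through a
quadratic expansion so the whole grid is one BLAS matrix product plus an
in-place log-sum-exp; batched trajectory evaluation replaces per-ordering
interpolation in the search inner loop. Both were verified against
straightforward reference implementations to < 1e-12. Greedy moves are
accepted only on strict improvement (> 1e-12), guaranteeing termination;
EM stops when the gain drops below 1e-4 (looser, with capped iterations,
inside cross-validation). Degenerate cases — empty subtypes during EM
(re-seeded once from the worst-fit subjects, then a hard error), constant
IC maps, empty ROIs, zero control residual SD, rank-deficient control
designs — fail loudly rather than silently.

## Problem sizes used in the checks

Recovery experiments use n = 300–600 subjects and K = 10 regions (N = 30
events), with 10-seed replication for ordering recovery and model
selection; ICA checks use four blob sources on a 24^3 grid with n = 200
scans. These sizes give stable pass/fail behaviour for the properties
being tested while keeping the whole suite lightweight; effects of
scaling further up are smooth in our experience (larger n sharpens
recovery).

## Known limitations

- The greedy/EM fit finds local optima; the pattern-k-means split
  initialization removes the dominant failure mode but multi-subtype fits
  at high noise can still mix patterns.
- MAP stage assignment on the integer grid discards within-stage
  information; an expectation stage is available as an option.
- The CVIC hedging bias described above is a property of predictive
  model selection for this mixture, not an implementation artifact.
- The fraction proposal's symmetry approximation slightly biases the
  sampled fraction posterior; ordering posteriors are unaffected.
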