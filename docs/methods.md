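# Methods

## Signal conditioning

Each region's series is band-pass filtered to 0.01–0.07 Hz with a
second-order zero-phase Butterworth (forward–backward `sosfiltfilt`),
isolating the slow-4/slow-5 fluctuation bands while removing scanner drift
and aliased physiological noise. Samples beyond 3 SD of the filtered
series are **winsorized** (clipped to the ±3 SD bound) rather than
deleted: deletion would desynchronize regions' time axes and break the
instantaneous co-activation matrix. The clipping statistics are computed
once on the filtered series, with no re-estimation loop; linear
interpolation over flagged samples is available via
`PreprocessParams(outlier_mode="interpolate")`. z-scoring uses the
population SD (divisor *n*); the choice only rescales and is fixed for
reproducibility. Filter family and order are configuration, since only the
band is scientifically pinned.

Driving events are upward threshold crossings, σ(t) = 1 iff z(t) > θ and
z(t−1) ≤ θ with θ = 0; the first timepoint can never be an event, and no
two consecutive timepoints can both be events, so raster density is below
one half.

## Ignition and metastability

Under the instantaneous co-event adjacency, active nodes form a clique, so
the largest connected component equals max(1, number of active nodes);
both the generic graph computation (networkx) and this closed form are
implemented and their equality is part of the test surface. Conventions:

- Window inclusive at both ends, [t, t + T_win], i.e. T_win + 1 steps.
- Φ of an empty graph is 1 — isolated nodes are components of size 1, so
  a solitary driving event scores 1 (the igniting node participates).
- Events whose window would overrun the series end are **discarded** so
  every retained event is scored over an identical duration; truncation is
  available behind `IgnitionParams(truncate_overrunning=True)`.
- Metastability is the sample SD (divisor n − 1); nodes with fewer than 2
  retained events have undefined metastability, nodes with none have
  undefined ignition, and undefined values are excluded from subject-level
  (unweighted) means with a logged warning.
- Integration is reported as a raw component size by default; a
  normalized (÷N) variant is a flag. Group comparisons are invariant to
  this scale.
- `window_length(tr_ms) = round(16800 / tr_ms)` (half-up), giving 7 TRs at
  2400 ms and 8 at 2100 ms and preserving the 16.8 s duration within half
  a TR for any repetition time.

## Tumor overlap and deltas

Probabilistic masks are thresholded at 0.1 **inclusive**; per region the
involvement fraction is (voxels ≥ 0.1 with that label) / (voxels with that
label), and a region is tumor-involved iff at least one voxel meets the
threshold. Fractions are binned exactly as [0.0], (0.0, 0.33),
[0.33, 0.66), [0.66, 1.0] — 0.33 falls in the third bin, 0.66 and 1.0 in
the fourth. Deltas are oriented as subject − control-group regional mean,
so negative values mark reductions versus controls; the opposite
orientation is a flag. Regions with fewer than two controls holding a
defined value are dropped with a warning; control rows (fraction 0) enter
the delta table only for diagnostics, never the mixed model.

## Group inference

Subject-level comparisons use two-sided Mann–Whitney U tests (exact when
both groups have ≤ 10 subjects and no ties, mid-rank normal approximation
with continuity correction otherwise), Benjamini–Hochberg adjusted within
each metric across the three pairwise comparisons; the family definition
is configuration. Stars: ns for p ≥ 0.05 (the boundary p = 0.05 prints *),
then \*, \*\*, \*\*\* at 0.05, 0.01, 0.001.

The sensitivity analysis solves power(d) = 0.8 by bisection
(|Δpower| < 1e−6) on the noncentral-t power function of a two-sided
α = 0.05 comparison with effective group sizes ARE × n_i and
df = ARE·(n₁+n₂) − 2. The parent-distribution convention defaults to
Laplace (ARE = 1.5), the unique choice among the three standard parents
(normal 3/π, Laplace 1.5, min-ARE 0.864) that reproduces both study
values, d = 0.97 (14 vs 10) and d = 1.06 (10 vs 10), simultaneously; all
three parents are selectable, and an explicit `are_factor_override=1.0`
recovers the plain t-test sensitivity.

### Mixed model

`ΔIM ~ TumorPercentage + (TumorPercentage | SubID) + (1 | RegionID)` is a
crossed-random-effects model with a correlated subject intercept/slope
pair, which neither the model class nor the Satterthwaite tests of the
usual Python mixed-model routine can express; the REML fit is therefore
implemented in-package. The engine profiles the residual variance out of
the REML criterion, parametrises the relative covariance factor by its
Cholesky elements (diagonals bounded at zero), and evaluates the criterion
through the Woodbury identity on the random-effects dimension
(q = 2·subjects + regions), so a full-size fit (14 × 268 rows) takes well
under a second. Optimization is L-BFGS-B with a Nelder–Mead polish on
non-success. Satterthwaite df for each fixed effect use
df = 2·Var(β̂ₖ)² / (gᵀ A g), with g the central-difference gradient of the
contrast variance in (θ, σ) and A twice the inverse finite-difference
Hessian of the REML deviance. A fit whose Cholesky diagonals fall below
1e−3 (relative) or whose slope–intercept correlation exceeds 0.995 is
declared singular and refitted along the fixed ladder full → drop
correlation → drop random slope; each simplification is recorded on the
returned fit. A response that is identically zero returns the degenerate
fit directly (all estimates and random SDs zero). An independent check
against the reference R implementation (lme4/lmerTest) on a simulated
table agrees to ~1e−6 in estimates and ~1e−3 relative in SE/df; the
acceptance surface is parameter recovery — nominal 95% CI coverage over
200 tables simulated from the model's own equations (10 subjects × 40
regions, slope −0.03, subject intercept/slope SDs 0.025/0.01 with
correlation −0.4, region SD 0.007, residual 0.01).

Diagnostics return the numeric arrays behind the three standard panels:
conditional (BLUP) residuals vs fitted values, QQ quantile pairs of
standardized residuals, and observed vs posterior-simulated KDE density
curves (≥ 200 draws from the fitted parameters); densities integrate to 1.

## Networks and cognition

Network signals are unweighted means of member-region signals; ignition
metrics run directly on the 7-node matrix (averaging region-level metrics
by network is available behind a flag). Correlation graphs across subjects
keep edges with Pearson r ≥ 0.4, never retain negatives, and report
unadjusted p-values; in the cross-metric (ignition–metastability) mode the
undirected edge weight between distinct networks is the mean of the two
directed correlations and self-edges are included. Cognition analyses use
Kruskal–Wallis (tie-corrected; all-equal data degenerate to H = 0, p = 1)
for group differences in latency, per-group Pearson correlations, and an
OLS interaction model with treatment coding, control as the reference
level, evaluated by Type III ANOVA under that coding (sum-to-zero coding
is not used; the interaction coefficients are interpreted as slope
deviations from controls, which requires the reference-cell coding).

## Synthetic cohort generator

The generator is an **event-propagation** model, not an oscillator model:
it directly manipulates the quantity the ignition metric measures, so
group manipulations are recoverable by construction. Per subject, each
region emits seed events as a Bernoulli process; a seed event recruits
every other region at the same timepoint with probability
`coupling_within` (same network) or `coupling_between` (different
network), scaled by the target region's propagation multiplier; spike
trains are smoothed with a Gaussian kernel (SD `hrf_width` timepoints) and
iid Gaussian noise is added. One global seed expands into per-subject
substreams, so adding a subject never perturbs the others' draws.

Default conditions: 10 controls, 14 meningioma-like, 10 glioma-like
subjects; 268 regions in 7 contiguous-block networks; mixed TRs (40%, 5/14
and 20% of each group at 2100 ms, the rest at 2400 ms); 180 timepoints;
`event_rate` 0.2 seed events per region per 100 TRs; `coupling_within`
0.5, `coupling_between` 0.18; `noise_sd` 0.08; `hrf_width` 2. Two pieces
of generator physics fix these scales. First, after band-passing, *any*
region's z-scored noise crosses zero upward about once per 9 TRs, so
roughly N/9 regions co-activate at every timepoint regardless of coupling;
coupling differences are measurable only through global cascades that are
simultaneously **rare** (here ~1 per 2 TRs brain-wide, hence the small
per-region seed rate at N = 268) and **large** (recruiting ~half of the
seed's network). Second, z-scoring erases amplitude, so attenuation must
act by *thinning participation* in discrete cascades, not by scaling a
continuous signal.

Pathology: glioma-like subjects carry the diffuse multiplier
`glioma_global_attenuation` (0.6) on every region, plus two severely
infiltrated networks per subject (multiplier further × 0.15; which
networks varies by subject), reflecting patient-to-patient variability in
tumor location; meningioma-like subjects have a contiguous focal block of
regions (fractions spanning all three nonzero bins) attenuated by
`meningioma_focal_attenuation` (0.5). Attenuated regions also receive
proportionally larger iid noise (SD ∝ 1/multiplier), modelling the
degraded signal-to-noise ratio of infiltrated or compressed tissue. Tumor
fractions are drawn once per subject and shared between the signal and
mask generators, so masks and dynamics are consistent; voxel masks on the
20×20×20 toy lattice reproduce the emitted fractions to within one voxel
of rounding, with a few deliberately sub-threshold voxels to exercise the
0.1 cutoff.

Cognition: latency = intercept + slope_group × x + noise with x the
subject's ignition standardized across the cohort (slopes in ms per
cohort-SD; −30 for controls, 0 for patients, noise SD 15 ms), centered
within group so group mean latencies are equal by construction — patients
show decoupling, not deficit. `standardize=False` yields the raw affine
map used in exact-algebra tests.

**What the generator does not emulate:** hemodynamic-model realism
(balloon dynamics), scanner noise spectra, motion artifacts, anatomically
realistic parcel geometry, and — importantly — structured, assembly-specific
co-activation. In this model global integration is one trajectory shared
by all nodes of a subject, so a node's metastability is a functional of
that shared trajectory no matter the node's own health; across-subject
correlations of network metastability are therefore strong in *every*
group, and the qualitative "attenuated cohorts lose strong metastability
edges" pattern appears only directionally (pooled edge counts are lower;
individual replicates at n = 10 subjects are noisy). Passing tests
demonstrate recovery of the manipulations the generator encodes, not
fidelity to every empirical property of real cohorts.

## Problem sizes in the validation suites

The heavier behavioural checks run at deliberately chosen sizes: group
detection and cohort-structure Monte-Carlos use the full default cohort
(34 subjects × 268 regions × 180 timepoints) over 25–50 replicates; mixed
model coverage uses 200 tables of 10 subjects × 40 regions; the
ignition/brute-force oracle battery enumerates all rasters at (N ≤ 2,
T ≤ 5) and (3, 4) exhaustively plus 1000 random rasters up to N = 6,
T = 15; null calibration uses 1000 permutation replicates. These sizes
give stable Monte-Carlo estimates while keeping the default test run
fast.

## Known limitations

- Real-data NIfTI inputs are supported through the same readers (labelled
  atlas mean extraction) but no motion correction, slice timing or
  registration is performed — inputs are assumed preprocessed.
- The LMM engine covers exactly the model family the analysis needs (one
  covariate, subject intercept+slope, crossed region intercept); it is
  not a general mixed-model package.
- Exact Mann–Whitney p-values are used only for small tie-free groups;
  elsewhere the continuity-corrected normal approximation applies.
- Pearson-based graph edges are sensitive to outliers at n ≈ 10 subjects;
  edge counts near the r = 0.4 threshold should be read qualitatively.
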