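# Methods

`tvanet` implements two linked analyses on synthetic data with known ground
truth: (i) estimation of individual visual-attention parameters from
whole-/partial-report letter tasks under the Theory of Visual Attention
(TVA), and (ii) a resting-state functional-connectivity (FC) group analysis
— dual regression against group network maps, intra-network voxelwise GLM
with permutation cluster-extent FWE, and inter-network Fisher-z group tests.

## The behavioural model

TVA models brief-display letter report as a fixed-capacity exponential
race.  Item *i* in a display is encoded into visual short-term memory
(VSTM) after an exponential waiting time with rate

    v_i = C · w_i / Σ_j w_j        [items/s]

so the rates always sum to the total processing capacity *C*.  Items that
finish within the effective exposure τ are encoded; only the first *K*
finishers are retained.  The effective exposure is τ = (t − t0)/1000 for
masked displays and τ = (t − t0 + mμ)/1000 for unmasked displays, where t0
is the minimum effective exposure (ms) and mμ the iconic-memory
prolongation (ms); negative values clamp to zero.

Six quantities describe a subject: C (processing speed), K (VSTM storage
capacity, the asymptote of the whole-report curve), t0, mμ, the top-down
control ratio α = Σw_distractor / Σw_target (lower = more selective), and
the spatial laterality w_lat = w_left / (w_left + w_right) (0.5 =
balanced).

### Exact race probabilities

For whole report the retained count does not depend on race order, so the
score distribution is a Poisson-binomial of the per-item finish
probabilities 1 − e^(−v_i τ), capped at capacity and marginalised over the
capacity mixture.  For partial report the identity of the retained items
matters: the probability that a finisher subset completes in a given order
within τ has a closed form via the sequential-minimum decomposition
(product of selection ratios times a hypoexponential CDF whose stage rates
are the strictly decreasing partial sums of the remaining rates).
Enumeration over subsets and orders is exact up to 8 items; a vectorised
Monte-Carlo race sampler serves as the independent oracle in tests.

A real-valued capacity K (e.g. 3.03) is realised as the two-point mixture
on {⌊K⌋, ⌈K⌉} with matching mean — the simplest mixture consistent with
non-integer asymptotes.

### Design and calibration

Whole report: 6-letter single-hemifield columns, 2 masking × 3 exposure ×
2 hemifield conditions, 192 trials in 4 blocks of 48, balanced within
block.  Partial report: letters at the corners of an imaginary square,
always masked; 4 single-target, 8 target-plus-distractor (horizontal or
vertical neighbour) and 4 dual-target conditions, 288 trials in 6 blocks of
48.  Exposures are calibrated per subject exactly as in the pretest
procedure: the whole-report middle duration solves E[masked score] = 1
letter (bisection to 0.1 ms), with short/long at 0.5×/2× (matching the
ratio of the reference cohort's mean pretest durations); the partial-report
duration solves single-target accuracy = 80%.

The letter count per whole-report display (6) and the short/long factors
are design choices the task description leaves open; both are configurable.

### Estimation

Fitting is maximum likelihood, statsmodels-style: `WholeReportModel`
(parameters C, K, t0, mμ from score counts) and `PartialReportModel`
(its own sensory rate C and t0 — the task is fully masked, so mμ drops —
plus α and w_lat from per-target report indicators; capacity fixed at the
whole-report estimate, since the weighting parameters derive from partial
report only).  `TVAModel.fit()` chains the two and assembles the full
parameter set.  Partial report is parameterised directly in (α, w_lat);
by weight scale-invariance this is likelihood-equivalent to estimating
four weights with one pinned.

Optimisation: bounded L-BFGS-B from 10 deterministic Latin-hypercube
multi-starts over C∈[1,100], K∈[0.5,6], t0∈[0,60] ms, mμ∈[0,500] ms,
α∈[1e-3,4], w_lat∈[0.01,0.99], run in box-normalised coordinates so the
finite-difference gradient is equally scaled across parameters; the seed is
derived per subject id (CRC32).  Standard errors come from the inverse
numerical Hessian at the optimum and are reported as NaN when a parameter
sits on a bound.  Zero-probability outcomes are floored at 1e-12 with a
counter.

Estimation noise is dominated by the C–t0 ridge (raising both changes
short-exposure predictions little).  At the design trial counts the median
absolute relative error of C is ≈ 10–15% — an information limit of the
design, not an optimiser artefact (the fitted likelihood always exceeds the
generating parameters' likelihood).  A small upward finite-sample bias in C
(~5%) and in α is expected of ML in this regime.

## Synthetic data

### Population

Subjects are drawn independently per parameter from truncated normals with
the reference cohort's means and SDs (C 25.89±7.34, K 3.03±0.47,
α 0.52±0.21, w_lat 0.49±0.06; n = 31).  The cohort does not report
generating values for t0 and mμ; the population uses 10±5 ms and
150±50 ms, typical of young-adult whole-report fits.  Independence mirrors
the empirical finding that the attention parameters are uncorrelated
traits.  Education is uniform on 9–13 years, gender balanced binary; both
default to pure nuisance (no FC effect).

### Resting-state scenes

A scene is a grid (default 24×24×12 voxels, 3 mm, 250 volumes, TR
2.608 s — volume count and TR as acquired in the reference study, the grid
scaled down so 31 subjects run in seconds) with G = 6 planted network
templates: Gaussian blobs at farthest-point-spread centres, smoothed,
unit peak, pairwise spatial |r| < 0.3.  Per subject, network time courses
are drawn from a G×G covariance (unit diagonal, base inter-network
correlation 0.1) and each voxel's series is

    baseline + Σ_g template_g(v)·gain_{s,g}·tc_{s,g}(t) + drift
    + motion-locked global artifact + N(0, σ²)

with gain ~ N(1, 0.2), σ = 1, baseline 100 (tSNR ≈ 70–100, typical of
3T EPI), a linear drift and six random-walk motion traces whose
volume-to-volume magnitude drives a global artifact.  Group effects are
planted as (i) intra-network: a Cohen's-d shift (default 1.2) of the gain
between median-split groups of a chosen parameter, and (ii) inter-network:
an additive shift of one off-diagonal correlation (default 0.15), with the
post-shift covariance checked for positive definiteness.  Defaults mirror
the reference findings: high processing speed → lower coupling in a
"ventral-attention-like" network and higher ventral↔right-frontoparietal
correlation; efficient top-down control → higher "dorsal-attention-like",
lower "visual-like" coupling and higher visual↔executive correlation.
The paper-scale analysis reports t-values, not effect sizes, so the planted
d and Δr are free generator parameters chosen once.

What the generator does *not* emulate: hemodynamic autocorrelation,
physiological noise spectra, susceptibility artifacts, registration error,
non-Gaussian BOLD amplitude distributions.  Passing tests therefore
validate the estimators' algebra and calibration under the stated noise
model, not their behaviour on real scanner data.

## FC pipeline

Processing order (as in the original pipeline): per-voxel OLS nuisance
regression (six motion parameters + global signal + intercept; residuals
exactly orthogonal to the confounds), then volume-wise Gaussian smoothing
(FWHM 4 mm, σ = FWHM/(2√(2 ln 2)); reflective boundary, sum-conserving).
Head-motion QC excludes subjects with cumulative translation/rotation
> 3 mm/3° or mean volume-to-volume translation/rotation > 0.15 mm/0.1°;
tSNR (voxelwise mean/SD over time) supports the 5th-percentile
extreme-value flagging.

Group decomposition replaces probabilistic ICA with a PCA + fixed-point
ICA contract: voxels are variance-normalised by their *residual* noise SD
(total variance minus a first-pass rank-G projection — normalising by total
SD would flatten signal voxels to the background level), subjects are
temporally concatenated, reduced to G components by randomised SVD, and
rotated to spatially independent maps by FastICA (negentropy fixed point,
seeded, positive-skewness sign convention).  Final maps are expressed in
data units by regressing the unnormalised series on the component time
courses.  Group maps may also be injected from ground truth, which makes
downstream stages deterministic.  Components are assigned to templates by
greedy spatial cross-correlation.

Dual regression per subject: stage 1 regresses every volume on all G maps
jointly (network time courses); stage 2 regresses every voxel's series on
all G variance-normalised time courses jointly and standardises the
coefficients by the residual noise SD (t-statistics), giving G Z-maps.
Inter-network FC is the 6×6 matrix of Fisher-transformed correlations of
the stage-1 time courses (diagonal NaN; |r| capped at 1−1e-15 and flagged
by the cap value itself).

## Group statistics

Median splits label the top ⌈n/2⌉ performers "high" (higher-better for C
and K, lower-better for α; w_lat splits into left/right preference), ties
broken by subject id; at n = 31 this reproduces the 16/15 groups.  The
voxelwise GLM uses a cell-means design — high and low group columns plus
five zero-mean covariates (the three remaining parameters, education,
gender) — so the residual df are n − 7 = 24, matching the reference
design; the contrast is high − low.

Cluster-extent FWE is by permutation rather than random-field theory:
clusters are 26-connected components above the one-sided t_{0.001,df}
height threshold; group labels are permuted (covariates fixed; permutations
that make the design singular — e.g. labels aligning exactly with the
binary gender column — are redrawn), the GLM is refitted, and the maximal
cluster size forms the null; corrected p = (1 + #{max ≥ observed})/(1 +
n_perm).  Bonferroni across the six networks (0.05/6 = 0.0083) is applied
on top.  Inter-network group tests are one-tailed pooled two-sample
t-tests (df = n − 2 = 29) with Bonferroni 0.05/5 = 0.01 across the five
tested pairs.  Intra-network summaries offer the mask mean and the
first-principal-component eigenvariate (sign-aligned with the mean);
partial correlation is Pearson on OLS residuals with p from
t = r√(df/(1−r²)), df = n − 2 − k.

## Validation experiments and problem sizes

`tvanet.experiments` packages the study-scale checks used by the test
suite and `scripts/acceptance.py`:

* exact enumeration vs a 10^6-sample Monte-Carlo race on all 28 design
  conditions (agreement reported as the max deviation in MC SEs);
* parameter recovery over 50 subjects generated at the cohort means with
  the full 192 + 288-trial design;
* dual-regression recovery of planted maps/time courses on a noisy
  default-size scene (31 subjects);
* cluster-FWE type-I calibration over 200 null replicates;
* end-to-end recovery of a planted d = 1.2 intra-network effect's
  direction over 100 replicates.

The two replicate experiments run on a reduced grid (16×16×8, 150
volumes, 4 networks) — chosen as this package's replicate-study size —
while keeping n = 31 subjects and d = 1.2; the sign-recovery replicates
split groups on the generating parameter values (parameter recovery is
validated separately, and the fitted-split path runs in `run_study`).

## Known limitations

* Letter-identity confusions, guessing and response times are not
  modelled; whole report observes only the correct count.
* The partial-report C/t0 pair is weakly identified at a single calibrated
  exposure (a deliberate property of the design); α and w_lat, the
  parameters of interest, are identified through condition contrasts.
* Permutation inference assumes exchangeability under the null; covariates
  are held fixed rather than Freedman–Lane-orthogonalised.
* Whether the original partial-report fit shared C/t0 with whole report is
  not documented; this package estimates them separately.
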