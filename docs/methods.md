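# Methods

This note documents the models, algorithms, simulation design and
numerical choices behind `modgain`, in the spirit of the methods
documentation of packages like statsmodels or msprime.

## Graph construction

A subject enters as a volumes × ROIs matrix of averaged regional
time series (the reference acquisition is 180 volumes at TR = 2 s over
252 retained regions of a 264-region cortical parcellation, but nothing
depends on those numbers). Pairwise Pearson correlations are Fisher
z-transformed (`z = atanh r`), the variance-stabilizing scale on which
all thresholding and averaging happens. The diagonal is stored as zero
and excluded everywhere.

**Proportional thresholding.** At cost `c`, the `floor(c · M)` largest
off-diagonal z-values are kept as unweighted edges, `M = n(n−1)/2`.
Choices worth noting:

* *floor*, because the rounding rule is otherwise unspecified; floor
  keeps density ≤ cost and makes edge sets exactly nested across
  increasing costs.
* *Signed* z-values, not magnitudes: at ≤10% density the positive tail
  is all that survives, which matches standard practice for this
  atlas-and-cost recipe. Ranking by |z| is available (`absolute=True`)
  for sensitivity analysis.
* Ties at the cutoff break by lexicographic (i, j) order. With
  continuous data ties have measure zero; the rule exists so results
  are bit-reproducible.

Costs of 2–10% in 2% steps are the reference grid; 6% is the primary
threshold in the analyses this pipeline supports.

## Modularity

For a partition of an undirected, unweighted graph,
`Q = Σ_i (e_ii − a_i²)` with `e_ii` the fraction of edges inside
module *i* and `a_i` the fraction of edge endpoints attached to it.
Q of the trivial one-module partition is exactly 0; Q is undefined
(raises) on an edgeless graph.

**Spectral maximization.** `spectral_partition` implements recursive
leading-eigenvector bisection of the modularity matrix
`B = A − k kᵀ/2m` (the generalized form `B_g − diag(row sums)` for
subgroups), with:

1. the eigenvector computed by a full symmetric eigendecomposition
   (`numpy.linalg.eigh`) — exact and deterministic at the matrix sizes
   this package targets (n ≤ a few hundred), in place of an iterative
   solver;
2. Kernighan–Lin refinement of each bisection: every node is
   tentatively flipped once per pass in order of steepest gain in
   `sᵀBs`, interim negative gains allowed, and the pass rolls back to
   its best prefix; a handful of additional KL runs from random sign
   vectors guard against refinement-level local optima;
3. recursion stops when the best split does not increase Q
   (`ΔQ = sᵀB_g s / 4m ≤ tol`), the leading eigenvalue is ≤ tol, or the
   refined sign vector is uniform;
4. global clean-up on the final labels: greedy single-node moves
   between modules (including to a fresh singleton), greedy module
   merges, and a multiway KL pass (tentative single-node relocations
   with best-prefix rollback);
5. iterated local search: a few perturb-and-reoptimize rounds
   (reassign a fifth or half of the nodes at random, rerun the local
   search, keep the better Q). Recursive bisection occasionally commits
   to a 2-way split incompatible with a 3-way optimum on small dense
   graphs; the ILS rounds recover those cases. Small graphs (n ≤ 100)
   get more rounds because the search is cheap there.

All randomness flows from the `seed` argument (`None` behaves as 0), so
the procedure is fully deterministic. Validation: on thousands of random
graphs with n ≤ 8, the achieved Q matches the exhaustive optimum over
all set partitions (Bell(8) = 4140) essentially always, and planted
4-block graphs (60 nodes, p_in = 0.6, p_out = 0.05) are recovered with
ARI ≥ 0.9 near-universally.

Disconnected components are partitioned independently (the modularity
matrix is block-diagonal); edgeless components become singletons.

**Canonical partition.** A fixed node-to-system table (13 functional
systems: default mode, fronto-parietal, cingulo-opercular, salience,
dorsal/ventral attention, auditory, visual, memory, two somatomotor
systems, subcortical, plus an explicit "unassigned" module) can be
evaluated on the same graphs; it is a fixed assignment, never re-fit.

**Sub-network modularity** for a class of modules (association =
DMN/FP/CO/Sal/DAN/VAN vs sensory-motor = auditory/visual/somatomotor)
defaults to the sum of per-module contributions `q_i = e_ii − a_i²`
evaluated on the whole-brain graph — the only decomposition whose class
values add up to whole-brain Q. Q of the induced subgraph is available
(`method="subgraph"`) since the literature is ambiguous about which is
meant. The "unassigned" module belongs to neither class.

**Module segregation** `(Zw − Zb)/Zw` uses the full weighted z-matrix
(no thresholding): Zw is the mean z over within-module pairs in scope,
Zb the mean over pairs joining a scope module to any other module. It
is exactly 1 when between-module weights vanish and 0 on a homogeneous
matrix; Zw = 0 raises.

## Motion quality control

Framewise displacement follows the Power convention: the L1 norm of
backward differences of the six rigid-body parameters, rotations
converted to arc length on a 50 mm sphere (so 0.01 rad contributes
0.5 mm). FD of the first frame is 0 and FD is invariant to constant
offsets. Subjects (not frames) are excluded when **strictly** more than
10% of volumes have FD > 0.5 mm, or the maximum absolute translation
from the first (reference) volume **strictly** exceeds 4.0 mm — the
inequalities are strict because the rules are stated as "more than"/
"greater than", so a scan exactly at a boundary is retained. The
motion-file reader requires an explicit rotation-unit declaration
(radians vs degrees) rather than guessing; only Power-style FD is
implemented.

## Behavioral scoring

Per test, across subjects:

1. **Cleaning.** Values strictly beyond 3 sample SDs of the mean are
   excluded; mean/SD are recomputed on the survivors and remaining
   values strictly beyond 3 SDs are clamped to the cutoff. Because
   clamping shrinks the SD, a clamped value can land back outside the
   recomputed band; the two passes are therefore iterated to a fixed
   point, which makes cleaning exactly idempotent (convergence takes
   one or two rounds in practice). A zero-SD sample short-circuits with
   a warning.
2. **Standardized gain** `direction · (post − pre)/SD_pre`, with SD_pre
   the sample SD of raw pre-test scores pooled across groups.
   `direction = −1` for lower-is-better measures (reaction-time costs),
   so positive gain always means improvement; gains are invariant to
   positive rescaling of the raw test.
3. **Composites.** Baseline z-scores (standardized against the analyzed
   sample, direction-aligned) and gains are averaged within four
   constructs — vocabulary, perceptual speed, episodic memory, and EF
   (the fluid-reasoning tests plus task switching and spatial working
   memory). Missing member tests are skipped rather than propagated;
   a completeness column per construct supports downstream filtering.
4. **Structure check.** PCA of the baseline correlation matrix with
   four components and an oblique promax rotation (statsmodels'
   implementation); a pattern matrix implies oblique rotation, and the
   construct factors are correlated by design. Each test's dominant
   component (largest absolute loading) should match its construct.
5. **Task switching.** Local switch cost = mean correct switch RT −
   mean correct non-switch RT (the intervention-analysis measure). The
   combined speed/accuracy "bin score" ranks subjects into deciles
   separately on RT cost and accuracy cost and sums the two bin
   numbers (lower = better); being rank-based it is invariant to
   transformations that preserve the subject ordering of costs.

## Inference

**Headline model.** Within each intervention group, OLS of EF gain on
age, mean FD, baseline EF, baseline modularity Q, and the product of
mean-centered baseline EF and mean-centered Q. Centering (default on)
does not change fitted values or the interaction coefficient; it makes
the EF and Q main effects simple effects at the sample mean of the
moderator. `center=False` gives the raw parameterization, in which the
Q coefficient is exactly the data-generating slope when the generator's
planted model is the truth — the parameter-recovery analyses use it for
that reason. A reduced (intercept + Q) model mirrors the follow-up
analyses reported for groups whose full model is not significant.
Designs with condition number > 1e8 are rejected as collinear; n must
exceed the parameter count by at least 2.

**Confidence intervals.** Coefficients get both analytic OLS intervals
and case-resampling BCa bootstrap intervals (default 5000 resamples):
bias correction `z0 = Φ⁻¹(#{θ* < θ̂}/B)`, acceleration from jackknife
skewness `a = Σd³ / 6(Σd²)^{3/2}`, endpoints at the adjusted percentiles
`Φ(z0 + (z0+z_α)/(1 − a(z0+z_α)))`. A point estimate outside the
bootstrap range clamps z0 with a warning; a degenerate (constant)
bootstrap distribution raises. With vanishing bias and acceleration the
interval reduces to the percentile interval. Coverage for a correlation
coefficient at n = 50 is ~94% at the nominal 95% (validated by
simulation against an independent implementation).

**ANOVAs.** The mixed time × group ANOVA delegates to pingouin
(classical sums of squares; partial η² reported); the one-way gain
ANOVA/ANCOVA is computed by residualization (covariate-adjusted group F)
with per-group one-sample t tests against zero and Bonferroni-corrected
pairwise contrasts (`p_adj = min(1, m·p)`). A >4-fold spread of group
variances triggers a heteroscedasticity warning rather than an
automatic Welch switch, matching the classical reporting style this
pipeline reproduces. Confirmatory partial correlations support
one-tailed p-values; everything else is two-tailed.

**Partial correlation** is the Pearson correlation of the OLS residuals
of x and y on the covariates, df = n − k − 2, validated against both the
inverse-correlation-matrix identity and pingouin.

## Synthetic cohort generator

The generator provides ground truth for every stage. Per subject, one
master seed and the subject index derive independent streams for
latents, time series, motion, and battery, so any subject regenerates
bit-identically in isolation.

* **Time series**: i.i.d. multivariate normal draws with block
  correlation — `r_within` inside planted modules, `r_between` across
  them — sampled exactly via shared/block/idiosyncratic components.
  Defaults: 252 ROIs in 13 modules, 180 volumes, `r_within = 0.25`,
  `r_between = 0.10`. The within/between values are chosen so the two
  sampled-correlation distributions *overlap* at the reference scan
  length, as they do in real data; with a much larger contrast every
  retained edge is within-module and measured Q saturates at a
  degenerate ceiling, carrying no subject information. In the default
  regime, measured spectral Q at 6% cost averages ≈ 0.55 and correlates
  ≈ 0.95 with the latent target across subjects.
* **Latent modularity**: each subject's within-module correlation is
  scaled by a latent target Q drawn from N(0.30, 0.06²) (clipped to
  [0.02, 0.65]), so the *measured* Q — not the latent — carries the
  planted brain-behavior effect with realistic attenuation.
* **Motion**: low-amplitude random-walk drift (0.01 mm and 1e-4 rad
  per-frame steps) plus sustained translation shifts of 0.6–1.5 mm at a
  per-volume spike probability. Spike signs mean-revert once the offset
  exceeds the spike magnitude, so each spike produces exactly one FD
  excursion > 0.5 mm without accumulating into a spurious
  maximum-displacement exclusion; expected FD-crossing counts are
  binomial in the spike probability.
* **Battery**: four correlated construct factors (r = 0.3) load each of
  17 tests at 0.75 on realistic raw scales; the switch-cost measure is
  generated lower-is-better. Construct gains are group means plus the
  planted EF model `group mean + β_Q (Q − q_ref) + β_EF·EF +
  β_int · EF (Q − q_ref) + noise` with `β_Q = 1.8`, `β_int = −2.4`,
  noise SD 0.15 — magnitudes of the order reported for moderated
  modularity-gain regressions in this literature. Group EF gain means
  (walk 0.16, walk+supplement 0.17, strength/stretching 0.19, dance
  0.03 SD units) and CRF gain means (0.55/0.55/0.22/0.06) follow the
  reported pattern: fitness and EF gains in three arms, neither in the
  dance arm.
* **Two output paths.** `simulate_cohort` emits raw data (time series,
  motion, battery) for end-to-end pipeline runs; 
  `simulate_regression_cohort` emits the analysis-ready table directly
  from the planted model with modularity equal to the latent target —
  the calibration path on which the inference layer's recovery,
  coverage, and type-I-error properties are measured without
  measurement attenuation and at sizes (hundreds of replicates of
  n = 120) where simulating raw scans would be pointless work.

**What the generator does not emulate**, hence what passing tests do
not establish about real data: temporal autocorrelation and hemodynamic
filtering, scanner noise spectra, physiological confounds, spatial
structure within modules, motion-connectivity coupling (simulated
motion is independent of the time series), practice effects beyond a
constant retest gain, and non-normal score distributions.

## Problem sizes and runtime choices

The test suite and the acceptance script compute everything from
scratch at sizes chosen to estimate each property precisely but
cheaply: exhaustive modularity checks on 200 graphs with n ≤ 8,
planted-partition recovery over 100 seeds, regression recovery over
300–500 replicates of n = 120 with 1000 bootstrap resamples, BCa
coverage over 500–1000 simulations, and end-to-end pipeline runs on
60-ROI cohorts of 16–40 subjects. Reported bootstrap CIs in actual
analyses should use the 5000-resample default.

## Known limitations

* The spectral maximizer is a strong heuristic, not an exact solver;
  its near-optimality is validated only at enumerable sizes.
* Subjects are excluded, never censored frame-wise; no scrubbing.
* Composites average available member tests; no imputation model.
* The bin-score recipe is one reasonable reading of a rank-binning
  procedure that is cited more often than printed; it is isolated in a
  single function so an alternative recipe is a one-function change.
* Only case-resampling (not residual) bootstrap is offered, consistent
  with treating regressors as random in observational cohorts.
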