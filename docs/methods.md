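# Methods

This note documents the models, the numerical choices and the synthetic
study conditions the test suite runs under, and what those conditions do
and do not establish about real tracking data.

## Movement-state model and rate estimation

Locomotion is a three-state continuous-time Markov chain over still (S),
forward (F) and backward (B). The generator `Q` has six free off-diagonal
rates `q_ij ≥ 0` (units s⁻¹) in the fixed trait order
(SF, SB, FS, FB, BS, BF); each diagonal element is minus its row's
off-diagonal sum, so rows sum to zero (enforced to 1e−12). Self
transitions within a frame are unobservable and are not modelled.

The chain is observed only at frame times (default 4 Hz, Δt = 0.25 s).
The sufficient statistic is the 3×3 table of consecutive-frame counts
`n_ij`, with log-likelihood `Σ n_ij ln [exp(QΔt)]_ij`. The six rates are
estimated by maximizing this in log-rate space (L-BFGS-B, bounds
e⁻¹⁸·⁴ ≈ 1e−8 to e⁶·⁹ ≈ 1e3 s⁻¹), initialized at the first-order
estimator `n_ij/(n_i Δt)`. A rate leaving a state never observed as a
source is unidentifiable: it is pinned at the floor of 1e−8 s⁻¹ and
flagged, never silently dropped. The point estimate is the MLE; an
optional random-walk Metropolis sampler over log-rates (independent
normal priors, SD 10 — a documented choice, wide enough to be
non-informative at these data volumes) confirms that the posterior mean
coincides with the MLE at movie-scale counts. At ~10⁵ observed
transitions per movie a full posterior adds nothing to the per-plate
point summary, which is the natural log of the six fitted rates.

Rate-recovery study conditions: the generator spans the realistic range
0.05–2 s⁻¹, and chains are simulated until 10⁵ state *changes* are
observed (~10⁶ frames at 4 Hz). Counting only state changes — not
same-state frame pairs — is the operative notion of an observed
transition, consistent with self-transitions being excluded from the
model. An a-priori Fisher-information calculation fixes the design: the
asymptotic relative standard error of `q_ij` is `1/sqrt(q_ij T_i)` with
`T_i` the total time spent in state `i`, so a 0.05 s⁻¹ rate out of a
well-occupied state needs ≈10⁶ frames for ~1% precision; at 10⁵ frames
its Monte-Carlo noise alone would exceed a 5% tolerance about half the
time. The slow rates are therefore placed on the slow-exit (hence
high-occupancy) state.

## Univariate mixed model: background effects and mutational bias

Each log transition rate is modelled with fixed effects for genotype
background, MA status and their interaction, plus crossed random
intercepts for MA line and assay block and a residual:

    ln q = α + δ·bg + β·MA + η·(bg×MA) + u_line + w_block + e.

Fitting profiles the fixed effects out of the Gaussian (restricted)
likelihood and optimizes the three log-variances by Nelder-Mead; the
log parametrization keeps variances non-negative, with effectively-zero
components landing at a tiny floor. On balanced one-way designs the REML
solution reproduces the closed-form ANOVA estimators to 1e−6, and on
crossed designs it matches statsmodels' MixedLM (variance-components
formulation) to the printed precision; both serve as independent oracles
in the tests. The native implementation exists because the calibration
studies refit the model ~1,000 times inside a test run, which needs a
few tens of milliseconds per fit.

Testing follows a fixed protocol: the interaction is tested first by a
likelihood-ratio test (ML fits, χ² with 1 df); when non-significant at
α = 0.05 it is removed, and the background and bias effects are each
tested by LRT against the reduced model. Homogeneity of variances across
the four genotype-by-MA groups is checked with the classic Levene test
(mean-centered absolute deviations — mean rather than median centering
is a documented choice) on the conditional residuals (BLUPs subtracted)
of the final model. Covariates are excluded from this univariate model
and included in the multivariate model, matching how the two model
equations are specified.

## Multivariate model and the Gibbs sampler

The six log rates form a multivariate response

    y_plate = B'x_plate + u_line + w_block + e_plate,

with `x` the mean-centered covariates (temperature, humidity, log
density; an assay-year factor can be added as an extra fixed effect for
standing-variation data), and `u ~ N(0, V_L)`, `w ~ N(0, V_B)`,
`e ~ N(0, V_E)` with full 6×6 covariance matrices. **M** is ½·V_L:
MA lines are fully selfed, so fixed mutations are homozygous and the
among-line variance is twice the per-generation mutational input
accumulated in the lines.

Estimation is by Gibbs sampling with conjugate full conditionals:

* fixed effects: matrix-normal around the GLS solution given the random
  effects and V_E (flat prior);
* line and block effect vectors: multivariate normal, batched over
  levels sharing a replicate count;
* V_L, V_B, V_E: inverse-Wishart, prior scale the diagonal matrix of
  empirical phenotypic variances and prior degrees of freedom
  n_traits + 1 = 7 (both configurable). Draws use the Bartlett
  decomposition (unit-tested against the scipy inverse-Wishart mean).

Production settings mirror the study design (500,000 iterations, 50,000
burn-in, thinning 10). The test suite uses scaled-down settings
(20,000/2,000/10 and smaller), which the conjugate sampler's fast mixing
supports; the stored-chain lag-1 autocorrelation is reported and checked
against the 0.05 convergence guideline. Chains are bit-reproducible
given a seed.

A known behavior worth stating: with only two plates per line the line
covariance is weakly identified, and under a zero-signal generator its
posterior mean settles visibly above zero (prior mass plus genuine
posterior uncertainty). This is a property of the model, not a defect —
it is exactly why significance statements rest on permutation nulls
(refits after independently shuffling line and block labels across
plates), which carry the same prior and design and therefore the same
baseline. Calibration tests that need the line variance to concentrate
near zero use six plates per line instead.

## Matrix comparison statistics

* Eigendecomposition sorts eigenvalues descending; eigenvector sign is
  fixed by making the largest-magnitude coordinate positive, and a
  leading-eigenvalue tie below 1e−8 flags `m_max` as ill-defined.
* The angle between leading eigenvectors is folded into [0°, 90°]
  (Θ → 180° − Θ above 90°) because eigenvector sign is arbitrary. Its
  Monte-Carlo null draws vector pairs coordinate-wise uniform on (−1,1):
  in dimension 2 the mean folded angle is exactly 45° by the four-fold
  symmetry of the square; in higher dimensions it grows towards 90°.
* Π = v'Mv/(|v|² λ_max) measures the fraction of a matrix's maximal
  variance lying along another matrix's leading axis; its null is
  Π₀ = λ̄/λ_max. Both are computed per posterior draw.
* Null eigenvalue bands come from rotating permutation-null matrices
  onto the observed eigenvectors (v_k' N v_k per null matrix).
* Credible intervals are equal-tailed sample quantiles (not HPD), which
  makes them order-statistics-testable; two posteriors are declared
  different when their 83% intervals are disjoint, and permutation-null
  comparisons use 95% bands. These conventions are centralized in the
  pipeline module.

## Eigentensor analysis

Symmetric n×n matrices are mapped to length n(n+1)/2 vectors (diagonal
first in trait order, then upper-triangle off-diagonals row-major, each
×√2), an isometry for the Frobenius inner product with bit-exact round
trips. `S` is the sample covariance (divisor m−1) of the vectorized
matrices across the set; its eigenvectors map back to unit-Frobenius
eigentensors `E_i` with eigenvalues `α_i` (at most m−1 nonzero,
Σα = trace S). Coordinates are Frobenius inner products ⟨G_j, E_i⟩, and
the across-set variance of coordinates in `E_i` equals `α_i` — an
identity asserted to 1e−8. `α` is reported both raw and as a proportion
of Σα.

Uncertainty attaches by projecting posterior draws of the member
matrices onto the *fixed* point-estimate eigentensors (per-draw
coordinates and α-analogues, equal-tailed intervals), rather than
re-decomposing S per draw; nulls run the full analysis per randomized
matrix set. Fixing the eigentensors is the documented, testable choice;
a fully Bayesian tensor is out of scope.

## Synthetic study conditions

The generators' defaults are the study conditions the analysis assumes:

* Four groups — two founder genotypes, each with an ancestor and its MA
  lines — sharing assay blocks; 54 and 62 MA lines, 16 blocks, most
  lines on two plates in separate blocks, ancestors replicated across
  blocks. Reduced line/block counts are used where a test needs many
  replicate datasets; the sizes are stated at each use.
* Line effects drawn once per line from N(0, 2**M**) and shared by all
  the line's plates; block effects from N(0, V_B); multivariate
  residuals; group means applied on the natural-log scale.
* Default **M**: variances 0.15 (squared log-rate units) with mild
  positive correlation (0.3) between rates sharing a source state;
  block covariance 0.05·I; residual 0.2·I. These magnitudes give
  phenotypic variances and line/residual ratios of realistic order for
  log transition rates.
* Covariates are independent normals — temperature 20 ± 0.5 °C,
  relative humidity 50 ± 5%, log density 6.9 ± 0.3 (≈1,000 worms per
  plate) — with a modest temperature effect (0.05 per °C) by default.
  Real covariate distributions are not described by the study design;
  these are configurable stand-ins.
* State sequences come from exact CTMC simulation (exponential holding
  times, embedded-chain jumps) sampled at frame times, with uniform or
  user-specified initial state distribution.

What passing tests show — and do not. The generators produce exactly the
statistical structure the models assume: Gaussian effects, correctly
specified covariance structure, no tracking artifacts, no missing data,
no state-assignment error. Recovery and calibration results therefore
validate the estimators and their implementation, not robustness to
model misspecification in real movies (segmentation noise, track
fragmentation, non-Markovian behavior, heavy-tailed residuals).

## Problem sizes and determinism

Test-suite problem sizes are scaled-down study conditions chosen as the
smallest designs at which each statistical property is decidable:
rate recovery at 10⁵ observed state changes; M-recovery over 20
replicate datasets of 100 lines × 2 plates at 20,000 iterations; LRT and
Levene calibration at 500 null replicates of a 15+15-line design;
permutation calibration with 100 label-shuffle refits at short chains.
All randomness flows through explicit numpy Generators; the pipeline
spawns per-stage substreams from one global seed, so config + seed fully
determine every output (manifests record SHA-256 digests of all files).

## Known limitations

* Point-estimate rates (MLE) stand in for per-movie posterior means;
  at movie-scale counts the difference is negligible, but for very short
  tracks a full posterior would propagate rate uncertainty into the
  phenotype table.
* The inverse-Wishart prior is informative for weakly identified
  covariance components (few replicates per line); conclusions about
  significance should always be read against the permutation nulls.
* Missing trait values are rejected, not imputed.
* No pedigree/relatedness structure: lines are treated as fully inbred
  replicates.
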