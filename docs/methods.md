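# Methods

This note documents the models, conventions and numerical choices behind
`mrcluster`, and what the synthetic-data validation does and does not
establish about real data.

## Data model and harmonization

A summary panel is a list of per-variant associations (alleles, optional
effect-allele frequency, beta, SE, p, optional N) for one trait; binary
traits carry log-odds-ratio betas. Dialect maps (default: the GCTA-COJO
`.ma` column convention) absorb the column-name heterogeneity of consortium
files. Rows violating invariants (SE ≤ 0, p outside (0,1], malformed
alleles) are dropped with per-row reasons in a load report; accepted +
rejected always equals the input row count.

Harmonization aligns each outcome record to the exposure instrument's
effect allele: identical allele pairs pass through, swapped pairs flip the
sign of the outcome beta (and reflect the frequency), anything else is
dropped as incompatible. Palindromic variants (A/T, C/G) are excluded
unconditionally — no frequency-based strand inference — and the exclusion
happens before clumping, so a palindromic variant can never shadow a
non-palindromic neighbour. Strand-flipped records that are not palindromic
surface as incompatible and are dropped rather than guessed at.

## Instrument selection

Criteria are applied in a fixed order — p-threshold, MAF, F — and the first
failure is recorded, making rejection reasons deterministic. F is the
summary-data approximation (β/se)²; the R²-and-sample-size variant adds no
information when only one variant's summary stats are in hand. Clumping is
the standard greedy prune: repeatedly keep the smallest-p remaining variant
(ties broken lexicographically by id) and discard same-chromosome variants
within ±10,000 kb whose r² with it reaches 0.001. The LD source is any
pairwise r² table; absent pairs count as unlinked.

## Estimators

* **Wald ratio** (J = 1): βy/βx with first-order SE se_y/|βx|.
* **IVW, multiplicative random effects**: weighted regression through the
  origin with weights 1/se_y². The residual scale φ inflates the SE when
  φ > 1 and is floored at 1 (no underdispersion credit), so homogeneous
  data reproduce the fixed-effect SE exactly. This equals the
  inverse-variance-weighted mean of per-instrument Wald ratios with
  weights βx²/se_y² — an identity the tests assert at 1e-10.
* **MR-Egger**: weighted least squares (via statsmodels WLS) of βy on βx
  with intercept, instruments re-signed so βx ≥ 0 first. The intercept and
  its test are reported as the directional-pleiotropy diagnostic; the SE
  scaling mirrors the IVW convention with J − 2 degrees of freedom.
* **Weighted median**: ratios sorted, estimate interpolated at cumulative
  standardized weight 0.5 using pᵢ = (Sᵢ − wᵢ/2)/ΣW, weights βx²/se_y².
* **Weighted mode**: argmax over a 512-point grid of the weighted
  normal-kernel density of the ratios with Silverman-type bandwidth
  0.9·min(sd, IQR/1.34)·J^(−1/5), times a configurable factor (default 1).
  All ratios identical is treated as a point mass.

**Bootstrap SEs.** The weighted median and mode take parametric-bootstrap
SEs (default 1000 replicates, explicit seed): replicates draw
βx* ~ N(βx, se_x) and βy* ~ N(θ̂·βx, se_y) with θ̂ the observed statistic,
i.e. from the *fitted* ratio line. Centering the outcome draws on the
observed βy instead would convolve the outcome noise twice and inflate the
SE by up to √2, which measurably over-covers: under the package's null
simulations that variant yields type-I error ≈ 0.028 (median) and ≈ 0.012
(mode) at nominal 0.05, versus ≈ 0.05–0.07 for the fitted-model bootstrap
used here. Repeated-simulation calibration studies use 200 bootstrap
replicates per fit (the per-fit default stays 1000); across hundreds of
repetitions the extra bootstrap noise averages out.

Confidence intervals are normal-theory 95% everywhere; binary outcomes are
estimated on the log-OR scale with exponentiated estimates and intervals
attached for reporting.

## Sensitivity battery and verdict

Cochran's Q uses ratio weights βx²/se_y² against the primary estimate with
J − 1 degrees of freedom. Leave-one-out refits IVW J times and flags
instability on any sign flip or p-value crossing of 0.05. The Steiger test
computes per-variant variance explained r² = t²/(t² + n − 2) on each side,
removes variants explaining more outcome than exposure variance, and calls
the aggregate direction by comparing the summed r². Because the two panels
come from disjoint samples, the aggregate p uses the independent-samples
Fisher-z comparison rather than the dependent-correlations form, which
presumes one sample.

The outlier search follows the residual-sum-of-squares scheme: observed
RSS = Σ wᵢ(βyᵢ − θ̂₋ᵢβxᵢ)² with leave-one-out IVW estimates, compared to
parametric simulations (default 1000, seeded) of the outcome betas around
the fitted values; per-variant contributions give Bonferroni-corrected
outlier p-values, outliers are removed for a corrected estimate, and a
distortion p compares that shift against random same-size removals.
Empirical p-values use the (r + 1)/(n + 1) convention so they are never
exactly zero, which makes the global test very slightly conservative.

The verdict combines these: rejected when a potential-tier association has
any secondary estimator disagreeing in sign with the primary, when
leave-one-out is unstable, when outlier removal flips the estimate's sign,
or when the Steiger direction is reverse; a significant-tier sign
disagreement downgrades to caution instead (the association is kept but
flagged); an Egger-intercept p < 0.05 adds a caution flag but never rejects
on its own. Single- and two-instrument exposures skip the tests that need
J ≥ 3 (or ≥ 4 for the outlier search) and are judged on what remains.

## Multiple testing and eligibility

Per-category thresholds are 0.05/n with n counted from the run itself —
exposures with at least one instrument surviving selection and clumping —
not from the nominal category size, so a category with an instrument-less
exposure divides by a smaller n. Full precision is used for classification;
reporting rounds half-up to 4 decimals. A (category, outcome, tier) group
enters multivariable MR only with ≥ 2 robust-or-caution members.

## MR-BMA

Associations are standardized by the outcome SE (ỹ = βy/se_y,
X̃ = βx/se_y) and each exposure column scaled to unit Euclidean norm, so a
single prior effect variance σ² is scale-free across exposures. For subset
S the Gaussian marginal likelihood with unit residual variance and
independent N(0, σ²) effect priors has the closed form used throughout
(computed via the Woodbury and determinant identities on the |S|-sized
Gram matrix). Posteriors combine it with the Bernoulli(p) inclusion prior
(defaults p = 0.1, σ² = 0.5) and are normalized over all non-empty subsets
up to the configured model size when the exposure count permits exhaustive
enumeration (d ≤ 18), otherwise over the set visited by a seeded shotgun
stochastic search with add/delete/swap proposals. MIP is the summed
posterior of models containing the exposure; MACE averages the
model-specific posterior-mean (ridge) effect over all models, zero when
excluded — a conditional-on-inclusion variant is available by config.

Diagnostics on each top model (those above a small posterior floor,
default 0.02, so negligible models cannot flag variants) use the model's
weighted least-squares fit: squared standardized residuals q and classic
Cook's distances from the hat matrix. The prior-ridge fit is deliberately
not used here — with unit-norm columns it shrinks coefficients by a fixed
factor, leaving nonzero residuals even on perfectly fitting data, which
would defeat the q > 10 outlier rule. Variants with q > 10 in any top
model, or Cook's distance above the median of an F(|S|, J − |S|) reference,
are removed and the averaging is repeated exactly once; the re-run is
skipped with a warning if removal would leave J < d + 2.

## Mediation

The three effects are univariable two-sample MR estimates (IVW, or Wald
ratio at J = 1): β1 exposure→mediator at the exposure's threshold, β2
mediator→outcome at the mediator's (genome-wide) threshold, β3 the total
effect. The mediated proportion β1β2/β3 is reported with a first-order
delta-method SE under independence of the three steps (justified by the
two-sample design); proportions outside [0, 1] or with sign-inconsistent
indirect and total effects are flagged, never clipped. Instruments shared
between exposure and mediator are counted and logged but not excluded.

## Synthetic generator

Summary statistics are simulated directly — two-sample MR consumes nothing
else, and this keeps full Monte-Carlo studies in seconds. True instrument
effects γⱼ are uniform on [0.07, 0.35] with exposure-increasing allele
coding (γ ≥ 0, the convention real instrument selection produces; without
it a constant-mean pleiotropy would cancel across oppositely signed
instruments and directional pleiotropy could not be exercised). With
se_x = 0.02 the implied F spans ≈ 12–306, mimicking mixed-strength
instruments selected at p < 1e-5. Observed effects add independent normal
noise; p-values are exact two-sided normal. Pleiotropy regimes: none,
balanced (mean-zero), directional (mean 0.1, InSIDE-satisfying),
InSIDE-violating (α correlated with γ). Panels carry realistic allele
pairs with configurable palindromic and strand-flip fractions, 1-based
positions spaced 20 Mb apart (independent by construction), and optional
LD blocks with set within-block r². Multivariable scenes draw a J×d true
effect matrix with configurable pairwise column correlation; mediation
scenes chain β1 and β2 with a direct effect and give the mediator its own
stronger instruments. Binary outcomes emit log-OR betas with SEs from the
case/control split via 1/sqrt(2f(1−f)·n_eff). A single root seed spawns
per-panel substreams, so adding panels never perturbs earlier ones.

What the generator does **not** emulate: realistic allele-frequency
spectra, sample overlap between panels, LD beyond block-constant r²,
winner's-curse selection of instruments, and population stratification.
Passing recovery tests therefore shows the estimators and workflow are
implemented correctly under their stated assumptions, not that those
assumptions hold in any particular consortium dataset.

## Validation study sizes

The packaged studies use: 500 null replicates (θ = 0, J = 50) for
estimator type-I error; 200 null datasets at 200 outlier-search
simulations each for the global-test rejection rate; 500 replicates for
the directional-pleiotropy bias contrast and for the 40%-contamination
weighted-median study (balanced, alternating-sign contamination — a
one-sided shift biases any quantile estimator by the order of the ratio
noise and is not the regime in which the median is consistent); 100
replicates of the planted 2-of-8 recovery at exposure correlation 0.5,
J = 60; and a single small-SE mediation chain (β1 = 0.3, β2 = 0.5,
direct = 0.1, truth proportion 0.6). These sizes keep the full validation
under a minute while leaving Monte-Carlo error well inside the asserted
bands.

## Known limitations

* Steiger r² for binary traits uses the observed log-OR scale; no
  liability-scale conversion.
* No correlated-instrument (generalized) IVW, MR-RAPS or debiased IVW; no
  proxy-variant lookup for instruments missing in the outcome panel.
* The stochastic model search normalizes over visited models only; its MIPs
  agree with exhaustive enumeration to ~0.02 on d = 8 test instances but
  carry no global guarantee for very large d.
* Mediation handles one mediator at a time; no joint multi-mediator
  decomposition.
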