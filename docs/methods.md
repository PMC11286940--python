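# Methods

This note documents the statistical machinery implemented in
`isodiet`: the models, their assumptions, the defaults and why, the
numerical choices, and what the synthetic-data generators do and do
not emulate.

## Study calendar and stratification

The analysis year runs April 1 → March 31. Seasons are fixed calendar
quarters — spring (Apr–Jun), summer (Jul–Sep), fall (Oct–Dec), winter
(Jan–Mar) — and day-of-year counts from April 1 (day 1) to the
following March 31 (day 365, or 366 across a leap February).
Multi-year inputs are split into April→March cycles before mapping.
Size classes split at 100 cm fork length; exactly 100.0 cm is assigned
to the adult class (the verbal definition "< 100 / > 100" leaves the
boundary open; a half-open interval keeps the rule deterministic).

## Filtering

Before any statistic: bait and chum items are discarded; non-prey
contents (Sargassum, parasites) are dropped without disqualifying the
stomach; prey identified more coarsely than family is dropped (the
order Stomatopoda is kept as an honorary family-level group, as is
conventional when an order is ecologically homogeneous and routinely
reported at that rank); stomachs left with no identifiable natural
prey are excluded. Every dropped row receives a reason code in an
exclusion log, and retained + logged rows partition the input exactly
— an invariant the test suite enforces. Filtering is idempotent.

## Importance indices

%N and %W are computed over all items in a stratum; %FO uses the
retained (post-filter) stomach count as its denominator — the
alternative (pre-filter) denominator would make %FO depend on the
number of unidentifiable-only stomachs, which carries no dietary
information. Indices can be aggregated at family level (default, the
reporting unit of the heat matrices) or at the lowest identifiable
rank. The heat-matrix inclusion threshold (%IRI ≥ 1% in at least one
season) is inclusive. A stomach whose items all weigh 0.0 g at the
0.1-g resolution has its %W term dropped and %NW renormalized from %N
alone; such stomachs are degenerate but rare and are logged.

## Community analysis

Bray–Curtis dissimilarity, PERMANOVA, SIMPER and accumulation curves
are implemented natively (they are simple enough that a transparent
implementation is worth more than a dependency), and the tests verify
them against independent references: a double-loop/`scipy` distance
check, `scikit-bio`'s PERMANOVA pseudo-F, brute-force pair enumeration
for SIMPER, and the closed-form hypergeometric expectation for
accumulation curves.

PERMANOVA partitions squared dissimilarities (total SS = Σ_{i<j}
d²_ij / n; within-group SS analogously per group) and uses unrestricted
random relabeling — the one-factor seasonal design has no blocking
structure. The permutation count defaults to 999; p-values include the
observed statistic in the null set, p = (1 + #{F* ≥ F}) / (1 + n_perm),
so p is never 0 and the test is exact under exchangeability. Pairwise
contrasts default to unadjusted p-values (Bonferroni and Holm are
available); no adjustment is the default because the adjustment choice
is a reporting decision, not a property of the statistic.

Prey source groups come from Ward-linkage agglomerative clustering on
Euclidean distances of z-scored per-taxon tracer means, cut at three
groups. Ward linkage is the standard choice for compact, roughly
spherical isotopic clusters; z-scoring prevents the tracer with the
largest dynamic range from dominating.

## Cyclic spline smooths

Seasonal curves use cyclic cubic regression splines: k evenly spaced
knots on [1, 366] with the last knot identified with the first, so the
fitted curve and its first two derivatives match across the year
boundary. The basis is parameterized by knot values; the natural-spline
continuity conditions give a cyclic tridiagonal system B γ = D β for
the knot second derivatives, and the curvature penalty is
β′ D′ B⁻¹ D β, whose null space is the constant function. The penalty
matrix is normalized to unit spectral norm so smoothing parameters are
comparable across bases. The construction was cross-checked against an
independent reference implementation of the same textbook
parameterization; frozen values live in the test suite.

Fits are penalized IRLS (binomial-logit for occurrence, Gaussian for
isotopes). The smoothing parameter is chosen by grid-search GCV over
43 log-spaced values spanning 1e-5–1e9; an approximate profiled-REML
criterion is available for Gaussian fits. GCV is the default because
it is family-agnostic and derivative-free; REML (as used with `mgcv`)
tends to smooth slightly more aggressively, and the two can select
different λ on small samples — fitted curves are typically
indistinguishable at the sample sizes here. Smooth-term p-values are
approximate Wald tests of the coefficient vector against its constant
projection, using the frequentist covariance and edf-matched reference
distributions; they are screening values, not exact tail
probabilities.

Hierarchical (group-wise) fits give each size class its own smooth and
its own λ — the "independent shape and wiggliness" hierarchical-GAM
variant — with the group intercept defined as the mean of the fitted
curve over the period, so group offsets are directly comparable. The
two-level "random effect" is thereby treated as fixed group structure;
with only two levels a variance component is not estimable anyway.
Occurrence models use k = 6 and isotope models k = 8; taxa present in
fewer than 5 stomachs, or present in all/none, are flagged and
skipped.

## Isotopes

δ values are per-mil deviations of heavy/light isotope ratios from
the international standards (VPDB, air N₂, VCDT). Consumer white
muscle δ¹³C is lipid-corrected with the arithmetic equation
δ¹³C + (9.356·C:N − 29.359)/(C:N + 2.181), applied only when C:N
strictly exceeds the equation's x-intercept 29.359/9.356 ≈ 3.14 — at
the threshold the correction is zero to < 0.01 ‰, so the strict/
non-strict choice is immaterial. Prey corrections are looked up from a
user-editable registry CSV (id, functional form, coefficients,
threshold) applied above C:N = 3.5; the registry ships with the
consumer equation's form as its default entry because the appropriate
literature equations are taxon-specific and must be supplied by the
analyst. A `lipid_corrected` flag makes correction idempotent.
Screening bounds on tracer values (δ¹³C ∈ [−40, −5] etc.) are
configurable validation aids, not science. Instrument-side two-point
normalization is assumed already done upstream.

## Bayesian mixing model

For consumer i and tracer j, with source proportions p on the
K-simplex, source tracer means μ_kj, SDs σ_kj, elemental
concentrations c_kj, and TDFs Δ_j ± τ_j:

    mean_j(p)    = Σ_k p_k c_kj (μ_kj + Δ_j) / Σ_k p_k c_kj
    procvar_j(p) = Σ_k (p_k c_kj)² (σ_kj² + τ_j²) / (Σ_k p_k c_kj)²

    x_ij ~ Normal(mean_j(p), ξ_j · procvar_j(p))

The per-tracer multiplicative factor ξ_j implements combined
residual × process error: ξ_j ≈ 1 means consumer scatter matches the
process (source + TDF) variance of a fixed diet, ξ_j > 1 absorbs
individual diet variation and unmodeled error. ξ_j gets a weakly
informative Lognormal(0, 1) prior. This multiplicative formulation is
one of the two standard conventions for combining the two error types;
it is documented here because the choice is not unique.

The prior on p is Dirichlet with α_k = K · share_k, where share_k is
the season-averaged %NW proportion of source group k in the stomach
data. This construction keeps the prior's total concentration Σα equal
to the source count — exactly as informative as a single uniform
observation — so stomach data shift the prior's location without
overwhelming the isotope likelihood. Zero shares are floored at 0.01
(then renormalized) to keep the Dirichlet proper.

Sampling: random-walk Metropolis on the unconstrained state
(additive-log-ratio coordinates of p, log ξ), all chains advanced in
lockstep. During burn-in the scalar step size adapts toward 30%
acceptance every 100 iterations, and a diagonal preconditioner
(per-dimension proposal scales from the pooled within-chain spread) is
refreshed at 50% and 90% of burn-in; all adaptation freezes before
retained sampling, preserving detailed balance. Chains initialize
overdispersed (z ~ N(0, 2)). Defaults are 4 chains × 20,000 iterations
with 10,000 burn-in and thinning 10 — desk-scale settings that give
~4,000 retained draws and split-chain Gelman–Rubin statistics
comfortably below the 1.1 convergence criterion for the three-source,
two-tracer problem; production-scale settings (e.g. 10⁶ iterations,
5·10⁵ burn-in, thin 500) are a configuration change. Convergence uses
the split-chain potential scale reduction factor; zero within-chain
variance (a constant parameter) is defined as R̂ = 1, and
non-convergence raises a warning rather than failing silently.

Tracer sets (e.g. with and without δ³⁴S) are compared by PSIS-LOO on
the pointwise log-likelihood over retained draws, falling back to WAIC
with a flag when more than 10% of Pareto-k diagnostics exceed 0.7. The
default tracer set is δ¹³C + δ¹⁵N; δ³⁴S is supported but optional,
reflecting both weaker model support and the absence of reliable δ³⁴S
discrimination factors for tuna-like fishes.

Tissue turnover lags diet, so mixing-model seasons are aligned to diet
windows by shifting sub-adult tissue seasons back 6 months (2 seasons)
and adult seasons back 9 months (3 seasons), cyclically.

## Synthetic data

The generators define the package's study conditions. The diet
generator emulates one April→March cycle: 78 sub-adult and 44 adult
stomachs per season (the retained sample sizes of a year-round
weekly-sampling study of this design), capture dates uniform within
season, fork lengths truncated-normal (82 ± 8 cm sub-adult, 130 ± 15
adult, truncated to 64.5–183.5 cm), multinomial prey draws from
season × size-class availability profiles over ten taxa (the nine
dissimilarity-driving families plus a coastal mugilid), zero-truncated
Poisson counts, lognormal weights rounded to 0.1 g, 10% bait
contamination and 15% empty stomachs. Availability profiles encode the
qualitative seasonal story — squids/flyingfishes in spring, juvenile
carangids in summer, coastal fishes in fall, planktonic amphipods in
winter.

The isotope generator is the mixing model's generative twin: consumers
are drawn Normal(mixture mean, process variance × residual multiplier)
at known proportions (default p = (0.2, 0.5, 0.3), 30 consumers), with
stand-in source parameters (δ¹³C means −17/−18.5/−20 ‰, δ¹⁵N
14.5/9.5/6.5 ‰ for coastal nekton / oceanic nekton / oceanic plankton)
and stand-in elemental concentrations (C ≈ 0.40–0.46, N ≈ 0.09–0.13,
S ≈ 0.01 dry-weight fractions). C:N ratios ~ N(3.3, 0.25) exercise the
lipid-correction path. A third generator scatters prey taxa around
planted tracer centroids for clustering checks.

What the generators do **not** emulate: real taxonomic richness (10
taxa vs. > 100 in real guts), digestion-state biases, gear/angler
selectivity, spatial structure, inter-annual variation, or isotopic
baseline shifts. Passing tests therefore demonstrate that the
estimators recover known structure under the models' own assumptions —
not that those assumptions hold for any particular field dataset.

## Known limitations

- The GAM engine is a single-smooth cyclic engine: no tensor products,
  multiple covariates, or exact REML with derivative-based
  optimization.
- The mixing sampler is random-walk Metropolis, adequate for ≤ ~5
  sources; gradient-based samplers would be preferable for larger
  source sets or covariate models.
- Posterior medians at n = 30 consumers scatter substantially (single
  datasets can sit ~0.2 from the generative truth while the 95%
  interval covers it); inferences at that sample size should lean on
  intervals, not point estimates.
- Smooth-term p-values are approximate; treat them as screening
  diagnostics.
- Continuous-covariate mixing models and consumer-level random effects
  are out of scope; size classes are handled as separate model runs.
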