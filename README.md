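# isodiet

Seasonal diet analysis for oceanic predators, combining stomach-content
importance indices, permutational community analysis, cyclic-spline
seasonal models, and a Bayesian stable-isotope mixing model (BSIMM) with
diet-informed priors.

The package is written for trophic ecologists who have two complementary
data streams on a predator such as yellowfin tuna: stomach contents (a
snapshot of the last hours of feeding) and bulk tissue stable isotopes
δ¹³C / δ¹⁵N / δ³⁴S (an integral over months of assimilated diet). It
implements the full quantitative chain needed to ask *how diet shifts
across the seasonal cycle and between predator size classes*, and ships
seeded synthetic-data generators so the whole chain is testable without
any field data.

## What it computes

**Prey importance.** Per season × size-class stratum, percent
composition by number (%N), wet weight (%W) and frequency of occurrence
(%FO), the index of relative importance

    IRI = (%N + %W) × %FO,        %IRI = 100 · IRI / Σ IRI,

and the per-stomach weighted composition metric %NW = (%N + %W)/2 whose
stomach × taxon matrix feeds everything downstream.

**Community analysis.** Native Bray–Curtis dissimilarity, one-way
PERMANOVA with permutation p-values (the observed statistic is always
included in the null set), pairwise contrasts with optional
Bonferroni/Holm adjustment, SIMPER decomposition of between-group
dissimilarity into per-taxon contributions, species accumulation curves
(permutation and closed-form), and Ward clustering of prey isotope
values into source groups.

**Seasonal smooths.** Cyclic cubic regression splines over day-of-year
(day 1 = April 1), penalized IRLS with GCV-selected smoothing:
binomial GAMs of prey occurrence (k = 6) and Gaussian hierarchical GAMs
of isotope values with an independent smooth per size class (k = 8).

**Isotope handling.** Delta-notation conversion, lipid correction of
δ¹³C for consumer white muscle (applied above the equation's C:N
x-intercept of 3.14) and registry-based literature corrections for prey
(applied above C:N = 3.5), plus stratified summaries.

**Mixing model.** A from-scratch BSIMM estimating the simplex p of
source-group contributions from consumer tracer values, with trophic
discrimination factors (defaults 0.82 ± 1.13 ‰ for Δ¹³C, 2.1 ± 1.0 ‰
for Δ¹⁵N), elemental concentration dependence, multiplicative
residual × process error, informative Dirichlet priors built from
stomach-content %NW shares (α_k = K · share_k), adaptive random-walk
Metropolis in log-ratio space, split-chain Gelman–Rubin diagnostics,
PSIS-LOO tracer-set comparison, and 6/9-month tissue-turnover season
alignment.

## Worked example

Run the full chain on a synthetic study cycle (489 stomachs across two
size classes and four seasons, 30 isotope consumers generated at known
source proportions p = (0.2, 0.5, 0.3)):

```bash
isodiet run --config run.yaml
```

with `run.yaml`:

```yaml
synthetic: true
synthetic_seed: 42
out_dir: demo_run
mcmc_seed: 7
```

The manifest reports every stage `ok`, and the run directory contains
the composition tables, diet matrix, PERMANOVA/SIMPER results,
occurrence curves and posterior summaries. Highlights of the output:

```
 pseudo_F  df_between  df_within  p_value  n_permutations
27.281197           3        413    0.001             999
```

Season strongly structures the diet (PERMANOVA on Bray–Curtis
dissimilarity of the %NW matrix, 999 permutations; p is the smallest
value resolvable at that permutation count).

```
          source  alpha          source  median  ci_low  ci_high
  coastal_nekton  0.206    coastal_nekton   0.129   0.047    0.246
  oceanic_nekton  2.159    oceanic_nekton   0.748   0.365    0.942
oceanic_plankton  0.635  oceanic_plankton   0.126   0.001    0.393
```

Left: the diet-informed Dirichlet prior built from the generated
stomach contents (α sums to the number of sources). Right: posterior
medians and 95% credible intervals for the source contributions; all
Gelman–Rubin statistics were below 1.06 (threshold 1.1). The posterior
pulls toward oceanic nekton relative to the generative truth because
the informative prior concentrates there — exactly the prior–data
interplay the model is designed to expose.

The same pieces are importable as a library:

```python
from isodiet import mixing
from isodiet.synthetic import IsotopeScenario, generate_consumers

consumers, sources, tdf = generate_consumers(IsotopeScenario(seed=42))
post = mixing.sample_posterior(
    consumers[["d13C", "d15N"]].to_numpy(), sources, tdf,
    mcmc=mixing.MCMCSettings(seed=1),
)
print(post.summary())          # median + 95% CI per source
print(max(post.rhat.values())) # split-chain Gelman-Rubin
```

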