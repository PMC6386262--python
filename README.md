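# pedsel

Pedigree-based quantitative genetics for multi-generation selection
programs, built around the problem of breeding away canine hip dysplasia
in a closed guide-dog colony.

Working-dog colonies select breeders on radiographic hip quality using two
measures: the ordinal **hip-extended score** (HES, 1 = worst to 8 = best)
and the **PennHIP distraction index** (DI, a continuous joint-laxity ratio
where lower is better and values at or below 0.30 indicate minimal
osteoarthritis risk). The central quantitative question is whether
selecting on one measure improves the other — which turns on the traits'
heritabilities and genetic correlation. `pedsel` provides the full
analysis stack for this kind of program:

* **Pedigree algebra** — topological validation, inbreeding coefficients
  F (Meuwissen–Luo tabular recursion), the numerator relationship matrix
  A and its sparse inverse by Henderson's rules with inbreeding, and
  approximate generation coefficients for overlapping generations.
* **Phenotype preparation** — the collapsed 7-class hip-score scale,
  breed-by-calendar-quarter contemporary groups, deviation adjustment,
  per-generation summary tables.
* **The two-trait animal model** — y_t = X_t b_t + Z u_t + e_t with
  var(u) = G0 ⊗ A, fitted by EM-REML (average-information standard
  errors) or a Gibbs sampler (inverse-Wishart full conditionals, data
  augmentation for trait-wise missing records), following the
  statsmodels pattern: `AnimalModel(...).fit(method=...)` returns a
  results object with estimates, intervals and `summary()`.
* **Selection-index EBVs** — the classical index from up to four
  information sources (own record, paternal/maternal half-sib means,
  progeny mean).
* **Response analysis** — correlated response CR = i·h·r_A·σ_A,
  selection differentials S = mean(parents) − mean(cohort), selection
  intensities.
* **Trend statistics** — Jonckheere–Terpstra ordered-trend test (exact
  enumeration at small n, tie-corrected normal approximation otherwise),
  sequential ANOVA, Pearson correlation with Fisher-z intervals.
* **A breeding-program simulator** — an infinitesimal-model generator of
  multi-generation two-trait programs with truncation selection, used as
  the test bed for everything above.

## Worked example

Simulate a small four-generation program selected on the hip score, fit
the two-trait animal model by REML, and predict the correlated response
in the distraction index:

```python
from pedsel.simulate import SimConfig, simulate_program
from pedsel.model import AnimalModel, TraitSpec
from pedsel.response import correlated_response

cfg = SimConfig(n_founders=60, litters_per_generation=15, litter_size_mean=5,
                n_generations=4, criterion="phenotype", selection_trait="HES",
                seed=1)
pop = simulate_program(cfg)
am = AnimalModel(
    pop.phenotypes(), pop.pedigree(),
    [TraitSpec("HES", "hes", ("sex",), ("age_days", "F_pct")),
     TraitSpec("DI", "di", ("sex",), ("F_pct",))],
)
res = am.fit_reml(tol=1e-5, max_rounds=300)
print(res.summary())
cr = correlated_response(1.0, res.h2[0], res.r_a, res.G0[1, 1])
print(f"predicted correlated response in DI at i=1: {cr:.3f} DI units/generation")
```

prints

```
EM-REML animal model
====================================================
records: 349   pedigree animals: 349
converged in 70 rounds

HES: sigma2_A=0.5585  sigma2_E=0.2724  h2=0.672 (SE 0.088)
DI: sigma2_A=0.009554  sigma2_E=0.004036  h2=0.703 (SE 0.088)
genetic correlation rA=-0.392 (SE 0.126)
predicted correlated response in DI at i=1: -0.031 DI units/generation
```

Both hip measures are strongly heritable in this simulated colony and
negatively genetically correlated (higher hip score goes with lower — 
better — distraction index), so one standard-deviation-intensity
selection on the score is predicted to drop the mean distraction index by
about 0.03 units per generation. `fit(method="gibbs")` gives the Bayesian
counterpart with 95% highest-posterior-density intervals.

A command-line surface wraps the same pipeline:

```bash
pedsel simulate --seed 1 --out simdata/
pedsel fit --pedigree simdata/pedigree.csv --phenotypes simdata/phenotypes.csv \
           --method both --out run/
pedsel response --variances run/variance_components.json --out response.csv
```

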