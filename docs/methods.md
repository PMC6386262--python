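# Methods

## The model

Each animal carries up to two hip-quality phenotypes: the hip-extended
score (HES), an ordinal 1–8 radiographic grade treated as a linear
variable for genetic analysis, and the PennHIP distraction index (DI), a
continuous laxity ratio. The joint model is the standard two-trait
animal model

    y_t = X_t b_t + Z u_t + e_t,        t ∈ {HES, DI}

with additive genetic effects u = (u_HES, u_DI) for **every** pedigree
member (phenotyped or not), var(u) = G0 ⊗ A, and residuals with 2×2
covariance R0 per animal, restricted to the observed traits when a record
carries only one of them (trait-wise missingness; no row-wise deletion and
no phenotype imputation in the likelihood). A is the numerator
relationship matrix implied by the pedigree; the model only ever uses its
sparse inverse, assembled directly by Henderson's rules with full
inbreeding accounting (diagonal Mendelian-sampling terms
d_i = 0.5 − 0.25(F_s + F_d) for two known parents, 0.75 − 0.25 F_p for
one, 1 for none).

Fixed effects follow the colony analysis they mirror: for HES — sex,
contemporary group (breed × calendar quarter of evaluation), generation
class, and covariates for age in days and inbreeding; for DI — sex,
generation class and inbreeding. The inbreeding covariate is expressed in
percent (0–100) so its slope reads "units per 1% inbreeding"; this is a
configurable convention. Class effects are dummy-coded with the first
level dropped; covariates are centred. Maternal and litter effects and
genomic relationships are out of scope.

Assumptions worth keeping in mind: additive infinitesimal inheritance
(no dominance/epistasis in A), HES treated as Gaussian despite its
ordinal ceiling, and selection ignorable given the pedigree and all
phenotypes used in selection — the usual justification for analysing
selected populations with an animal model.

## Estimation

**EM-REML.** The expectation-maximisation updates operate on the
mixed-model equations: G0 ← (û'A⁻¹û + tr(A⁻¹ C^{uu}))/q per trait pair,
and R0 from per-record expected residual cross-products, with the
conditional-expectation completion for records observed on one trait
only. The MME coefficient matrix is factorised densely each round
(Cholesky; the full inverse provides the trace and prediction-error
terms). Plain EM converges linearly and stalls near the optimum, so every
third round a safeguarded component-wise Aitken extrapolation is applied;
jumps are accepted only if both matrices stay positive definite. The
convergence criterion is the maximum relative parameter change (default
1e-9, configurable; the recovery tests use 1e-4, which is far below the
sampling noise at their data sizes). If an update leaves the
positive-definite cone it is bent back to the nearest PD matrix with a
warning. Standard errors come from the inverse average-information matrix
evaluated at the optimum, with delta-method SEs for h² = σ²A/(σ²A+σ²E)
and r_A = σA12/√(σA1²σA2²); intervals are estimate ± 1.96 SE.

**Gibbs sampling.** All location effects are refreshed coordinate-wise
from univariate normal full conditionals (a single-site scan over the
sparse MME, compiled with numba); G0 and R0 are drawn from their
inverse-Wishart full conditionals; records missing one trait have that
trait's value augmented from its residual conditional each round, which
keeps the R0 conditional a complete-data inverse-Wishart. Priors are flat
on fixed effects and proper inverse-Wishart on G0 and R0 with df =
dimension + 2 and scale = `prior_scale` · I. The default scale is 1e-6:
with an identity-scale prior the posterior scale matrix is I + Σe_ie_i',
which for a trait with variance ~0.01 (DI) would be dominated by the
prior and inflate the residual variance severely (about +50% at n = 360
in our checks); the tiny scale keeps the prior proper but practically
flat. Chain defaults are 50,000 iterations, 5,000 burn-in, thinning 500
→ kept draws (iterations − burn-in)/thin; `ChainConfig.paper_scale()`
gives the 500,000/50,000/500 production geometry (900 retained draws).
Point summaries use the ratio of posterior means for h² (the
report-table convention); per-draw ratios feed the 95%
highest-posterior-density intervals, computed as the shortest window
containing ⌈0.95 n⌉ sorted draws. Identical seeds give identical chains.

## Selection index

Before animal-model BLUP, EBVs were computed from up to four
contemporary-group-deviated information sources (own record, paternal
half-sib mean, maternal half-sib mean, progeny mean) by solving P b = g
with the textbook (co)variance entries (documented in the module). Two
conventions are choices, not data: progeny are treated as half-sibs of
one another (studs have many mates; configurable to full-sib), and no
adjustment is made for the sources themselves being selected — a known
limitation of index theory. Half-sib sets exclude the candidate and the
candidate's own progeny.

## Response analysis

Correlated response uses CR = i · h_X · r_A · σ_A(Y) per generation;
selection differentials are retrospective: the "parents" of generation
class k are the measured dogs of class k that later produced offspring,
compared against all measured dogs of the class. Report tables round DI
to 2 decimals and correlated responses to 3, matching the conventions of
the tables they mirror.

## Trend statistics

The Jonckheere–Terpstra statistic sums pairwise Mann–Whitney counts over
ordered group pairs with the half-count tie convention. For total n ≤ 12
the exact permutation distribution is enumerated (all distinct
assignments of the observations to the group sizes); otherwise the
normal approximation with tie-corrected variance is used. The default
alternative is one-sided increasing (a shift toward better scores in
later generations). The raw JT statistic scales like n²; published
values from other software may use a different normalisation, so only
ordering behaviour and p-values, not raw magnitudes, are comparable
across implementations.

## The simulator

The generator reproduces the statistical structure of the colony data:
two traits per animal with additive covariance G0 and residual covariance
R0 on a deepening pedigree; a latent Gaussian HES cut at thresholds
(default 1.5, 2.5, …, 7.5) into the 1–8 scale, giving the right-skewed
score distribution a selected colony shows; a male–female DI difference
(default −0.034 DI units for males); inbreeding depression entering the
*phenotype* only (default −0.001 DI units per percent F, matching the
fixed-covariate treatment in the model); one evaluation per animal at age
~ N(480, 90²) days. Offspring breeding values are midparent plus a
Mendelian-sampling deviation with covariance 0.5(1 − (F_s+F_d)/2)G0,
with F tracked exactly through the recorded pedigree. Default variance
parameters are Labrador-like colony estimates (additive variances 1.700
for latent HES, 0.0096 for DI — so DI heritability 0.0096/0.0144 = 0.67 —
genetic correlation −0.21, residual variances 0.662 and 0.0048 with
residual correlation −0.30, the latter a package choice since no
Bayesian residual covariance is published). Parents are truncation-
selected per sex (defaults: top 15% of males, 50% of females) by
phenotype, selection-index EBV, animal-model BLUP EBV, or at random; a
fraction of sires (default 0.1) carries over from the previous cohort,
which makes generation coefficients fractional and exercises the
overlapping-generation class machinery.

What the simulator does **not** emulate: litter and maternal
environmental effects, real mating constraints beyond full-sib
avoidance, culling on other traits, scorer drift within contemporary
groups, and the historical founder structure of any real colony.
Passing recovery tests therefore show the estimators are correct for the
generative model, not that real-data estimates are unbiased.

Two generative facts matter for interpreting tests. First, cutting the
latent HES into 8 ordinal classes attenuates its expressed genetic
variance and its correlation with DI, so parameter-recovery checks fit
the latent column the simulator also emits; the ordinal column is used
where the ordinal scale is the point (trend tests, class tables). Second,
under random mating the per-generation trait means follow a random walk
(drift), so "no trend" checks average regression slopes over independent
replicates rather than testing one run's slope against its own OLS
standard error.

## Problem sizes and numerical choices

The variance-component recovery studies use one simulated program of
about 1,550 animals over 8 generations (REML tolerance 1e-4; Gibbs chain
20,000/2,000/20, 900 retained draws), interval-coverage studies use 20
replicates of ~360 animals, and the end-to-end pipeline check simulates
~1,250 dogs over 8 generations and fits both estimators — sizes chosen
so the whole suite runs comfortably on one CPU while leaving the Monte
Carlo error well inside the asserted tolerances. Dense A is allowed only
up to 5,000 animals (everything model-side uses sparse A⁻¹). The MME
solver verifies a relative residual below 1e-8. Quartiles default to the
linearly interpolated empirical CDF (numpy's default, "type 7");
generation coefficients round half-up into classes (2.5 → 3), both
configurable. Rank-deficient fixed-effect designs raise by default,
naming the confounded terms; the pipeline opts into pivoted-QR dropping
of aliased columns, which is the practical choice when contemporary
groups nest inside generation classes in simulated data.

## Known limitations

EM-REML standard errors assume the optimum is interior; near a variance
boundary (h² → 0 or |r_A| → 1) the delta-method intervals are unreliable.
The Gibbs sampler's single-site location scan mixes more slowly than a
blocked sampler on very dense pedigrees, which the variance draws absorb
by running longer chains. HES is analysed on the linear scale by design
fidelity; a threshold model would be the statistically cleaner treatment
of an ordinal trait with a ceiling. The selection index ignores parental
selection and information from relatives outside the four sources.
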