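# Methods

## Two-sex moving-optimum model

One ecological trait is expressed in both sexes. In environment ε the
sex-specific optimum is θ_s = B_s·ε and the mean phenotype is
z̄_s = ā_s + b_s·ε, where ā_s is the mean breeding value and b_s the
fixed reaction-norm slope (plasticity). Fitness is Gaussian around the
optimum with strength γ_s; an optional quadratic cost of plasticity
subtracts (γ_b,s/2)·b_s² from that sex's growth contribution. Additive
genetic (co)variances are constant:

    G = [[V_A,f, r_mf√(V_A,f V_A,m)], [·, V_A,m]].

Each generation the mean breeding values respond as
Δā = ½·G·β with β_s = −γ_s·L_s and lag L_s = z̄_s − θ_s (the ½ is
autosomal inheritance: each sex inherits half its breeding value from
each parental sex). Population growth is r_max minus the demographically
weighted loads: under *female demographic dominance*
r = r_max − (γ_f/2)L_f² − cost_f; under *co-dominance* each sex's lag
load and cost carries weight ½.

**Directional change** (ε = η·t). Stationarity of the recursion gives
the steady lags

    L_f = −(2η / (γ_f V_A,f (1 − r_mf²))) (K_f − r_mf K_m √(V_A,f/V_A,m)),

(and symmetrically for males), with K_s = B_s − b_s the effective rate
of optimum change. Substituting into the load expressions yields the
closed-form r_eq implemented in `theory.growth_directional`. Because
r_eq is quadratic in b_SD = b_f − b_m at fixed b̄, the growth-maximising
dimorphism has a closed form (`theory.optimal_bsd`); in the cost-free
symmetric case (B_f = B_m, V_A,f = V_A,m) under female dominance it
collapses to b̂_SD = 2(B_f − b̄)(1 − r_mf)/(1 + r_mf), and under
co-dominance with equal selection and variances to exactly 0. The
co-dominance closed form assumes equal plasticity costs in the two
sexes and refuses unequal costs.

The printed equations this implementation descends from survive only in
typographically damaged form in the source text, so the algebra was
re-derived from the model definition; *the package treats the forward
simulator, not the transcription, as ground truth*. `sexplas.validation`
draws random valid parameter sets and the test suite requires
|simulated r_eq − closed form| < 1% of r_max over hundreds of draws (in
practice agreement is at machine precision for directional change,
since the recursion is linear and the steady state exact).

**Cyclic change.** Slow cycles (period ≫ 1/(γV)) reduce to the
directional result. Fast cycles leave no time for evolutionary
tracking; averaging the plastic mismatch over a cycle gives
r̄_eq = r_max − (γ_f/4)·A·K_f² (female dominance) and
r̄_eq = r_max − (γ_f/8)·A·K_f² − (γ_m/8)·A·K_m² (co-dominance). The
simulator realises ε(t) = √A·sin(2πt/period), so ⟨ε²⟩ = A/2 and the
amplitude parameter A enters the load exactly as in the closed forms.
"Fast relative to evolution" is taken as γ_s·V_A,s·period ≪ 1; the
randomised cross-checks draw from that regime and require agreement
within 2% of r_max.

Singularities at |r_mf| = 1 raise errors (the lags carry 1 − r_mf²
denominators). Constants independent of b_SD (e.g. any standing-variance
load) are treated as absorbed into r_max. Numeric optimisation uses a
deterministic golden-section search on b_SD ∈ [−10, 10] with tolerance
1e-8.

### Default parameterisation

The default `TheoryParams` (B = 1, b̄ = 0.5, V_A = 0.5, r_mf = 0.5,
γ = 1, r_max = 0.05, no cost, with η = 0.05) is the standard symmetric
setting used throughout the examples and sweeps; the source material
leaves γ unspecified there (it cancels from the cost-free optimum), and
γ = 1 is this package's choice. The "orange"/"blue" sweep curves apply
B_f − B_m = ±0.2 and V_A,f − V_A,m = ∓0.1 around the same means.

### Simulator defaults

5000 generations (directional), burn-in 40% of the run, convergence
flagged when the two halves of the post-burn-in window differ by more
than 1e-6·max(1, r_max); cyclic averages are taken over an integer
number of cycles. Divergence (|lag| > 1e6) aborts with diagnostics —
it indicates γV large enough that the discrete recursion is unstable
(spectral radius of ½GΓ above 2).

## Effect sizes

Hedges' d uses the pooled SD on n₁+n₂−2 df, small-sample factor
J = 1 − 3/(4df − 1), and the Borenstein large-sample variance
(n₁+n₂)/(n₁n₂) + d²/(2df). lnCVR follows Nakagawa et al.'s
definition with the 1/(2(n−1)) bias terms, and its variance assumes
independence of means and SDs within groups. Operand order: classes
where larger values are expected in the cold (development time,
longevity, size, survival) subtract warm from cold; resistance and
gene-expression classes subtract cold from warm — so positive d is
plasticity in the a-priori adaptive direction everywhere. Levels are
ordered by temperature; non-temperature manipulations (e.g. duration of
cold exposure) need an explicit `direction_override`
(`a_colder`/`b_colder`, referring to the alphabetically first level) or
the contrast is excluded. lnCVR between sexes puts the male CV in the
numerator (positive = males more variable). Exclusions — zero SD,
pooled n < 5, zero mean (lnCVR only), unorderable levels — are emitted
as reason-coded records so that attempts, effects and exclusions always
balance. |d| is *not* computed per effect; it is obtained from the
model posterior via the folded normal (below).

## Reaction-norm slopes

Per experiment and sex, level means are divided by that sex's
across-level mean and regressed on temperature with equal weight per
level (the regression is over level means, not raw replicates; a
per-replicate standardisation variant was considered and rejected as
unidentifiable from group summaries). Slopes are per °C and invariant
to rescaling either sex's trait.

## Phylogenetic correlation

Grafen branch lengths with power ρ = 1: node height = descendant tips −
1, normalised to root height 1; tip correlation = shared root-to-MRCA
path = 1 − normalised MRCA height. Polytomies are accepted; species
matching normalises underscores/case. Missing species are an error
unless explicitly allowed, in which case they attach at the root
(correlation 0). The matrix is ultrametric-PSD by construction and the
tests verify eigenvalues ≥ −1e-10.

## Multilevel meta-regression

Model: y = Xβ + Z_sp u_sp + Z_ph u_ph + Z_st u_st + Z_ex u_ex + s + e,
where X = intercept (female mean) + sex(male) deviation (+ moderator ×
sex terms, or the sampling SE for the Egger refit); u_ph ~ N(0, σ²_ph A)
with A the Grafen matrix (species and phylogeny are two separate
components sharing labels); s ~ N(0, M) is the known sampling error with
cov_ij = 0.5·√(V_i V_j) within an experiment; e has a separate variance
per sex. All conditionals are conjugate, so a blocked Gibbs sampler is
used: flat prior on β, scaled inverse-gamma(0.001, 0.001) on every
variance component, the latent s drawn per iteration from its
block-diagonal-precision conditional. Default settings are 4 chains ×
30,000 iterations, burn-in 10,000, thin 10 (overridable everywhere;
tests and the analysis drivers use reduced chains). Split R-hat and ESS
are computed with arviz; fits with any monitored R-hat above 1.1 raise
unless forced. Identical seeds give identical draws.

With `residual="none"` the per-sex residual is dropped and M becomes
the full error covariance — the classical meta-analysis special case.
This mode exists because the latent-s scheme mixes arbitrarily slowly
as the residual variance → 0, exactly the regime needed to check the
sampler against the closed-form inverse-variance-weighted posterior.

A sex-relabelling symmetry (the sex coefficient flips sign) holds in
distribution and is tested statistically; it cannot hold draw-for-draw
because the Cholesky factor used in the β update is not equivariant
under the induced design recoding.

**Folded |d|.** Per posterior draw, E|X| for
X ~ N(μ_sex, σ²) with σ² the sum of all heterogeneity components plus
the sex's residual variance (config `folded_sigma="total"`, the
default) or the residual alone; E|X| = σ√(2/π)·exp(−μ²/2σ²) +
μ(1 − 2Φ(−μ/σ)).

**I² and R².** I²_k = σ²_k/(Σ_j σ²_j + σ²_resid + σ²_typical) per draw,
with the Higgins-style typical sampling variance
Σw(k−1)/((Σw)² − Σw²), w = 1/V; components sum to I²_total by
construction. The residual component uses the sample-size-weighted mean
of the two sex-specific residual variances. R² places var(Xβ) over
var(Xβ) + all heterogeneity + σ²_typical; the conditional numerator
adds the non-residual components. Including σ²_typical in the
denominator is what makes R² and the I² columns mutually consistent in
a results table (conditional R² ≈ non-residual I² share + marginal R²).

## Synthetic data generator

Emulates the statistical structure the model assumes, for one trait
class at a time. True per-(experiment, sex) effects are
μ_class + δ·[male] + u_species + u_phylo + u_study + u_experiment +
e_sex, with u_phylo drawn on a simulated Yule tree (birth rate 1) via
the Grafen covariance. Group summaries are then *sampled* statistics —
mean ~ N(μ, σ²/n), SD² ~ σ²χ²_{n−1}/(n−1), n ~ DiscreteUniform(5, 50) —
so computed effect sizes scatter around the truth with exactly the
sampling variance the meta-analysis assumes. Defaults: 30 species × 1
study × 3 experiments × 2 levels (180 d effects), cold-resistance-style
truth (female mean d 1.76, male deviation −0.82), variance components
(0.05, 0.05, 0.10, 0.10) and per-sex residuals 0.20, baseline mean 100
with CV 0.15, temperatures drawn from {18, 22, 25, 28} °C. With more
than two levels the per-(experiment, sex) residual is shared along the
temperature gradient (only L − 1 free means exist per sex), so the
exact-per-contrast generative model holds at the default two levels.
An optional warm-level CV inflation creates lnCVR_treatment structure,
and `censor_effects` implements the |d|/SE-threshold funnel-censoring
rule for publication-bias simulations.

What passing recovery tests on these data do *not* show: robustness to
non-Gaussian effect distributions, correlated moderators, unbalanced
designs, reporting errors, or taxonomic misclassification — all present
in real compilations and all outside the generator.

## Problem sizes used in the checks

Randomised theory-simulator equivalence uses 200 parameter sets (4000
generations directional; 400 cycles fast-cyclic). Sampler coverage uses
200 synthetic replicates of 40 effects over 10 species with single
chains of 1000 iterations (burn-in 300, thin 2); the conjugate
special-case check uses 2 × 6000 iterations. The Monte-Carlo check of
the folded-normal mean uses 10⁷ draws. These sizes are the package's
own choices and scale up linearly through the respective configs.

## Known limitations

* The theory is the infinite-population, constant-G, fixed-reaction-norm
  limit: no drift, no density dependence, no evolution of plasticity
  itself, and demographic weighting only at the two extremes
  (female dominance, co-dominance).
* The fast-cycle formulas are asymptotic; outside γVP ≪ 1 the simulated
  mean growth departs from them (by design, not error).
* The Gibbs sampler assumes Gaussian effects with known sampling
  (co)variance; it is not a general GLMM engine.
* Egger-style refits flag funnel asymmetry; they do not correct it, and
  for d-type effect sizes a large true mean alone induces slope through
  the mechanical d-SE dependence (see `analysis/05_publication_bias.py`).
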