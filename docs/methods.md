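# Methods

## Model and design

One biallelic SNP with risk allele G at population frequency `maf` under
Hardy–Weinberg equilibrium (HWE): genotype priors
Pr(gg, Gg, GG) = ((1−maf)², 2·maf·(1−maf), maf²).  Disease risk is
parameterized by penetrances f₀ = Pr(case|gg), f₁ = λ₁f₀, f₂ = λ₂f₀ and
prevalence K, which fixes the baseline penetrance

    f₀ = K / [Pr(gg) + λ₁ Pr(Gg) + λ₂ Pr(GG)].

Bayes' rule gives the case genotype distribution pᵢ = Pr(i) fᵢ / K and the
control distribution qᵢ = Pr(i)(1−fᵢ)/(1−K).  λ₁ = λ₂ = 1 is the null of no
association; the recessive, additive and dominant models correspond to
λ₁ = 1 < λ₂, 2λ₁ = λ₂ + 1, and λ₁ = λ₂ > 1.

A two-stage study genotypes πr cases and πs controls in stage 1 (nearest-
integer rounding; stage 2 receives the remainder, so totals are exact) and
advances SNPs with stage-1 p < γ to stage 2.  Genotype counts per arm are
multinomial draws from (p, q); the two stages are independent samples from
the same population.  Genome-wide error is controlled at α via the
Bonferroni per-SNP level α/m.

## Stage statistics

All four statistics operate on a 2×3 genotype count table and are
asymptotically N(0,1) under the null:

* **AFDT** — Z = (θ̂−ϖ̂) / √[(1/(2n_r) + 1/(2n_s)) p̄(1−p̄)], with θ̂, ϖ̂ the
  case/control risk-allele frequencies and p̄ = ξθ̂ + (1−ξ)ϖ̂ the pooled
  frequency (ξ = case fraction).  The variance pools cases and controls.
* **CATT** — the trend statistic with genotype scores x, standardized by
  the pooled-sample score variance; affine-invariant in the scores.
  Score sets (0,0,1) / (0,1,2) / (0,1,1) target the recessive / additive /
  dominant models.
* **MERT** — (T_R + T_D)/√(2(1+ρ̂_RD)).  ρ_RD is the null correlation of
  the recessive and dominant trend tests, a pure function of the genotype
  distribution: ρ_xy = Cov_g(x,y)/√(Var_g(x)Var_g(y)).  The package
  estimates ρ̂_RD **from the case sample** by default (`rho_from="cases"`,
  with `"pooled"` and `"controls"` available).  Under the null all three
  estimates are consistent and the choice is immaterial; under the
  alternative they differ, and the case-based convention is the one whose
  analytic power reproduces the published reference values (confirmed by
  direct simulation of both statistic variants; the pooled variant has
  higher power under recessive alternatives but does not match the
  reference numbers).
* **MAX3** — max(|T_R|, |T_A|, |T_D|).  Its null law follows from the
  bivariate normality of (T_R, T_D) and the exact identity
  T_A = ω₁T_R + ω₂T_D with ω₁ = (ρ_RA − ρ_RDρ_AD)/(1−ρ_RD²) (and
  symmetrically ω₂), which holds on any table when all three statistics
  share the pooled variance estimates.  Algebraically ω₁ = σ_R/σ_A,
  ω₂ = σ_D/σ_A (ratios of null SDs of the unstandardized score sums), and
  Var(ω₁T_R + ω₂T_D) = 1.

Monomorphic or zero-variance tables raise `DegenerateTableError` rather
than returning NaN, so pipelines can skip such SNPs deliberately.  A
warning is emitted when any expected cell count is below 5 (asymptotics
get rough).  No continuity correction is applied anywhere.

## Joint analysis and thresholds

The joint statistic is T_J = √π T₁ + √(1−π) T₂ for each method's stage
statistics; for MAX3 the combination is **component-wise**:
T_Jmax = max(|√π T₁c + √(1−π) T₂c|) over c ∈ {R, A, D} — not a function of
the two stage maxima.

Under the null, (T₁, T_J) is standard bivariate normal with correlation
√π, so for the normal-based methods the joint threshold b_J solves

    Pr(|T₁| > b₁, |T_J| > b_J) = α/m,    b₁ = Φ⁻¹(1 − γ/2).

The rectangle probability is computed as a sum of four orthant
probabilities, each a 1-D integral ∫ φ(x)Φ̄((b−ρx)/√(1−ρ²))dx evaluated
with adaptive quadrature at relative tolerance 1e-13.  Because the
integrand is positive there is no cancellation, so the tail value (1e-7
scale) is accurate in relative terms — subtracting CDFs would lose all
precision there.  The root is bracketed and solved by Brent's method
(xtol 1e-14); the residual of the defining equation is below 1e-12·(α/m).
Note the direction of the γ-dependence: a *smaller* γ makes stage-1
selection harder and **lowers** b_J; as γ → 1 the threshold rises to the
unconditional Bonferroni quantile Φ⁻¹(1 − α/(2m)).

**MAX3 stage-1 threshold v₁** solves Pr(T₁max > v₁) = γ.  The acceptance
region {|T_R| ≤ t, |T_D| ≤ t, |ω₁T_R + ω₂T_D| ≤ t} is a hexagon in the
(T_R, T_D) plane; its probability is a 1-D integral of the conditional
normal CDF over T_R ∈ [−t, t], with the integrand's kinks (where the T_A
slab crosses |T_D| = t) passed to the quadrature as break points.

**MAX3 joint threshold v_J** is Monte Carlo: draw B₁ stage-1 pairs
(T_R, T_D) *conditioned on* T₁max > v₁, pair each with an independent
stage-2 draw from the null bivariate normal, form T_Jmax, and take v_J
from the simulated values such that the exceedance fraction among selected
replicates is ≤ α/(mγ) and closest to it (the sorted value at index
⌊B₁·α/(mγ)⌋; ties resolve to the smallest admissible value, the most
powerful admissible threshold).  `mc_meta` records B₁, the target and the
attained fraction.

*Conditional sampling.*  Naive rejection needs ≈ 1/γ proposals per
accepted draw (10⁴ at γ = 10⁻⁴), so the selection event is sampled
exactly as a union of three slabs {|L_i| > v₁}, L₁ = T_R,
L₂ = ω₁T_R + ω₂T_D, L₃ = T_D, each with unit variance: choose a slab
uniformly, draw L_i from the two-sided truncated normal via inverse-CDF,
draw the orthogonal component from the exact conditional normal
N(Σaᵢℓ, Σ − (Σaᵢ)(Σaᵢ)'), and accept with probability 1/#{slabs
containing the point}.  The acceptance step cancels the multiple counting
of the overlap regions, so accepted draws follow the conditional law
exactly; the test-suite verifies this against naive rejection with
two-sample Kolmogorov–Smirnov tests.

## Moments under the alternative

Power for the normal-based methods needs the mean and variance of each
stage statistic at a fixed alternative (p ≠ q).

* **AFDT** uses the closed forms
  μ = (θ−ϖ)/√[(1/(2n_r)+1/(2n_s)) p̄(1−p̄)] and
  δ = [(1−ξ)θ(1−θ) + ξϖ(1−ϖ)]/[p̄(1−p̄)]
  with population allele frequencies.  δ is the binomial-allele variance of
  θ̂−ϖ̂ relative to the null variance; under alternatives whose *case
  genotype* distribution departs from HWE (recessive models especially)
  the true genotype-multinomial variance of the plug-in statistic is a few
  percent larger.  The closed forms are retained because they are the
  reference formulation whose power values this package reproduces; the
  tests validate δ against a binomial-allele simulation oracle and μ
  against the full genotype-multinomial simulation.
* **CATT and MERT** use a *full delta method over the six cell
  frequencies*: the statistic is treated as a smooth function
  T(p̂, q̂), its gradient is taken numerically (central differences,
  h = 1e-6), and the variance is g'Σg with the multinomial covariances
  (diag(w) − ww')/n per arm.  This includes the variability of the pooled
  variance denominator and (for MERT) of ρ̂ — both matter at fixed
  alternatives: e.g. at the strongest recessive configuration the simple
  numerator-only variance is 1.00 while the full delta value 0.94 matches
  the simulated variance of the statistic.  Simulation oracles in the
  test-suite confirm mean and variance to Monte-Carlo precision.

The joint pair (T₁, T_J) under H₁ is then bivariate normal with mean
(μ₁, √π μ₁ + √(1−π) μ₂) and covariance Γ diag(δ₁, δ₂) Γ',
Γ = [[1, 0], [√π, √(1−π)]], and analytic power is the rectangle
probability over the double-exceedance region — deterministic, sub-second
per cell.  At the null it reduces to α/m exactly.

**MAX3J power** is empirical: n_rep (default 10,000) two-stage multinomial
datasets under the alternative; power = #{T₁max > v₁ and T_Jmax > v_J}/n_rep.
Threshold estimation and power estimation use separate seeded streams so
the two Monte-Carlo error sources remain separable; the reported standard
error is the binomial part, and `mc_meta` carries the threshold part.  The
default B₁ = 2·10⁶ conditional draws puts ≈ 2000 exceedances at the
GWAS-scale conditional level α/(mγ) = 10⁻³, keeping v_J noise well below
the power tolerance; B₁ = 10⁶–10⁷ brackets the accuracy/runtime trade-off.

## Real-data analysis

`analyze_snp` computes, per method: stage statistics, the joint statistic,
the stage-1 p-value and selection flag, and two p-values whose distinction
the literature often leaves implicit:

* *marginal* — the tail probability of T_J alone (normal two-sided; for
  MAX3 the hexagon tail with correlations mixed across stages in
  proportion π : 1−π);
* *selection-adjusted* — Pr₀(stage-1 statistic beyond its γ-threshold AND
  |T_J| beyond the observed value), the quantity the threshold equations
  control (bivariate integral for normal methods; conditional Monte Carlo
  for MAX3).

Stage weights: by default the *design* π (0.5 when no design is attached —
equal weighting, the convention of the reference analyses).  Any fixed
weights give a valid N(0,1) combination under the null, so this is a power
choice, not a validity one.  `pi="observed"` instead uses the per-SNP
genotyped stage-1 fraction, which tracks the information split when
missingness makes the design π inexact; note that for MAX3 the two
conventions can rank SNPs differently when the best-supported genetic
model differs between stages.  MAX3 correlations for observed tables come
from each stage's pooled genotype counts.

Count tables are exchanged as TSV (`snp_id`, then r0_1 … s2_2, stage 1
then stage 2, genotype order gg/Gg/GG with G the risk allele; `--flip`
reverses tables oriented the other way).

## Synthetic data and what the tests show

The simulator emulates exactly the sampling process of the power study:
independent multinomial genotype counts per arm and stage, an HWE source
population, and a penetrance model tied to prevalence.  It does **not**
emulate linkage disequilibrium between SNPs (SNPs are independent, as the
Bonferroni accounting assumes), covariates or population stratification,
genotyping error, or missingness; passing tests therefore certify the
statistical machinery under the stated model, not robustness of the tests
to those real-data complications.

The family-wise error-rate validation runs the full pipeline on a
scaled-down genome: m′ = 200 null SNPs, γ = 0.05, α = 0.05, 10⁴ genome
replicates, r = s = 8000, MAF 0.3.  The per-SNP sample size is chosen so
the asymptotic tails are accurate at the b_J ≈ 4.06 threshold this design
implies (at 1000 subjects per arm and stage the multinomial discreteness
leaves the trend tests visibly conservative at that depth); the expected
FWER is 1 − (1 − α/m′)^m′ = 0.0488.

## Numerical conventions

* One integer master seed per entry point; per-replicate and per-purpose
  streams are derived with `numpy.random.SeedSequence.spawn`, so runs are
  reproducible and parallel-safe.
* Stage sizes: nearest-integer rounding of πr, πs; stage 2 takes the
  remainder.
* MAF > 0.5 is allowed with a warning (the formulas do not require the
  risk allele to be minor).
* Degenerate inputs (monomorphic tables, zero score variance, ρ_RD = ±1,
  α/(mγ) ≥ 1, B₁ too small for the target tail) raise errors or warnings
  with actionable messages rather than propagating NaN.

## Known limitations

* The reference power values for the trend-based joint tests carry a small
  systematic excess (≈ +0.005 … +0.01) over both this package's analytic
  values and direct simulation of the statistics; one published additive
  cell (0.900) slightly exceeds the largest power attainable by the
  statistic under that configuration (the stage-1 selection probability
  caps it at 0.8995, simulated truth 0.894).  The analytic cells here
  agree with the published ones to ≤ 1.2% relative and with simulated
  truth to ±0.002.
* The published real-data p-values follow a convention that could not be
  fully reconstructed; the package reports explicitly labelled marginal
  and selection-adjusted p-values instead and reproduces the published
  *ranking* of the two example SNPs under every method.
* All tests are asymptotic; no exact/permutation variants are provided.
* The MAX3 joint p-value mixes stage correlations linearly in π : 1−π,
  which is exact when the two stages share genotype frequencies and an
  approximation otherwise.
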