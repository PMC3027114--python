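# robustjoint

Robust joint analysis for **two-stage case-control genetic association
studies** (GWAS).  In a two-stage design, all *m* SNPs are genotyped on a
fraction π of the subjects (stage 1); SNPs with stage-1 p-value below γ are
genotyped on the remaining subjects (stage 2).  The joint analysis combines
the two stage statistics,

```
T_J = √π · T₁ + √(1−π) · T₂ ,
```

which is more efficient than treating stage 2 as a stand-alone replication.
Because the true genetic inheritance model (recessive / additive /
dominant) of a susceptibility locus is usually unknown, this package
provides joint analyses for four single-marker tests with different
robustness profiles:

| method | stage statistic | character |
|---|---|---|
| ALLEJ | allele-frequency-difference test (pooled-variance standardized) | powerful near additive, needs HWE |
| CATAJ | Cochran–Armitage trend test, scores (0, 1, 2) | optimal under the additive model |
| MERTJ | maximin efficiency robust test (T_R + T_D)/√(2(1+ρ_RD)) | maximin compromise across models |
| MAX3J | max(\|T_R\|, \|T_A\|, \|T_D\|) | robust to model misspecification |

For each method the package computes

* **exact significance thresholds**: the stage-1 gate b₁ = Φ⁻¹(1−γ/2) and
  the joint threshold b_J solving Pr₀(|T₁|>b₁, |T_J|>b_J) = α/m under the
  null bivariate normal with Corr(T₁, T_J) = √π (tail-safe 1-D quadrature,
  no library CDF subtraction);
* **MAX3 thresholds**: v₁ from a 2-D Gaussian integral over the hexagonal
  acceptance region in the (T_R, T_D) plane, and v_J by Monte Carlo with an
  exact union-of-slabs conditional sampler (no 10⁹-draw naive rejection
  needed at GWAS-scale γ);
* **power**: closed-form bivariate-normal power for ALLEJ/CATAJ/MERTJ
  (delta-method moments under the alternative) and seeded empirical power
  for MAX3J (10,000 multinomial replicates by default);
* **real-data analysis**: per-SNP statistics, marginal and
  selection-adjusted p-values, and significance flags from two-stage
  genotype count tables (TSV);
* a seeded **multinomial simulator** of two-stage genotype counts under a
  prevalence/relative-risk disease model with HWE in the source population.

## Worked example

Power of the four joint analyses for a recessive locus (risk-allele
frequency 0.15, genotype relative risks λ₁ = 1, λ₂ = 2, prevalence 0.1)
with 5000 cases and 5000 controls, half genotyped in stage 1, stage-1 gate
γ = 10⁻⁴, genome-wide α = 0.05 over m = 500,000 SNPs:

```
$ robustjoint power --maf 0.15 --lambda1 1 --lambda2 2 -r 5000 -s 5000 \
      --pi 0.5 --gamma 1e-4 --seed 1
allej: 0.0696
cataj: 0.0570
mertj: 0.3817
max3j: 0.7545 (se 0.0043)
```

The allele-frequency and additive-trend joint tests are nearly blind to
this recessive signal (7% and 6% power); the robust MERT joint test reaches
38%, and MAX3 76% — the motivation for using a robust statistic when the
inheritance model is uncertain.  The thresholds behind those numbers:

```
$ robustjoint thresholds --method allej --pi 0.5 --gamma 1e-4
b1 = 3.890592
bJ = 5.176698
$ robustjoint thresholds --method max3j --pi 0.5 --gamma 1e-4 --maf 0.15 \
      -B 1000000 --seed 1
v1 = 4.103353
vJ = 5.333377
```

`b1` is the two-sided stage-1 selection threshold; a SNP is declared
genome-wide significant when it passes stage 1 **and** its joint statistic
exceeds `bJ` (resp. `v1`/`vJ` for MAX3).  Other subcommands: `simulate`
(two-stage count tables under a disease model), `analyze` (p-values for
observed count tables, one SNP per TSV row), `power-table` (full
model × π × γ power grids), `fwer` (family-wise error-rate simulation of
the whole pipeline).  Every stochastic command is reproducible from
`--seed`, and each output TSV carries a JSON sidecar echoing the
configuration.

The same machinery as a library:

```python
from robustjoint import (DiseaseModel, StudyDesign, PowerScenario,
                         analytic_power_joint, empirical_power_max3j)

model = DiseaseModel(prevalence=0.1, maf=0.15, lambda1=1.0, lambda2=2.0)
design = StudyDesign(r=5000, s=5000, pi=0.5, gamma=1e-4, alpha=0.05, m=500_000)
scenario = PowerScenario(model, design, seed=1)
analytic_power_joint("mertj", scenario).power   # 0.3817
empirical_power_max3j(scenario).power           # ~0.754
```

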