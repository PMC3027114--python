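"""Disease models, genotype distributions and two-stage data simulation.

A biallelic SNP with alleles g and G (G the risk allele) has genotypes
(gg, Gg, GG).  Under Hardy-Weinberg equilibrium with risk-allele frequency
``maf`` the population genotype priors are ((1-maf)^2, 2 maf (1-maf), maf^2).
The disease model is parameterized by prevalence K and genotype relative
risks lambda1 = f1/f0 and lambda2 = f2/f0, where f_i is the penetrance of
genotype i.  The baseline penetrance f0 follows from prevalence:

    f0 = K / [Pr(gg) + lambda1 Pr(Gg) + lambda2 Pr(GG)]

and Bayes' rule gives the case and control genotype distributions

    p_i = Pr(genotype i | case)    = Pr(i) f_i / K
    q_i = Pr(genotype i | control) = Pr(i) (1 - f_i) / (1 - K).

A two-stage design genotypes a fraction ``pi`` of the r cases and s controls
in stage 1; SNPs with stage-1 p-value below ``gamma`` advance to stage 2 on
the remaining subjects.  Genotype counts per arm are multinomial draws from
the corresponding genotype distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiseaseModel",
    "GenotypePopulation",
    "StudyDesign",
    "GenotypeTable",
    "TwoStageData",
    "baseline_penetrance",
    "genotype_distribution",
    "allele_frequencies",
    "simulate_table",
    "simulate_two_stage",
]


class PenetranceError(ValueError):
    """Raised when the implied penetrance of a genotype exceeds 1."""


@dataclass(frozen=True)
class DiseaseModel:
    """Penetrance/prevalence parameterization of one biallelic SNP.

    Parameters
    ----------
    prevalence : float
        Disease prevalence K, in (0, 1).
    maf : float
        Risk-allele (G) frequency in the source population, in (0, 1).
    lambda1, lambda2 : float
        Genotype relative risks f1/f0 and f2/f0.  ``lambda1 = lambda2 = 1``
        encodes the null of no association; the alternative requires
        ``lambda2 >= lambda1 >= 1`` with ``lambda2 > 1``.
    model_label : str
        Free text; conventional values are ``recessive`` (lambda1 = 1),
        ``additive`` (2 lambda1 = lambda2 + 1), ``dominant``
        (lambda1 = lambda2) and ``custom``.
    """

    prevalence: float
    maf: float
    lambda1: float = 1.0
    lambda2: float = 1.0
    model_label: str = "custom"

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError(f"prevalence must be in (0,1), got {self.prevalence}")
        if not 0.0 < self.maf < 1.0:
            raise ValueError(f"maf must be in (0,1), got {self.maf}")
        if self.maf > 0.5:
            warnings.warn(
                f"maf={self.maf} > 0.5: the risk allele is not the minor allele; "
                "formulas remain valid",
                stacklevel=2,
            )
        if min(self.lambda1, self.lambda2) < 0:
            raise ValueError("relative risks must be non-negative")
        # guard: implied f2 must not exceed 1 (checked again in baseline_penetrance)
        baseline_penetrance(self)

    @property
    def is_null(self) -> bool:
        return self.lambda1 == 1.0 and self.lambda2 == 1.0

    def genotype_priors(self) -> np.ndarray:
        """HWE genotype probabilities (gg, Gg, GG) in the source population."""
        f = self.maf
        return np.array([(1.0 - f) ** 2, 2.0 * f * (1.0 - f), f * f])

    @classmethod
    def recessive(cls, prevalence: float, maf: float, lambda2: float) -> "DiseaseModel":
        return cls(prevalence, maf, 1.0, lambda2, "recessive")

    @classmethod
    def additive(cls, prevalence: float, maf: float, lambda1: float, lambda2: float) -> "DiseaseModel":
        return cls(prevalence, maf, lambda1, lambda2, "additive")

    @classmethod
    def dominant(cls, prevalence: float, maf: float, lam: float) -> "DiseaseModel":
        return cls(prevalence, maf, lam, lam, "dominant")


def baseline_penetrance(model: DiseaseModel) -> float:
    """Baseline penetrance f0 = Pr(case | gg) implied by prevalence.

    Raises
    ------
    PenetranceError
        If ``lambda2 * f0 > 1`` (the GG penetrance would exceed 1).
    """
    priors = model.genotype_priors()
    lam = np.array([1.0, model.lambda1, model.lambda2])
    f0 = model.prevalence / float(priors @ lam)
    if max(model.lambda1, model.lambda2) * f0 > 1.0:
        raise PenetranceError(
            f"penetrance exceeds 1: f0={f0:.6g}, lambda2*f0="
            f"{model.lambda2 * f0:.6g}"
        )
    return f0


@dataclass(frozen=True)
class GenotypePopulation:
    """Case and control genotype probability triples over (gg, Gg, GG)."""

    case_probs: tuple[float, float, float]
    control_probs: tuple[float, float, float]

    def __post_init__(self) -> None:
        for name, triple in (("case", self.case_probs), ("control", self.control_probs)):
            arr = np.asarray(triple, dtype=float)
            if arr.shape != (3,):
                raise ValueError(f"{name}_probs must have 3 entries")
            if (arr < 0).any():
                raise ValueError(f"{name}_probs must be non-negative")
            if abs(arr.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name}_probs must sum to 1, got {arr.sum()!r}")

    @property
    def p(self) -> np.ndarray:
        return np.asarray(self.case_probs, dtype=float)

    @property
    def q(self) -> np.ndarray:
        return np.asarray(self.control_probs, dtype=float)


def genotype_distribution(model: DiseaseModel) -> GenotypePopulation:
    """Case/control genotype distributions implied by the disease model."""
    priors = model.genotype_priors()
    f0 = baseline_penetrance(model)
    f = f0 * np.array([1.0, model.lambda1, model.lambda2])
    p = priors * f / model.prevalence
    q = priors * (1.0 - f) / (1.0 - model.prevalence)
    # guard against rounding drift before the dataclass validates
    p = p / p.sum()
    q = q / q.sum()
    return GenotypePopulation(tuple(p), tuple(q))


def allele_frequencies(pop: GenotypePopulation) -> tuple[float, float]:
    """Risk-allele frequencies (theta, varpi) in cases and controls."""
    p, q = pop.p, pop.q
    return float(p[2] + p[1] / 2.0), float(q[2] + q[1] / 2.0)


@dataclass(frozen=True)
class StudyDesign:
    """Two-stage design parameters.

    Parameters
    ----------
    r, s : int
        Total numbers of cases and controls.
    pi : float
        Fraction of subjects genotyped in stage 1, in (0, 1].
    gamma : float
        Stage-1 selection p-value threshold.
    alpha : float
        Genome-wide type-I error, controlled at alpha/m per SNP (Bonferroni).
    m : int
        Number of SNPs genotyped in stage 1.
    """

    r: int
    s: int
    pi: float = 0.5
    gamma: float = 1e-4
    alpha: float = 0.05
    m: int = 500_000

    def __post_init__(self) -> None:
        if self.r <= 0 or self.s <= 0:
            raise ValueError("r and s must be positive")
        if not 0.0 < self.pi <= 1.0:
            raise ValueError(f"pi must be in (0,1], got {self.pi}")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma must be in (0,1), got {self.gamma}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    @property
    def xi(self) -> float:
        """Case fraction r / (r + s)."""
        return self.r / (self.r + self.s)

    def stage_sizes(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """((cases1, controls1), (cases2, controls2)).

        Stage-1 sizes are pi*r and pi*s rounded to nearest integer; stage 2
        receives the remainder so totals are exactly (r, s).
        """
        r1 = int(round(self.pi * self.r))
        s1 = int(round(self.pi * self.s))
        return (r1, s1), (self.r - r1, self.s - s1)


@dataclass(frozen=True)
class GenotypeTable:
    """Observed 2x3 genotype counts for one stage (rows: cases, controls)."""

    case_counts: tuple[int, int, int]
    control_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        for name, row in (("case", self.case_counts), ("control", self.control_counts)):
            arr = np.asarray(row)
            if arr.shape != (3,):
                raise ValueError(f"{name}_counts must have 3 entries")
            if (arr < 0).any():
                raise ValueError(f"{name}_counts must be non-negative")
            if not np.issubdtype(arr.dtype, np.integer):
                if not np.allclose(arr, np.round(arr)):
                    raise ValueError(f"{name}_counts must be integers")
        if self.n_cases == 0 and self.n_controls == 0:
            raise ValueError("table has no subjects")

    @property
    def cases(self) -> np.ndarray:
        return np.asarray(self.case_counts, dtype=float)

    @property
    def controls(self) -> np.ndarray:
        return np.asarray(self.control_counts, dtype=float)

    @property
    def n_cases(self) -> int:
        return int(sum(self.case_counts))

    @property
    def n_controls(self) -> int:
        return int(sum(self.control_counts))

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    def pooled_frequencies(self) -> np.ndarray:
        """Genotype relative frequencies of the combined case+control sample."""
        return (self.cases + self.controls) / self.n_total

    def flipped(self) -> "GenotypeTable":
        """Reverse the genotype order (use when the risk allele is listed first)."""
        return GenotypeTable(self.case_counts[::-1], self.control_counts[::-1])


@dataclass(frozen=True)
class TwoStageData:
    """Genotype count tables for both stages of one SNP."""

    stage1: GenotypeTable
    stage2: GenotypeTable | None
    design: StudyDesign | None = None
    snp_id: str = ""

    @property
    def pi_observed(self) -> float:
        """Stage-1 fraction recomputed from genotyped totals.

        Real tables can have missing genotypes, so the effective stage-1
        fraction may differ from the design value.
        """
        n1 = self.stage1.n_total
        n2 = self.stage2.n_total if self.stage2 is not None else 0
        return n1 / (n1 + n2)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_table(
    pop: GenotypePopulation, n_cases: int, n_controls: int, seed=None
) -> GenotypeTable:
    """Draw one multinomial genotype count table.

    Case counts ~ Multinomial(n_cases, p), control counts ~
    Multinomial(n_controls, q), independently.
    """
    if n_cases < 0 or n_controls < 0:
        raise ValueError("sample sizes must be non-negative")
    rng = _rng(seed)
    cases = rng.multinomial(n_cases, pop.p) if n_cases else np.zeros(3, dtype=int)
    controls = rng.multinomial(n_controls, pop.q) if n_controls else np.zeros(3, dtype=int)
    return GenotypeTable(tuple(int(c) for c in cases), tuple(int(c) for c in controls))


def simulate_two_stage(
    model: DiseaseModel, design: StudyDesign, seed=None
) -> TwoStageData:
    """Simulate two independent stage tables from the same population.

    Both stages draw from the genotype distribution implied by ``model``;
    stage sizes follow ``design.stage_sizes()``.  With ``pi == 1`` the
    stage-2 table is empty (``None``).
    """
    pop = genotype_distribution(model)
    (r1, s1), (r2, s2) = design.stage_sizes()
    if r1 < 1 or s1 < 1:
        raise ValueError("stage-1 sizes must be >= 1 after rounding")
    rng = _rng(seed)
    stage1 = simulate_table(pop, r1, s1, rng)
    stage2 = simulate_table(pop, r2, s2, rng) if (r2 or s2) else None
    return TwoStageData(stage1, stage2, design)
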