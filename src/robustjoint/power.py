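"""Power and type-I-error computation for the four joint analyses.

For the normal-based methods (ALLEJ, CATAJ, MERTJ) the power at a fixed
alternative is the exact rectangle probability of the shifted bivariate
normal of (T_1, T_J):

    Pr_H1(|T_1| > b_1, |T_J| > b_J),
    mean (mu_1, sqrt(pi) mu_1 + sqrt(1-pi) mu_2),
    cov  Gamma diag(delta_1, delta_2) Gamma',  Gamma = [[1, 0],
                                                        [sqrt(pi), sqrt(1-pi)]]

with stage moments (mu_k, delta_k) from the module :mod:`robustjoint.stats`.
MAX3 power is estimated empirically: simulate two-stage multinomial data
under the alternative and count replicates exceeding both Monte-Carlo
thresholds (v_1, v_J).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .joint import (
    METHODS,
    JointThresholds,
    bivariate_rect_prob,
    joint_threshold_normal,
    max3_joint_threshold,
    max3_stage1_threshold,
)
from .models import DiseaseModel, StudyDesign, genotype_distribution
from .stats import (
    ADD,
    DOM,
    REC,
    AltMoments,
    NullCorrelations,
    afdt_alt_moments,
    afdt_bulk,
    catt_alt_moments,
    catt_bulk,
    mert_alt_moments,
    mert_bulk,
)

__all__ = [
    "PowerScenario",
    "PowerResult",
    "analytic_power_joint",
    "empirical_power",
    "empirical_power_max3j",
    "empirical_fwer",
    "reproduce_table",
    "TABLE_GRIDS",
]


@dataclass(frozen=True)
class PowerScenario:
    """One disease model + study design + Monte-Carlo configuration."""

    model: DiseaseModel
    design: StudyDesign
    n_rep: int = 10_000
    B1: int = 2_000_000
    seed: int | None = None


@dataclass(frozen=True)
class PowerResult:
    method: str
    power: float
    se: float
    thresholds: JointThresholds
    meta: dict = field(default_factory=dict)


def _stage_moments(
    method: str, model: DiseaseModel, design: StudyDesign, rho_from: str
) -> tuple[AltMoments, AltMoments]:
    pop = genotype_distribution(model)
    (r1, s1), (r2, s2) = design.stage_sizes()
    xi = design.xi
    if method == "allej":
        return (
            afdt_alt_moments(pop, r1, s1, xi),
            afdt_alt_moments(pop, r2, s2, xi),
        )
    if method == "cataj":
        return (
            catt_alt_moments(pop, ADD, r1, s1),
            catt_alt_moments(pop, ADD, r2, s2),
        )
    if method == "mertj":
        return (
            mert_alt_moments(pop, r1, s1, rho_from),
            mert_alt_moments(pop, r2, s2, rho_from),
        )
    raise ValueError(f"no analytic power for method {method!r}")


def analytic_power_joint(
    method: str, scenario: PowerScenario, rho_from: str = "cases"
) -> PowerResult:
    """Exact bivariate-normal joint power for ALLEJ, CATAJ or MERTJ."""
    design = scenario.design
    thr = joint_threshold_normal(design.pi, design.gamma, design.alpha, design.m, method)
    m1, m2 = _stage_moments(method, scenario.model, design, rho_from)
    pi = design.pi
    mean1 = m1.mean
    meanJ = math.sqrt(pi) * m1.mean + math.sqrt(1 - pi) * m2.mean
    var1 = m1.var
    varJ = pi * m1.var + (1 - pi) * m2.var
    cov = math.sqrt(pi) * m1.var
    corr = cov / math.sqrt(var1 * varJ)
    power = bivariate_rect_prob(
        thr.stage1, thr.joint, corr,
        mean=(mean1, meanJ), sd=(math.sqrt(var1), math.sqrt(varJ)),
    )
    return PowerResult(method, float(power), 0.0, thr, {"moments": (m1, m2)})


def _simulate_stage_stats(
    model: DiseaseModel, n_cases: int, n_controls: int, n_rep: int,
    rng: np.random.Generator, method: str, rho_from: str,
) -> np.ndarray:
    """Stage statistics for n_rep tables; for MAX3 the (n_rep, 3) trend
    components (REC, ADD, DOM), since the joint MAX3 statistic combines the
    stages component-wise before taking the maximum."""
    pop = genotype_distribution(model)
    cases = rng.multinomial(n_cases, pop.p, size=n_rep)
    controls = rng.multinomial(n_controls, pop.q, size=n_rep)
    if method == "allej":
        return afdt_bulk(cases, controls)
    if method == "cataj":
        return catt_bulk(cases, controls, ADD)
    if method == "mertj":
        return mert_bulk(cases, controls, rho_from)
    if method == "max3j":
        return np.stack(
            [catt_bulk(cases, controls, s) for s in (REC, ADD, DOM)], axis=1
        )
    raise ValueError(f"unknown method {method!r}")


def empirical_power(
    method: str,
    scenario: PowerScenario,
    thresholds: JointThresholds,
    n_rep: int | None = None,
    seed=None,
    rho_from: str = "cases",
) -> PowerResult:
    """Monte-Carlo joint power for any method given its thresholds.

    Simulates ``n_rep`` independent two-stage multinomial datasets under the
    scenario's disease model and counts the fraction with the stage-1
    statistic beyond the stage-1 threshold and the joint statistic beyond
    the joint threshold (both in absolute value for the normal-based
    methods; MAX3 is already non-negative).
    """
    n_rep = n_rep or scenario.n_rep
    if n_rep < 100:
        import warnings

        warnings.warn(f"n_rep={n_rep} is small; power estimate will be noisy", stacklevel=2)
    rng = np.random.default_rng(seed if seed is not None else scenario.seed)
    design = scenario.design
    (r1, s1), (r2, s2) = design.stage_sizes()
    t1 = _simulate_stage_stats(scenario.model, r1, s1, n_rep, rng, method, rho_from)
    t2 = _simulate_stage_stats(scenario.model, r2, s2, n_rep, rng, method, rho_from)
    pi = design.pi
    tj = math.sqrt(pi) * t1 + math.sqrt(1 - pi) * t2
    if method == "max3j":
        t1max = np.abs(t1).max(1)
        tjmax = np.abs(tj).max(1)
        hit = (t1max > thresholds.stage1) & (tjmax > thresholds.joint)
    else:
        hit = (np.abs(t1) > thresholds.stage1) & (np.abs(tj) > thresholds.joint)
    power = float(hit.mean())
    se = math.sqrt(power * (1 - power) / n_rep)
    return PowerResult(method, power, se, thresholds, {"n_rep": n_rep})


def empirical_power_max3j(
    scenario: PowerScenario,
    thresholds: JointThresholds | None = None,
    n_rep: int | None = None,
    seed=None,
) -> PowerResult:
    """MAX3 joint power with Monte-Carlo thresholds and empirical power.

    Thresholds (v_1 exact integral, v_J conditional Monte Carlo with
    ``scenario.B1`` stage-1 draws) are computed under the null at the
    model's HWE genotype frequencies unless supplied.  Power uses a fresh
    simulation stream so the two Monte-Carlo error sources stay separable;
    the reported ``se`` is the binomial half of the budget, and
    ``thresholds.mc_meta`` records the threshold half.
    """
    design = scenario.design
    base_seed = seed if seed is not None else scenario.seed
    ss = np.random.SeedSequence(base_seed)
    s_thr, s_pow = ss.spawn(2)
    if thresholds is None:
        corrs = NullCorrelations.from_frequencies(scenario.model.genotype_priors())
        thresholds = max3_joint_threshold(
            design.pi, design.gamma, design.alpha, design.m,
            corrs, corrs, B1=scenario.B1, seed=np.random.default_rng(s_thr),
        )
    return empirical_power(
        "max3j", scenario, thresholds, n_rep=n_rep, seed=np.random.default_rng(s_pow)
    )


def empirical_fwer(
    null_model: DiseaseModel,
    design: StudyDesign,
    n_genomes: int = 10_000,
    seed=None,
    methods=METHODS,
    B1: int = 2_000_000,
    batch: int = 1_000,
    rho_from: str = "cases",
) -> dict:
    """Family-wise error rate of the full two-stage pipeline on null SNPs.

    Simulates ``n_genomes`` genome replicates of ``design.m`` independent
    null SNPs, applies each method's stage-1 selection and joint threshold,
    and reports the fraction of genomes with at least one rejection,
    together with the per-SNP rejection rate.  The per-SNP level is
    alpha/m, so the expected FWER is 1 - (1 - alpha/m)^m ~= alpha.
    """
    if not null_model.is_null:
        raise ValueError("empirical_fwer expects a null disease model")
    mprime = design.m
    ss = np.random.SeedSequence(seed)
    s_thr, s_sim = ss.spawn(2)
    thr: dict[str, JointThresholds] = {}
    for method in methods:
        if method == "max3j":
            corrs = NullCorrelations.from_frequencies(null_model.genotype_priors())
            thr[method] = max3_joint_threshold(
                design.pi, design.gamma, design.alpha, mprime,
                corrs, corrs, B1=B1, seed=np.random.default_rng(s_thr),
            )
        else:
            thr[method] = joint_threshold_normal(
                design.pi, design.gamma, design.alpha, mprime, method
            )
    pop = genotype_distribution(null_model)
    (r1, s1), (r2, s2) = design.stage_sizes()
    pi = design.pi
    rng = np.random.default_rng(s_sim)
    any_hit = {method: np.zeros(0, dtype=bool) for method in methods}
    n_rej = {method: 0 for method in methods}
    done = 0
    while done < n_genomes:
        g = min(batch, n_genomes - done)
        k = g * mprime
        c1 = rng.multinomial(r1, pop.p, size=k)
        d1 = rng.multinomial(s1, pop.q, size=k)
        c2 = rng.multinomial(r2, pop.p, size=k)
        d2 = rng.multinomial(s2, pop.q, size=k)
        for method in methods:
            if method == "allej":
                t1, t2 = afdt_bulk(c1, d1), afdt_bulk(c2, d2)
            elif method == "cataj":
                t1, t2 = catt_bulk(c1, d1, ADD), catt_bulk(c2, d2, ADD)
            elif method == "mertj":
                t1, t2 = mert_bulk(c1, d1, rho_from), mert_bulk(c2, d2, rho_from)
            else:
                t1 = np.stack([catt_bulk(c1, d1, s) for s in (REC, ADD, DOM)], 1)
                t2 = np.stack([catt_bulk(c2, d2, s) for s in (REC, ADD, DOM)], 1)
            tj = math.sqrt(pi) * t1 + math.sqrt(1 - pi) * t2
            if method == "max3j":
                hit = (np.abs(t1).max(1) > thr[method].stage1) & (
                    np.abs(tj).max(1) > thr[method].joint
                )
            else:
                hit = (np.abs(t1) > thr[method].stage1) & (np.abs(tj) > thr[method].joint)
            hit = hit.reshape(g, mprime)
            any_hit[method] = np.concatenate([any_hit[method], hit.any(1)])
            n_rej[method] += int(hit.sum())
        done += g
    out = {}
    for method in methods:
        fwer = float(any_hit[method].mean())
        out[method] = {
            "fwer": fwer,
            "se": math.sqrt(fwer * (1 - fwer) / n_genomes),
            "per_snp_rate": n_rej[method] / (n_genomes * mprime),
            "thresholds": thr[method],
        }
    return out


# ---------------------------------------------------------------------------
# simulation-study grids
# ---------------------------------------------------------------------------

#: per-table (maf, {model: (lambda1, lambda2, r=s)}) for the power study;
#: prevalence 0.1, alpha 0.05, m 500,000 throughout
TABLE_GRIDS = {
    2: (0.15, {"recessive": (1.0, 2.0, 5000), "additive": (1.4, 1.8, 2000), "dominant": (1.5, 1.5, 2000)}),
    3: (0.25, {"recessive": (1.0, 1.5, 5000), "additive": (1.4, 1.8, 2000), "dominant": (1.5, 1.5, 2000)}),
    4: (0.35, {"recessive": (1.0, 1.5, 4000), "additive": (1.4, 1.8, 2000), "dominant": (1.5, 1.5, 2000)}),
    5: (0.45, {"recessive": (1.0, 1.5, 2000), "additive": (1.4, 1.8, 2000), "dominant": (1.5, 1.5, 2000)}),
}

PI_GRID = (0.5, 0.4, 0.3)
GAMMA_GRID = (1e-4, 2e-4)


def reproduce_table(
    table_id: int,
    models=("recessive", "additive", "dominant"),
    pis=PI_GRID,
    gammas=GAMMA_GRID,
    methods=METHODS,
    n_rep: int = 10_000,
    B1: int = 2_000_000,
    seed=None,
    prevalence: float = 0.1,
    alpha: float = 0.05,
    m: int = 500_000,
):
    """Power grid (model x pi x gamma x method) for one simulation table.

    Yields dict rows; analytic methods are deterministic, MAX3J rows carry a
    Monte-Carlo standard error.
    """
    if table_id not in TABLE_GRIDS:
        raise ValueError(f"table_id must be one of {sorted(TABLE_GRIDS)}")
    maf, grid = TABLE_GRIDS[table_id]
    ss = np.random.SeedSequence(seed)
    for label in models:
        l1, l2, rs = grid[label]
        model = DiseaseModel(prevalence, maf, l1, l2, label)
        for pi in pis:
            for gamma in gammas:
                design = StudyDesign(rs, rs, pi, gamma, alpha, m)
                scenario = PowerScenario(model, design, n_rep=n_rep, B1=B1)
                row = {
                    "table": table_id, "maf": maf, "model": label,
                    "lambda1": l1, "lambda2": l2, "r": rs, "s": rs,
                    "pi": pi, "gamma": gamma,
                }
                for method in methods:
                    if method == "max3j":
                        res = empirical_power_max3j(
                            scenario, seed=ss.spawn(1)[0].generate_state(1)[0] % (2**31)
                        )
                    else:
                        res = analytic_power_joint(method, scenario)
                    row[method] = res.power
                    row[f"{method}_se"] = res.se
                yield row
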