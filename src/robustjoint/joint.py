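"""Joint two-stage analysis: combined statistics, thresholds, p-values.

The joint statistic for any single-marker test T is

    T_J = sqrt(pi) T_1 + sqrt(1 - pi) T_2

with T_1, T_2 the independent stage statistics and pi the stage-1 subject
fraction.  Under the null, (T_1, T_J) is standard bivariate normal with
correlation sqrt(pi), so the per-SNP significance threshold b_J at
Bonferroni level alpha/m solves

    Pr(|T_1| > b_1, |T_J| > b_J) = alpha / m,    b_1 = Phi^-1(1 - gamma/2),

for the normal-based tests (AFDT, CATT, MERT).  MAX3 needs its own stage-1
threshold v_1 (a 2-D Gaussian integral over the hexagonal acceptance region
in the (T_R, T_D) plane) and a Monte-Carlo joint threshold v_J estimated
from replicates conditioned on stage-1 selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .models import GenotypeTable, TwoStageData
from .stats import (
    ADD,
    DOM,
    REC,
    DegenerateTableError,
    NullCorrelations,
    afdt_statistic,
    catt_statistic,
    max3_statistic,
    mert_statistic,
    omega_weights,
)

__all__ = [
    "METHODS",
    "JointThresholds",
    "JointResult",
    "joint_statistic",
    "stage1_threshold",
    "bivariate_rect_prob",
    "joint_threshold_normal",
    "max3_tail_prob",
    "max3_stage1_threshold",
    "conditional_stage1_sampler",
    "max3_joint_threshold",
    "analyze_snp",
]

#: the four joint-analysis methods
METHODS = ("allej", "cataj", "mertj", "max3j")


def joint_statistic(t1: float, t2: float, pi: float) -> float:
    """Combine stage statistics: sqrt(pi) t1 + sqrt(1-pi) t2."""
    if not 0.0 < pi <= 1.0:
        raise ValueError(f"pi must be in (0,1], got {pi}")
    return math.sqrt(pi) * t1 + math.sqrt(1.0 - pi) * t2


def stage1_threshold(gamma: float) -> float:
    """Two-sided normal selection threshold b1 = Phi^-1(1 - gamma/2)."""
    if not 0.0 < gamma <= 1.0:
        raise ValueError(f"gamma must be in (0,1], got {gamma}")
    return float(ndtri(1.0 - gamma / 2.0))


def _orthant_upper(a: float, b: float, rho: float) -> float:
    """Pr(X > a, Y > b) for standard bivariate normal with correlation rho.

    One-dimensional tail-safe quadrature: integrates phi(x) Phibar((b - rho
    x)/s) over (a, inf); accurate in relative terms even deep in the tails
    because the integrand is positive.
    """
    if rho >= 1.0:
        return float(ndtr(-max(a, b)))
    if rho <= -1.0:
        return float(max(0.0, ndtr(-a) - ndtr(b)))
    s = math.sqrt(1.0 - rho * rho)

    def f(x):
        return norm.pdf(x) * ndtr(-(b - rho * x) / s)

    hi = max(a + 10.0, 10.0)
    v, _ = quad(f, a, hi, epsabs=0.0, epsrel=1e-13, limit=300)
    return v


def bivariate_rect_prob(
    h1: float,
    h2: float,
    rho: float,
    mean: tuple[float, float] = (0.0, 0.0),
    sd: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Pr(|X| > h1, |Y| > h2) for a bivariate normal.

    ``mean``/``sd`` shift and scale the marginals; ``rho`` is the
    correlation.  Computed as a sum of four orthant probabilities, avoiding
    catastrophic cancellation in the far tails.
    """
    m1, m2 = mean
    s1, s2 = sd
    a_hi, a_lo = (h1 - m1) / s1, (-h1 - m1) / s1
    b_hi, b_lo = (h2 - m2) / s2, (-h2 - m2) / s2
    return (
        _orthant_upper(a_hi, b_hi, rho)
        + _orthant_upper(-a_lo, -b_lo, rho)
        + _orthant_upper(a_hi, -b_lo, -rho)
        + _orthant_upper(-a_lo, b_hi, -rho)
    )


@dataclass(frozen=True)
class JointThresholds:
    """Stage-1 and joint significance thresholds for one method."""

    method: str
    stage1: float
    joint: float
    pi: float
    gamma: float
    alpha: float
    m: int
    mc_meta: dict = field(default_factory=dict)


def joint_threshold_normal(
    pi: float, gamma: float, alpha: float, m: int, method: str = "allej"
) -> JointThresholds:
    """Exact joint threshold for the normal-based methods.

    Solves Pr(|Z1| > b1, |ZJ| > bJ) = alpha/m under the null bivariate
    normal with Corr(Z1, ZJ) = sqrt(pi).  Shared by AFDT, CATT and MERT
    joint analyses (identical null joint distribution).
    """
    if not 0.0 < pi <= 1.0:
        raise ValueError(f"pi must be in (0,1], got {pi}")
    level = alpha / m
    if level >= gamma:
        raise ValueError(
            f"alpha/m = {level:g} must be below gamma = {gamma:g}: the joint "
            "rejection is a sub-event of stage-1 selection"
        )
    b1 = stage1_threshold(gamma)
    rho = math.sqrt(pi)

    def resid(b):
        return bivariate_rect_prob(b1, b, rho) - level

    lo, hi = 0.5 * stage1_threshold(level), 10.0
    tries = 0
    while resid(hi) > 0:
        hi += 5.0
        tries += 1
        if tries > 5:
            raise RuntimeError("could not bracket the joint threshold")
    while resid(lo) < 0:
        lo *= 0.5
        if lo < 1e-8:
            raise RuntimeError("could not bracket the joint threshold from below")
    bj = brentq(resid, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return JointThresholds(method, b1, float(bj), pi, gamma, alpha, m)


# ---------------------------------------------------------------------------
# MAX3: tail probability, thresholds, conditional sampling
# ---------------------------------------------------------------------------

def max3_tail_prob(t: float, corrs: NullCorrelations) -> float:
    """Pr(max(|T_R|, |T_A|, |T_D|) > t) under the null.

    (T_R, T_D) is standard bivariate normal with correlation rho_RD and
    T_A = omega1 T_R + omega2 T_D, so the acceptance event is a hexagon in
    the (T_R, T_D) plane; its probability is a one-dimensional integral of
    the conditional normal CDF.
    """
    if t <= 0:
        return 1.0
    w1, w2 = omega_weights(corrs)
    rho = corrs.rho_rd
    s = math.sqrt(1.0 - rho * rho)

    def f(u):
        lo = max(-t, (-t - w1 * u) / w2)
        hi = min(t, (t - w1 * u) / w2)
        if hi <= lo:
            return 0.0
        return norm.pdf(u) * (ndtr((hi - rho * u) / s) - ndtr((lo - rho * u) / s))

    # integrand kinks where the T_A slab boundary crosses |T_D| = t
    pts = sorted(
        x for x in (t * (1 - w2) / w1, -t * (1 - w2) / w1) if -t < x < t
    )
    inside, _ = quad(f, -t, t, points=pts or None, epsabs=1e-13, epsrel=1e-11, limit=400)
    return 1.0 - inside


def max3_stage1_threshold(gamma: float, corrs: NullCorrelations) -> float:
    """Stage-1 threshold v1 solving Pr(T1max > v1) = gamma."""
    if not 0.0 < gamma < 1.0:
        raise ValueError(f"gamma must be in (0,1), got {gamma}")
    return float(
        brentq(lambda t: max3_tail_prob(t, corrs) - gamma, 1e-6, 10.0, xtol=1e-10)
    )


def _slab_matrix(corrs: NullCorrelations) -> tuple[np.ndarray, np.ndarray]:
    """Coefficient rows a_i with L_i = a_i . (T_R, T_D) for (R, A, D)."""
    w1, w2 = omega_weights(corrs)
    A = np.array([[1.0, 0.0], [w1, w2], [0.0, 1.0]])
    S = np.array([[1.0, corrs.rho_rd], [corrs.rho_rd, 1.0]])
    return A, S


def conditional_stage1_sampler(
    v1: float,
    corrs: NullCorrelations,
    n_draws: int,
    seed=None,
    batch_factor: float = 1.8,
) -> np.ndarray:
    """Exact draws of (T_R, T_D) given max(|T_R|, |T_A|, |T_D|) > v1.

    The selection region is the union of three slabs {|L_i| > v1} for linear
    functionals L_i of the bivariate normal (each with unit variance, by the
    omega identity).  A slab is chosen uniformly (equal marginal
    probabilities), L_i is drawn from the two-sided truncated normal, the
    orthogonal component from the exact conditional normal, and the draw is
    accepted with probability 1/#{slabs containing it}.  This reproduces the
    conditional law exactly; naive rejection is retained in the test-suite
    as the oracle.

    Returns an array of shape (n_draws, 2).
    """
    if v1 <= 0:
        raise ValueError("v1 must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    A, S = _slab_matrix(corrs)
    # conditional covariance given L_i = ell: S - (S a_i)(S a_i)' (Var L_i = 1)
    roots = []
    for i in range(3):
        Ci = S - np.outer(S @ A[i], A[i] @ S)
        w, V = np.linalg.eigh(Ci)
        roots.append(V * np.sqrt(np.clip(w, 0.0, None)))
    tail = float(ndtr(-v1))
    out = np.empty((0, 2))
    while out.shape[0] < n_draws:
        k = int((n_draws - out.shape[0]) * batch_factor) + 16
        slab = rng.integers(0, 3, size=k)
        sign = rng.choice([-1.0, 1.0], size=k)
        ell = sign * ndtri(1.0 - rng.random(k) * tail)
        z = rng.standard_normal((k, 2))
        draws = np.empty((k, 2))
        for i in range(3):
            idx = slab == i
            if idx.any():
                draws[idx] = (S @ A[i]) * ell[idx, None] + z[idx] @ roots[i].T
        ncover = (np.abs(draws @ A.T) > v1).sum(1)
        accept = (ncover > 0) & (rng.random(k) < 1.0 / np.maximum(ncover, 1))
        out = np.vstack([out, draws[accept]])
    return out[:n_draws]


def max3_joint_threshold(
    pi: float,
    gamma: float,
    alpha: float,
    m: int,
    rho1: NullCorrelations,
    rho2: NullCorrelations | None = None,
    B1: int = 2_000_000,
    seed=None,
    v1: float | None = None,
) -> JointThresholds:
    """Monte-Carlo joint threshold v_J for the MAX3 joint analysis.

    Simulates B1 stage-1 replicates conditioned on T1max > v1 (the
    conditional sampler replaces naive rejection exactly), pairs each with
    an independent stage-2 replicate, forms T_Jmax, and picks v_J from the
    simulated values so that the conditional exceedance fraction is <=
    alpha/(m gamma) and closest to it; ties resolve to the smallest value.
    """
    if rho2 is None:
        rho2 = rho1
    level = alpha / (m * gamma)
    if level >= 1.0:
        raise ValueError(
            f"alpha/(m*gamma) = {level:g} >= 1: joint threshold undefined "
            "(every selected SNP would be declared significant)"
        )
    if B1 * level < 100:
        import warnings

        warnings.warn(
            f"B1={B1} gives only ~{B1 * level:.0f} expected exceedances at "
            f"level {level:g}; increase B1 for a stable threshold",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if v1 is None:
        v1 = max3_stage1_threshold(gamma, rho1)
    t1 = conditional_stage1_sampler(v1, rho1, B1, rng)
    A1, _ = _slab_matrix(rho1)
    A2, S2 = _slab_matrix(rho2)
    t2 = rng.standard_normal((B1, 2)) @ np.linalg.cholesky(S2).T
    tj = math.sqrt(pi) * (t1 @ A1.T) + math.sqrt(1.0 - pi) * (t2 @ A2.T)
    tjmax = np.abs(tj).max(1)
    vals = np.sort(tjmax)[::-1]
    k = int(math.floor(level * B1))  # admissible number strictly above v_J
    if k >= B1:
        raise RuntimeError("level too large for B1")
    vj = float(vals[k])
    # ties: several equal values attain the same admissible fraction; the
    # sort already returns the smallest such value at index k
    attained = float((tjmax > vj).sum()) / B1
    meta = {"B1": B1, "target_fraction": level, "attained_fraction": attained, "v1": v1}
    return JointThresholds("max3j", float(v1), vj, pi, gamma, alpha, m, meta)


# ---------------------------------------------------------------------------
# per-SNP analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JointResult:
    """Per-method two-stage result for one SNP."""

    method: str
    t1: float
    t2: float
    t_joint: float
    pi: float
    p_stage1: float
    selected: bool
    p_marginal: float
    p_selection_adjusted: float
    significant: bool | None = None


def _stage_statistic(method: str, table: GenotypeTable, rho_from: str) -> float:
    if method == "allej":
        return afdt_statistic(table)
    if method == "cataj":
        return catt_statistic(table, ADD)
    if method == "mertj":
        return mert_statistic(table, rho_from=rho_from)
    if method == "max3j":
        return max3_statistic(table)
    raise ValueError(f"unknown method {method!r}")


def analyze_snp(
    data: TwoStageData,
    gamma: float,
    alpha: float,
    m: int,
    methods=METHODS,
    rho_from: str = "cases",
    mc_B1: int = 200_000,
    seed=None,
    pi: float | str | None = None,
) -> dict[str, JointResult]:
    """Run the joint analyses on one SNP's two-stage count tables.

    For each method, reports the stage statistics, the joint statistic and
    two p-values.  ``pi`` sets the stage weights sqrt(pi), sqrt(1-pi):

    * ``None`` (default) -- the design value if ``data.design`` is present,
      else 0.5 (equal weighting).  Any fixed weights give a valid N(0, 1)
      joint statistic under the null; equal weighting is the convention of
      the original two-stage analyses this package reproduces.
    * ``"observed"`` -- the per-SNP genotyped stage-1 fraction
      (``data.pi_observed``), which tracks the information split when
      missingness makes the design fraction inexact.
    * a float in (0, 1] -- used as given.

    The two p-values:

    * ``p_marginal`` -- the tail probability of the joint statistic alone,
      ignoring stage-1 selection;
    * ``p_selection_adjusted`` -- Pr_H0(stage-1 statistic beyond its
      gamma-threshold AND |T_J| beyond the observed value), the joint tail
      used by the threshold equations.

    A SNP whose stage-1 p-value is >= gamma is flagged unselected; its joint
    p-values are still reported but carry no significance claim.  The
    significance flag compares the selection-adjusted p-value to alpha/m.

    MAX3 correlations are estimated from each stage's pooled genotype
    counts; its selection-adjusted p-value uses conditional Monte Carlo with
    ``mc_B1`` stage-1 draws.
    """
    if data.stage2 is None:
        raise ValueError("two-stage analysis requires a stage-2 table")
    if pi is None:
        pi = data.design.pi if data.design is not None else 0.5
    elif pi == "observed":
        pi = data.pi_observed
    elif not (isinstance(pi, (int, float)) and 0.0 < pi <= 1.0):
        raise ValueError(f"pi must be None, 'observed' or a fraction, got {pi!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    results: dict[str, JointResult] = {}
    for method in methods:
        if method == "max3j":
            # MAX3 combines stages component-wise: TJmax is the maximum of
            # the three joint trend statistics, not a function of the two
            # stage maxima
            comp1 = [catt_statistic(data.stage1, s) for s in (REC, ADD, DOM)]
            comp2 = [catt_statistic(data.stage2, s) for s in (REC, ADD, DOM)]
            t1 = max(abs(c) for c in comp1)
            t2 = max(abs(c) for c in comp2)
            tj = max(
                abs(joint_statistic(c1, c2, pi)) for c1, c2 in zip(comp1, comp2)
            )
        else:
            t1 = _stage_statistic(method, data.stage1, rho_from)
            t2 = _stage_statistic(method, data.stage2, rho_from)
            tj = joint_statistic(t1, t2, pi)
        if method == "max3j":
            rho1 = NullCorrelations.from_frequencies(data.stage1.pooled_frequencies())
            rho2 = NullCorrelations.from_frequencies(data.stage2.pooled_frequencies())
            p1 = max3_tail_prob(t1, rho1)
            # joint components share the stage mixture of correlations
            rho_j = NullCorrelations(
                rho_rd=pi * rho1.rho_rd + (1 - pi) * rho2.rho_rd,
                rho_ra=pi * rho1.rho_ra + (1 - pi) * rho2.rho_ra,
                rho_ad=pi * rho1.rho_ad + (1 - pi) * rho2.rho_ad,
            )
            p_marg = max3_tail_prob(tj, rho_j)
            selected = p1 < gamma
            v1 = max3_stage1_threshold(gamma, rho1)
            draws1 = conditional_stage1_sampler(v1, rho1, mc_B1, rng)
            A1, _ = _slab_matrix(rho1)
            A2, S2 = _slab_matrix(rho2)
            draws2 = rng.standard_normal((mc_B1, 2)) @ np.linalg.cholesky(S2).T
            tjmax = np.abs(
                math.sqrt(pi) * (draws1 @ A1.T) + math.sqrt(1 - pi) * (draws2 @ A2.T)
            ).max(1)
            p_adj = gamma * float((tjmax > tj).mean())
        else:
            p1 = 2.0 * float(ndtr(-abs(t1)))
            p_marg = 2.0 * float(ndtr(-abs(tj)))
            selected = p1 < gamma
            b1 = stage1_threshold(gamma)
            p_adj = bivariate_rect_prob(b1, abs(tj), math.sqrt(pi))
        results[method] = JointResult(
            method=method,
            t1=t1,
            t2=t2,
            t_joint=tj,
            pi=pi,
            p_stage1=p1,
            selected=selected,
            p_marginal=p_marg,
            p_selection_adjusted=p_adj,
            significant=bool(selected and p_adj < alpha / m),
        )
    return results
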