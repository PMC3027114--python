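"""Single-stage association statistics and their asymptotic moments.

Four statistics for one 2x3 genotype count table:

* AFDT -- allele-frequency-difference test: compares the case and control
  risk-allele frequencies, standardized by the binomial variance at the
  pooled allele frequency (cases and controls combined).
* CATT -- Cochran-Armitage trend test with genotype scores x = (x0, x1, x2);
  the score sets (0,0,1), (0,1,2) and (0,1,1) are optimal under the
  recessive, additive and dominant risk models respectively.
* MERT -- maximin efficiency robust test, the standardized sum of the
  recessive and dominant trend tests: (T_R + T_D) / sqrt(2 (1 + rho_RD)).
* MAX3 -- max(|T_R|, |T_A|, |T_D|), robust against model misspecification.

All four are asymptotically N(0, 1) under the null (MAX3 has its own null
tail, determined by the joint normality of (T_R, T_D) and the identity
T_A = omega1 T_R + omega2 T_D).

Moments under the alternative are obtained by the delta method over the six
genotype cell frequencies, treating a statistic as a smooth function of
(p_hat, q_hat).  This includes the variability of the pooled variance
denominator (and, for MERT, of the estimated correlation), which matters at
the fixed alternatives used in power calculations.  The AFDT moments use the
closed forms mu = (theta - varpi) / sqrt[(1/(2 n_r) + 1/(2 n_s)) pbar (1 -
pbar)] and delta = [(1 - xi) theta (1 - theta) + xi varpi (1 - varpi)] /
[pbar (1 - pbar)], which coincide with the numerator-only delta method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import GenotypePopulation, GenotypeTable

__all__ = [
    "ScoreSet",
    "REC",
    "ADD",
    "DOM",
    "NullCorrelations",
    "AltMoments",
    "DegenerateTableError",
    "afdt_statistic",
    "catt_statistic",
    "null_trend_correlation",
    "omega_weights",
    "mert_statistic",
    "max3_statistic",
    "afdt_alt_moments",
    "catt_alt_moments",
    "mert_alt_moments",
]


class DegenerateTableError(ValueError):
    """Raised when a statistic is undefined (zero variance / monomorphic)."""


@dataclass(frozen=True)
class ScoreSet:
    """Genotype scores (x0, x1, x2) for the trend test."""

    scores: tuple[float, float, float]
    name: str = ""

    def __post_init__(self) -> None:
        if len(set(self.scores)) == 1:
            raise ValueError("scores must not all be equal")

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.scores, dtype=float)


REC = ScoreSet((0.0, 0.0, 1.0), "recessive")
ADD = ScoreSet((0.0, 1.0, 2.0), "additive")
DOM = ScoreSet((0.0, 1.0, 1.0), "dominant")

#: sources for estimating the null genotype distribution behind rho_RD
_RHO_SOURCES = ("cases", "pooled", "controls")


def _moments(g: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    m = float(g @ x)
    return m, float(g @ (x * x)) - m * m


def _cov(g: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    return float(g @ (x * y)) - float(g @ x) * float(g @ y)


def null_trend_correlation(
    genotype_freqs, scores_x: ScoreSet, scores_y: ScoreSet
) -> float:
    """Null correlation of two trend statistics sharing one genotype table.

    rho = Cov_g(x, y) / sqrt(Var_g(x) Var_g(y)) with moments over the
    genotype distribution g.  The standardized statistics share the same
    multinomial noise, so rho does not depend on the case fraction.
    """
    g = np.asarray(genotype_freqs, dtype=float)
    if g.shape != (3,):
        raise ValueError("genotype_freqs must have 3 entries")
    if abs(g.sum() - 1.0) > 1e-9:
        raise ValueError("genotype_freqs must sum to 1")
    x, y = scores_x.x, scores_y.x
    _, vx = _moments(g, x)
    _, vy = _moments(g, y)
    if vx <= 0 or vy <= 0:
        raise DegenerateTableError("zero score variance under these frequencies")
    return _cov(g, x, y) / np.sqrt(vx * vy)


@dataclass(frozen=True)
class NullCorrelations:
    """Pairwise null correlations of the three trend tests.

    ``omega`` weights satisfy T_A = omega1 T_R + omega2 T_D whenever all
    three statistics are standardized with the same pooled genotype
    frequency estimates.
    """

    rho_rd: float
    rho_ra: float
    rho_ad: float

    def __post_init__(self) -> None:
        for r in (self.rho_rd, self.rho_ra, self.rho_ad):
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation out of (-1,1): {r}")

    @classmethod
    def from_frequencies(cls, genotype_freqs) -> "NullCorrelations":
        return cls(
            rho_rd=null_trend_correlation(genotype_freqs, REC, DOM),
            rho_ra=null_trend_correlation(genotype_freqs, REC, ADD),
            rho_ad=null_trend_correlation(genotype_freqs, ADD, DOM),
        )


def omega_weights(corrs: NullCorrelations) -> tuple[float, float]:
    """Coefficients (omega1, omega2) with T_A = omega1 T_R + omega2 T_D.

    omega1 = (rho_RA - rho_RD rho_AD) / (1 - rho_RD^2) and symmetrically for
    omega2; algebraically omega1 = sigma_R / sigma_A and omega2 = sigma_D /
    sigma_A, the ratios of null standard deviations of the unstandardized
    score sums.
    """
    d = 1.0 - corrs.rho_rd**2
    if d <= 0:
        raise DegenerateTableError("rho_RD = +/-1")
    w1 = (corrs.rho_ra - corrs.rho_rd * corrs.rho_ad) / d
    w2 = (corrs.rho_ad - corrs.rho_rd * corrs.rho_ra) / d
    return w1, w2


# ---------------------------------------------------------------------------
# statistics as smooth functions of the six cell frequencies
# ---------------------------------------------------------------------------

def _afdt_from_freqs(p: np.ndarray, q: np.ndarray, nr: float, ns: float) -> float:
    theta = p[2] + p[1] / 2.0
    varpi = q[2] + q[1] / 2.0
    xi = nr / (nr + ns)
    pbar = theta * xi + varpi * (1.0 - xi)
    denom = (1.0 / (2.0 * nr) + 1.0 / (2.0 * ns)) * pbar * (1.0 - pbar)
    return (theta - varpi) / np.sqrt(denom)


def _catt_from_freqs(
    p: np.ndarray, q: np.ndarray, nr: float, ns: float, x: np.ndarray
) -> float:
    N = nr + ns
    xi = nr / N
    g = xi * p + (1.0 - xi) * q
    mg = g @ x
    vg = g @ (x * x) - mg * mg
    return np.sqrt(nr * ns / N) * float(p @ x - q @ x) / np.sqrt(vg)


def _mert_from_freqs(
    p: np.ndarray, q: np.ndarray, nr: float, ns: float, rho_from: str
) -> float:
    tR = _catt_from_freqs(p, q, nr, ns, REC.x)
    tD = _catt_from_freqs(p, q, nr, ns, DOM.x)
    if rho_from == "cases":
        g = p
    elif rho_from == "controls":
        g = q
    else:  # pooled
        xi = nr / (nr + ns)
        g = xi * p + (1.0 - xi) * q
    g = g / g.sum()
    _, vR = _moments(g, REC.x)
    _, vD = _moments(g, DOM.x)
    rho = _cov(g, REC.x, DOM.x) / np.sqrt(vR * vD)
    return (tR + tD) / np.sqrt(2.0 * (1.0 + rho))


# ---------------------------------------------------------------------------
# table statistics
# ---------------------------------------------------------------------------

def _check_counts(table: GenotypeTable) -> None:
    if table.n_cases == 0 or table.n_controls == 0:
        raise DegenerateTableError("need at least one case and one control")
    expected = np.outer(
        [table.n_cases, table.n_controls], table.pooled_frequencies()
    )
    nonzero = table.pooled_frequencies() > 0
    if (expected[:, nonzero] < 5).any():
        warnings.warn(
            "expected cell count below 5; asymptotic p-values may be inaccurate",
            stacklevel=3,
        )


def afdt_statistic(table: GenotypeTable) -> float:
    """Allele-frequency-difference statistic Z for one stage.

    Z = (theta_hat - varpi_hat) / sqrt[(1/(2 n_r) + 1/(2 n_s)) pbar (1-pbar)]
    with pbar the pooled risk-allele frequency estimate; asymptotically
    N(0, 1) under the null.
    """
    _check_counts(table)
    p = table.cases / table.n_cases
    q = table.controls / table.n_controls
    theta = p[2] + p[1] / 2
    varpi = q[2] + q[1] / 2
    xi = table.n_cases / table.n_total
    pbar = theta * xi + varpi * (1 - xi)
    if not 0.0 < pbar < 1.0:
        raise DegenerateTableError("pooled sample is monomorphic")
    return float(_afdt_from_freqs(p, q, table.n_cases, table.n_controls))


def catt_statistic(table: GenotypeTable, scores: ScoreSet = ADD) -> float:
    """Cochran-Armitage trend statistic; N(0, 1) under the null.

    Invariant under affine transformations of the scores.
    """
    _check_counts(table)
    g = table.pooled_frequencies()
    _, vg = _moments(g, scores.x)
    if vg <= 0:
        raise DegenerateTableError("zero pooled score variance")
    p = table.cases / table.n_cases
    q = table.controls / table.n_controls
    return float(_catt_from_freqs(p, q, table.n_cases, table.n_controls, scores.x))


def mert_statistic(table: GenotypeTable, rho_from: str = "cases") -> float:
    """Maximin efficiency robust statistic (T_R + T_D)/sqrt(2 (1 + rho_RD)).

    ``rho_from`` selects the sample used to estimate the null correlation
    rho_RD: ``"cases"`` (default), ``"pooled"`` or ``"controls"``.  Under the
    null all three are consistent; they differ under the alternative.
    """
    if rho_from not in _RHO_SOURCES:
        raise ValueError(f"rho_from must be one of {_RHO_SOURCES}")
    _check_counts(table)
    g = table.pooled_frequencies()
    for s in (REC, DOM):
        if _moments(g, s.x)[1] <= 0:
            raise DegenerateTableError("zero pooled score variance")
    p = table.cases / table.n_cases
    q = table.controls / table.n_controls
    return float(_mert_from_freqs(p, q, table.n_cases, table.n_controls, rho_from))


def max3_statistic(table: GenotypeTable) -> float:
    """MAX3 statistic max(|T_R|, |T_A|, |T_D|)."""
    return max(
        abs(catt_statistic(table, REC)),
        abs(catt_statistic(table, ADD)),
        abs(catt_statistic(table, DOM)),
    )


# ---------------------------------------------------------------------------
# vectorized kernels for simulation pipelines (counts arrays of shape (n, 3))
# ---------------------------------------------------------------------------

def catt_bulk(cases: np.ndarray, controls: np.ndarray, scores: ScoreSet = ADD) -> np.ndarray:
    """Trend statistics for a batch of tables; rows with zero variance -> nan."""
    x = scores.x
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    nr = cases.sum(1)
    ns = controls.sum(1)
    N = nr + ns
    n = cases + controls
    num = (x * (ns[:, None] * cases - nr[:, None] * controls)).sum(1)
    var = nr * ns * (N * (x * x * n).sum(1) - ((x * n).sum(1)) ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.sqrt(N) * num / np.sqrt(var)


def afdt_bulk(cases: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """Allele-frequency-difference statistics for a batch of tables."""
    half = np.array([0.0, 0.5, 1.0])
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    nr = cases.sum(1)
    ns = controls.sum(1)
    theta = (cases * half).sum(1) / nr
    varpi = (controls * half).sum(1) / ns
    xi = nr / (nr + ns)
    pbar = theta * xi + varpi * (1 - xi)
    with np.errstate(invalid="ignore", divide="ignore"):
        return (theta - varpi) / np.sqrt(
            (1 / (2 * nr) + 1 / (2 * ns)) * pbar * (1 - pbar)
        )


def mert_bulk(
    cases: np.ndarray, controls: np.ndarray, rho_from: str = "cases"
) -> np.ndarray:
    """MERT statistics for a batch of tables."""
    if rho_from not in _RHO_SOURCES:
        raise ValueError(f"rho_from must be one of {_RHO_SOURCES}")
    tR = catt_bulk(cases, controls, REC)
    tD = catt_bulk(cases, controls, DOM)
    w = {"cases": cases, "controls": controls, "pooled": cases + controls}[rho_from]
    w = np.asarray(w, dtype=float)
    g = w / w.sum(1, keepdims=True)
    mR = (g * REC.x).sum(1)
    vR = (g * REC.x * REC.x).sum(1) - mR**2
    mD = (g * DOM.x).sum(1)
    vD = (g * DOM.x * DOM.x).sum(1) - mD**2
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = ((g * REC.x * DOM.x).sum(1) - mR * mD) / np.sqrt(vR * vD)
        return (tR + tD) / np.sqrt(2 * (1 + rho))


def max3_bulk(cases: np.ndarray, controls: np.ndarray) -> np.ndarray:
    """MAX3 statistics for a batch of tables."""
    return np.max(
        np.abs(
            np.stack([catt_bulk(cases, controls, s) for s in (REC, ADD, DOM)], 1)
        ),
        axis=1,
    )


# ---------------------------------------------------------------------------
# moments under the alternative
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AltMoments:
    """Asymptotic mean and variance of a standardized statistic under H1."""

    mean: float
    var: float

    def __post_init__(self) -> None:
        if not self.var > 0:
            raise ValueError("variance must be positive")


def _delta_moments(fun, p: np.ndarray, q: np.ndarray, nr: float, ns: float) -> AltMoments:
    """Delta-method moments of fun(p_hat, q_hat) under multinomial sampling.

    The gradient is taken numerically (central differences) with respect to
    all six cell frequencies; the multinomial covariance (diag(w) - w w')/n
    projects out the off-simplex direction automatically.
    """
    h = 1e-6
    mean = fun(p, q, nr, ns)
    gp = np.zeros(3)
    gq = np.zeros(3)
    for i in range(3):
        e = np.zeros(3)
        e[i] = h
        gp[i] = (fun(p + e, q, nr, ns) - fun(p - e, q, nr, ns)) / (2 * h)
        gq[i] = (fun(p, q + e, nr, ns) - fun(p, q - e, nr, ns)) / (2 * h)
    Sp = (np.diag(p) - np.outer(p, p)) / nr
    Sq = (np.diag(q) - np.outer(q, q)) / ns
    var = float(gp @ Sp @ gp + gq @ Sq @ gq)
    return AltMoments(mean=float(mean), var=var)


def afdt_alt_moments(
    pop: GenotypePopulation, n_cases: float, n_controls: float, xi: float | None = None
) -> AltMoments:
    """Mean and variance of the AFDT stage statistic under the alternative.

    Closed forms with population allele frequencies theta (cases) and varpi
    (controls):

        mu    = (theta - varpi) / sqrt[(1/(2 n_r) + 1/(2 n_s)) pbar (1-pbar)]
        delta = [(1-xi) theta (1-theta) + xi varpi (1-varpi)] / [pbar (1-pbar)]

    where pbar = xi theta + (1-xi) varpi and xi defaults to the stage case
    fraction n_r / (n_r + n_s).
    """
    p, q = pop.p, pop.q
    theta = p[2] + p[1] / 2
    varpi = q[2] + q[1] / 2
    if not (0.0 < theta < 1.0 and 0.0 < varpi < 1.0):
        raise DegenerateTableError("degenerate population allele frequencies")
    if xi is None:
        xi = n_cases / (n_cases + n_controls)
    pbar = theta * xi + varpi * (1 - xi)
    denom = pbar * (1 - pbar)
    mean = (theta - varpi) / np.sqrt((1 / (2 * n_cases) + 1 / (2 * n_controls)) * denom)
    var = ((1 - xi) * theta * (1 - theta) + xi * varpi * (1 - varpi)) / denom
    return AltMoments(mean=float(mean), var=float(var))


def catt_alt_moments(
    pop: GenotypePopulation, scores: ScoreSet, n_cases: float, n_controls: float
) -> AltMoments:
    """Delta-method moments of the trend statistic under the alternative."""
    g = (n_cases * pop.p + n_controls * pop.q) / (n_cases + n_controls)
    for w, who in ((pop.p, "case"), (pop.q, "control"), (g, "pooled")):
        if _moments(w, scores.x)[1] <= 0:
            raise DegenerateTableError(f"zero score variance in {who} distribution")
    return _delta_moments(
        lambda p, q, nr, ns: _catt_from_freqs(p, q, nr, ns, scores.x),
        pop.p, pop.q, n_cases, n_controls,
    )


def mert_alt_moments(
    pop: GenotypePopulation,
    n_cases: float,
    n_controls: float,
    rho_from: str = "cases",
) -> AltMoments:
    """Delta-method moments of the MERT statistic under the alternative."""
    if rho_from not in _RHO_SOURCES:
        raise ValueError(f"rho_from must be one of {_RHO_SOURCES}")
    for s in (REC, DOM):
        catt_alt_moments(pop, s, n_cases, n_controls)  # raises if degenerate
    return _delta_moments(
        lambda p, q, nr, ns: _mert_from_freqs(p, q, nr, ns, rho_from),
        pop.p, pop.q, n_cases, n_controls,
    )
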