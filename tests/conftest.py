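import numpy as np
import pytest

from robustjoint import (
    DiseaseModel,
    GenotypeTable,
    NullCorrelations,
    StudyDesign,
    TwoStageData,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def null_model():
    return DiseaseModel(0.1, 0.3)


@pytest.fixture
def recessive_model():
    # the strongest-contrast scenario of the power study
    return DiseaseModel(0.1, 0.15, 1.0, 2.0, "recessive")


@pytest.fixture
def additive_model():
    return DiseaseModel(0.1, 0.15, 1.4, 1.8, "additive")


@pytest.fixture
def design():
    return StudyDesign(5000, 5000, pi=0.5, gamma=1e-4, alpha=0.05, m=500_000)


# Published two-stage genotype counts for two type-2-diabetes SNPs
# (gg, Gg, GG orientation as printed; stage 1 then stage 2).
TABLE6_COUNTS = {
    "rs1005316": (((13, 224, 457), (44, 211, 399)), ((89, 669, 1708), (89, 913, 1856))),
    "rs2876711": (((99, 322, 272), (121, 351, 182)), ((389, 1191, 989), (484, 1404, 987))),
}


@pytest.fixture
def table6_records():
    out = []
    for snp, (st1, st2) in TABLE6_COUNTS.items():
        out.append((snp, TwoStageData(GenotypeTable(*st1), GenotypeTable(*st2), snp_id=snp)))
    return out


@pytest.fixture
def table6_tsv(tmp_path, table6_records):
    from robustjoint.io import write_counts_tsv

    path = tmp_path / "table6.tsv"
    write_counts_tsv(path, table6_records)
    return path


def random_table(rng, n_min=50, n_max=400):
    """A random non-degenerate genotype table (all genotypes present pooled)."""
    while True:
        nr = int(rng.integers(n_min, n_max))
        ns = int(rng.integers(n_min, n_max))
        g = rng.dirichlet([2.0, 2.0, 2.0])
        tilt = g * rng.dirichlet([8, 8, 8])
        cases = rng.multinomial(nr, g)
        controls = rng.multinomial(ns, tilt / tilt.sum())
        pooled = cases + controls
        if (pooled > 0).all():
            return GenotypeTable(tuple(int(v) for v in cases), tuple(int(v) for v in controls))


def naive_conditional_draws(v1, corrs: NullCorrelations, n, rng):
    """Oracle sampler: naive rejection from the bivariate normal."""
    from robustjoint import omega_weights

    w1, w2 = omega_weights(corrs)
    A = np.array([[1.0, 0.0], [w1, w2], [0.0, 1.0]])
    S = np.array([[1.0, corrs.rho_rd], [corrs.rho_rd, 1.0]])
    L = np.linalg.cholesky(S)
    out = np.empty((0, 2))
    while out.shape[0] < n:
        z = rng.standard_normal((200_000, 2)) @ L.T
        keep = (np.abs(z @ A.T) > v1).any(axis=1)
        out = np.vstack([out, z[keep]])
    return out[:n]
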