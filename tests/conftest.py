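import numpy as np
import pytest

from irongc import grm as grm_mod
from irongc import simulate as sim
from irongc.genio import GenotypeMatrix


def make_genotype_matrix(dosages, snp_ids=None, sample_ids=None):
    """Wrap a raw dosage array in a GenotypeMatrix with stub metadata."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    return GenotypeMatrix(
        sample_ids=np.array(
            [f"S{i}" for i in range(n)] if sample_ids is None else sample_ids, dtype=object
        ),
        snp_ids=np.array(
            [f"snp{j}" for j in range(m)] if snp_ids is None else snp_ids, dtype=object
        ),
        dosages=dosages,
        chrom=np.array(["1"] * m, dtype=object),
        pos=np.arange(1, m + 1),
        allele_a=np.array(["A"] * m, dtype=object),
        allele_b=np.array(["B"] * m, dtype=object),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """n=200, m=300, two traits with rG=0.5 — shared across fast tests."""
    gcov = np.array([[0.5, 0.25], [0.25, 0.5]])
    cfg = sim.SimulationConfig(
        n_samples=200,
        n_snps=300,
        n_traits=2,
        genetic_cov=gcov,
        residual_cov=0.5 * np.eye(2),
        covariate_effects={},
        add_lipids=False,
        seed=42,
    )
    gm = sim.simulate_genotypes(cfg)
    pheno, truth = sim.simulate_phenotypes(gm, cfg)
    return cfg, gm, pheno, truth


@pytest.fixture(scope="session")
def small_eig(small_cohort):
    _, gm, _, _ = small_cohort
    return grm_mod.eigendecompose(grm_mod.compute_grm(gm))
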