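import numpy as np
import pytest

from meqtlseq import simulate as sim


@pytest.fixture(scope="session")
def small_ref():
    """400 kb x 2 chromosomes, deterministic."""
    return sim.simulate_reference({"chr1": 400_000, "chr2": 400_000},
                                  cpg_density=0.02, n_cell_types=2, seed=101)


@pytest.fixture(scope="session")
def small_geno(small_ref):
    return sim.simulate_genotypes(small_ref, n_subjects=60, n_snps=400, seed=102)


@pytest.fixture(scope="session")
def small_cov():
    return sim.simulate_covariates(60, n_batches=3, confounding_strength=1.0,
                                   seed=103)


@pytest.fixture(scope="session")
def small_truth(small_ref, small_geno):
    return sim.plant_meqtls(small_ref, small_geno, n_cpg_snp_effects=6,
                            n_binding_effects=6, seed=104)
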