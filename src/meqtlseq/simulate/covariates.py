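"""Subject-level covariates and the latent cell-type mixture."""
from __future__ import annotations

import numpy as np
import pandas as pd

from ..datatypes import CovariateTable
from ..errors import ConfigError


def simulate_covariates(
    n_subjects: int,
    n_batches: int = 3,
    confounding_strength: float = 1.0,
    n_cell_components: int = 3,
    mixture_alpha: float = 4.0,
    seed: int = 0,
) -> CovariateTable:
    """Draw sex, batch, two continuous assay variables, four ancestry (MDS)
    dimensions, and a Dirichlet cell-type mixture.

    The mixture is the latent confounder: :func:`simulate_fragments` lets it
    load onto many regions (scaled by ``confounding_strength``) so that
    methylation principal components can capture and remove it. Ancestry
    dimensions are independent of the methylation truth.
    """
    if n_batches < 1:
        raise ConfigError("n_batches must be >= 1")
    if n_subjects < 2:
        raise ConfigError("n_subjects must be >= 2")
    rng = np.random.default_rng(seed)
    table = pd.DataFrame({
        "sex": rng.integers(0, 2, size=n_subjects),
        "batch": rng.integers(0, n_batches, size=n_subjects),
        "lab_input_ng": rng.normal(0.0, 1.0, size=n_subjects),
        "lab_enrichment": rng.normal(0.0, 1.0, size=n_subjects),
        "mds1": rng.normal(0.0, 1.0, size=n_subjects),
        "mds2": rng.normal(0.0, 1.0, size=n_subjects),
        "mds3": rng.normal(0.0, 1.0, size=n_subjects),
        "mds4": rng.normal(0.0, 1.0, size=n_subjects),
    })
    table.index = [f"S{i:04d}" for i in range(n_subjects)]
    alpha = np.full(n_cell_components, float(mixture_alpha))
    alpha[0] *= 2.0  # one dominant cell type, as in whole blood
    mixture = rng.dirichlet(alpha, size=n_subjects)
    return CovariateTable(table=table, cell_mixture=mixture,
                          confounding_strength=float(confounding_strength))
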