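"""MBD-seq fragment simulation.

Fragments are emitted only from methylated molecules: each region's expected
fragment yield is proportional to its per-subject methylation level times
its CpG count, scaled to a target per-subject depth. A fragment is anchored
on one of the region's CpGs and placed uniformly over the positions at which
it covers that CpG, with its length drawn *length-biased* (pmf ∝ l·f(l)) —
under uniform shearing, longer fragments are proportionally more likely to
cover any fixed CpG, and only then does the read-start offset distribution
at isolated CpGs reproduce the fragment-size survival function.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from ..datatypes import CovariateTable, FragmentSet, GenotypeMatrix, ReferenceModel
from ..dists import FragmentLengthDistribution
from ..errors import ConfigError
from .truth import latent_methylation


def simulate_fragments(
    ref: ReferenceModel,
    truth: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: Optional[CovariateTable] = None,
    depth: int = 100_000,
    frag_len_dist: Optional[FragmentLengthDistribution] = None,
    read_len: int = 50,
    seed: int = 0,
    confounded_frac: float = 0.3,
    loading_sd: float = 0.15,
    batch_frac: float = 0.2,
    batch_sd: float = 0.05,
    noise_sd: float = 0.05,
    background_frac: float = 0.05,
) -> FragmentSet:
    """Simulate per-subject captured fragments.

    Confounding enters as a low-rank term: a random ``confounded_frac`` of
    regions receive loadings on the latent cell-type mixture, scaled by the
    covariate table's ``confounding_strength``; batch shifts and iid noise
    are added on top, and the result is clipped to [0, 1].

    A further ``background_frac`` of the depth is emitted uniformly over the
    genome regardless of methylation — the non-specific capture noise floor
    that the background (non-CpG) coverage filter is calibrated against.
    """
    if depth <= 0:
        raise ConfigError("depth must be positive")
    dist = frag_len_dist or FragmentLengthDistribution.gamma()
    if dist.min_length < read_len:
        raise ConfigError("fragment length support must be >= read length")

    rng = np.random.default_rng(seed)
    n, R = genotypes.n_subjects, len(truth)
    m = latent_methylation(truth, genotypes)

    if covariates is not None:
        strength = covariates.confounding_strength
        mix = covariates.cell_mixture - covariates.cell_mixture.mean(axis=0)
        W = np.zeros((R, mix.shape[1]))
        hit = rng.random(R) < confounded_frac
        W[hit] = rng.normal(0.0, loading_sd, size=(int(hit.sum()), mix.shape[1]))
        m = m + strength * (mix @ W.T)
        batch = covariates.table["batch"].to_numpy()
        bhit = rng.random(R) < batch_frac
        shifts = rng.normal(0.0, batch_sd, size=(batch.max() + 1, int(bhit.sum())))
        m[:, bhit] = m[:, bhit] + shifts[batch]
    if noise_sd > 0:
        m = m + rng.normal(0.0, noise_sd, size=m.shape)
    m = np.clip(m, 0.0, 1.0)

    lam = m * truth["n_cpgs"].to_numpy()[None, :]
    row = lam.sum(axis=1, keepdims=True)
    row[row == 0] = 1.0
    counts = rng.poisson(depth * lam / row)          # n x R

    # expand to one row per fragment
    per_subject = counts.sum(axis=1)
    subject = np.repeat(np.arange(n, dtype=np.int32), per_subject)
    region = np.concatenate([np.repeat(np.arange(R), counts[i]) for i in range(n)]) \
        if counts.sum() else np.empty(0, dtype=np.int64)

    _, cpg_pos_all = ref.all_cpg_positions()
    cpg_lo = truth["cpg_lo"].to_numpy()
    n_cpgs = truth["n_cpgs"].to_numpy()
    chrom_names = ref.chrom_names
    chrom_code_of_region = np.array(
        [chrom_names.index(c) for c in truth["chrom"]], dtype=np.int16)
    lengths_by_code = np.array([ref.lengths[c] for c in chrom_names], dtype=np.int64)

    N = region.size
    cpg_idx = cpg_lo[region] + rng.integers(0, n_cpgs[region])
    anchor = cpg_pos_all[cpg_idx]
    L = dist.sample_length_biased(rng, N).astype(np.int64)
    offset = (rng.random(N) * L).astype(np.int64)        # uniform over covering placements
    strand = np.where(rng.random(N) < 0.5, 1, -1).astype(np.int8)
    start = np.where(strand > 0, anchor - offset, anchor + offset - L + 1)
    code = chrom_code_of_region[region]
    ok = (start >= 0) & (start + L <= lengths_by_code[code])
    code, start, L, strand, subject = (a[ok] for a in (code, start, L, strand, subject))

    if background_frac > 0:
        n_bg = int(rng.poisson(background_frac * depth * n))
        bsub = rng.integers(0, n, size=n_bg).astype(np.int32)
        probs = lengths_by_code / lengths_by_code.sum()
        bcode = rng.choice(len(chrom_names), size=n_bg, p=probs).astype(np.int16)
        bL = dist.sample(rng, n_bg).astype(np.int64)
        bstart = (rng.random(n_bg) * (lengths_by_code[bcode] - bL)).astype(np.int64)
        bstrand = np.where(rng.random(n_bg) < 0.5, 1, -1).astype(np.int8)
        code = np.concatenate([code, bcode])
        start = np.concatenate([start, bstart])
        L = np.concatenate([L, bL])
        strand = np.concatenate([strand, bstrand])
        subject = np.concatenate([subject, bsub])

    return FragmentSet(chrom_code=code, start=start.astype(np.int64),
                       length=L.astype(np.int32), strand=strand,
                       subject=subject, chrom_names=list(chrom_names),
                       subjects=list(genotypes.subjects), read_len=read_len)
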