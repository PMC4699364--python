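"""Genotype simulation with haplotype-block LD structure.

Each chromosome carries a pool of founder haplotypes; every subject
haplotype is a mosaic of founders whose switch probability grows with
inter-SNP distance (1 - exp(-rate * d / block_len)). Within a stretch copied
from one founder all SNPs are perfectly correlated with founder identity, so
r^2 is high at short range and decays toward zero across blocks.
"""
from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
import pandas as pd

from ..datatypes import A, C, G, T, GenotypeMatrix, ReferenceModel
from ..errors import ConfigError

_COMP_SAFE = {A: T, T: A, C: A, G: T}  # substitution that can never touch a CpG
_BASE_STR = {A: "A", C: "C", G: "G", T: "T"}


def _founder_paths(n_hap: int, pos: np.ndarray, n_founders: int,
                   block_len: float, recomb_rate: float,
                   rng: np.random.Generator) -> np.ndarray:
    """(n_hap x n_snps) founder index mosaic."""
    S = pos.size
    p_switch = np.empty(S)
    p_switch[0] = 1.0
    if S > 1:
        d = np.diff(pos).astype(float)
        p_switch[1:] = 1.0 - np.exp(-recomb_rate * d / block_len)
    switch = rng.random((n_hap, S)) < p_switch
    switch[:, 0] = True
    proposals = rng.integers(0, n_founders, size=(n_hap, S))
    # forward-fill the founder chosen at the most recent switch
    col = np.arange(S)
    last = np.where(switch, col, 0)
    last = np.maximum.accumulate(last, axis=1)
    return proposals[np.arange(n_hap)[:, None], last]


def simulate_genotypes(
    ref: ReferenceModel,
    n_subjects: int,
    n_snps: int = 1000,
    block_len: float = 20_000.0,
    maf_range: Tuple[float, float] = (0.05, 0.5),
    n_founders: int = 12,
    recomb_rate: float = 1.0,
    cpg_snp_frac: float = 0.3,
    seed: int = 0,
) -> GenotypeMatrix:
    """Simulate a dosage matrix on the reference.

    A fraction ``cpg_snp_frac`` of SNPs is placed on CpG dinucleotides with
    the alternate allele abolishing the CpG (C>T at the C, or G>A at the G);
    the rest are placed away from CpGs with alleles chosen so no CpG is
    created. ``is_cpg_snp`` is then re-derived from sequence context by the
    enrichment module rather than trusted from construction.
    """
    from ..enrichment import call_cpg_snps  # local import: no cycle at module load

    lo, hi = maf_range
    if not (0.0 < lo < hi <= 0.5):
        raise ConfigError(f"maf_range {maf_range} must satisfy 0 < lo < hi <= 0.5")
    if n_subjects < 2:
        raise ConfigError("n_subjects must be >= 2")
    if n_founders < 2:
        raise ConfigError("n_founders must be >= 2")

    rng = np.random.default_rng(seed)
    total = sum(ref.lengths.values())
    rows = []
    for chrom in ref.chrom_names:
        L = ref.lengths[chrom]
        seq = ref.sequences[chrom]
        cpg = ref.cpg_positions[chrom]
        n_here = max(2, int(round(n_snps * L / total)))
        n_cpg = int(round(cpg_snp_frac * n_here))

        # CpG-SNPs: pick planted CpGs, mutate the C or the G
        n_cpg = min(n_cpg, cpg.size)
        picks = rng.choice(cpg.size, size=n_cpg, replace=False)
        on_g = rng.random(n_cpg) < 0.5
        pos_c = cpg[picks] + on_g.astype(np.int64)
        ref_a = np.where(on_g, G, C).astype(np.uint8)
        alt_a = np.where(on_g, A, T).astype(np.uint8)
        for p, r, a in zip(pos_c, ref_a, alt_a):
            rows.append((chrom, int(p), _BASE_STR[int(r)], _BASE_STR[int(a)]))

        # non-CpG SNPs: positions not on (or adjacent to) a CpG
        forbidden = np.union1d(cpg, cpg + 1)
        n_other = n_here - n_cpg
        cand = rng.integers(1, L - 1, size=4 * n_other + 16)
        near = np.searchsorted(forbidden, cand)
        bad = np.zeros(cand.size, dtype=bool)
        for off in (0, 1):  # candidate equal to a CpG base or one left of the C
            idx = np.clip(near - 1 + off, 0, forbidden.size - 1)
            bad |= (forbidden[idx] == cand) | (forbidden[idx] == cand + 1)
        cand = cand[~bad][:n_other]
        for p in cand:
            r = int(seq[p])
            rows.append((chrom, int(p), _BASE_STR[r], _BASE_STR[_COMP_SAFE[r]]))

    snps = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    snps = (snps.drop_duplicates(["chrom", "pos"])
                .sort_values(["chrom", "pos"], kind="mergesort")
                .reset_index(drop=True))

    # founder alleles per SNP: carrier count targets a Uniform(maf_range) MAF
    dosage_cols = []
    keep_idx = []
    n_hap = 2 * n_subjects
    for chrom, grp in snps.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        S = pos.size
        target = rng.uniform(lo, hi, size=S)
        carriers = np.clip(np.round(target * n_founders).astype(int), 1, n_founders - 1)
        F = np.zeros((n_founders, S), dtype=np.int8)
        for j in range(S):
            F[rng.choice(n_founders, size=carriers[j], replace=False), j] = 1
        paths = _founder_paths(n_hap, pos, n_founders, block_len, recomb_rate, rng)
        hap_allele = F[paths, np.arange(S)]
        dosage_cols.append(hap_allele[0::2] + hap_allele[1::2])
        keep_idx.append(grp.index.to_numpy())
    dosages = np.concatenate(dosage_cols, axis=1).astype(np.float64)
    snps = snps.loc[np.concatenate(keep_idx)].reset_index(drop=True)

    # drop realized-monomorphic SNPs
    freq = dosages.mean(axis=0) / 2.0
    poly = (freq > 0) & (freq < 1)
    dosages, snps, freq = dosages[:, poly], snps.loc[poly].reset_index(drop=True), freq[poly]
    snps["maf"] = np.minimum(freq, 1.0 - freq)
    snps.insert(0, "snp", [f"snp{i:06d}" for i in range(len(snps))])

    calls = call_cpg_snps(snps, ref)
    snps["is_cpg_snp"] = calls["is_cpg_snp"].to_numpy()

    subjects = [f"S{i:04d}" for i in range(n_subjects)]
    return GenotypeMatrix(dosages=dosages, snps=snps, subjects=subjects)
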