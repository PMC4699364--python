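"""Planting meQTL effects of two mechanisms into the region truth table.

Mechanism "cpg_snp": the methylation substrate itself is polymorphic — a SNP
inside (or within 250 bp of) the region creates/abolishes a CpG, so the
methylated-fragment yield tracks the number of CpG-bearing alleles. These
are planted preferentially in heavily methylated quiescent/heterochromatic
regions, where a polymorphic CpG is simply methylated when present.

Mechanism "binding": a non-CpG variant shifts methylation by perturbing the
binding of a chromatin factor (the Sp1-style mechanism); planted in active
promoter/enhancer states.
"""
from __future__ import annotations

from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ..datatypes import GenotypeMatrix, ReferenceModel
from ..errors import ConfigError, ShortfallError
from .reference import methylation_regions

_BASELINE_BETA = {
    # heavily methylated inactive chromatin (>75% on average)
    "high": (12.0, 3.0),
    # active promoters/enhancers: mostly unmethylated
    "low": (2.0, 6.0),
    # everything else: intermediate
    "mid": (5.0, 5.0),
}
_HIGH_STATES = frozenset({"Quies", "Het"})
_LOW_STATES = frozenset({"TssA", "TssFlnk", "TssFlnkU", "TssFlnkD",
                         "EnhG1", "EnhG2", "EnhA1", "EnhA2", "EnhWk",
                         "TssBiv", "EnhBiv"})


def _default_effect_dist(rng: np.random.Generator, size: int) -> np.ndarray:
    """Per-allele methylation shift for binding effects: magnitude 0.15-0.30
    (at least ~1 SD of site-level noise at default depth), random sign
    (binding can either promote or prevent methylation)."""
    mag = rng.uniform(0.15, 0.30, size=size)
    return mag * rng.choice([-1.0, 1.0], size=size)


def _snps_near(regions: pd.DataFrame, snps: pd.DataFrame, mask: np.ndarray,
               flank: int) -> list:
    """For each region, indices of SNPs (restricted by ``mask``) within
    [start - flank, end + flank)."""
    out = [[] for _ in range(len(regions))]
    sub = snps.loc[mask]
    for chrom, grp in sub.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos)
        pos, idx = pos[order], grp.index.to_numpy()[order]
        sel = regions["chrom"] == chrom
        starts = regions.loc[sel, "start"].to_numpy() - flank
        ends = regions.loc[sel, "end"].to_numpy() + flank
        lo = np.searchsorted(pos, starts, side="left")
        hi = np.searchsorted(pos, ends, side="left")
        for r, (a, b) in zip(np.flatnonzero(sel.to_numpy()), zip(lo, hi)):
            if b > a:
                out[r] = list(idx[a:b])
    return out


def plant_meqtls(
    ref: ReferenceModel,
    genotypes: GenotypeMatrix,
    n_cpg_snp_effects: int,
    n_binding_effects: int,
    effect_size_dist: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None,
    seed: int = 0,
    regions: Optional[pd.DataFrame] = None,
    flank: int = 250,
    cpg_snp_states: Sequence[str] = ("Quies", "Het"),
    binding_states: Sequence[str] = ("TssA", "EnhA1"),
    causal_window: int = 10_000,
    min_causal_maf: float = 0.2,
    peri_bp: int = 0,
    subtel_bp: int = 0,
) -> pd.DataFrame:
    """Build the region truth table with planted effects.

    Causal SNPs are drawn from variants with MAF >= ``min_causal_maf``:
    planted effects are meant to be recoverable (at least ~1 SD of
    site-level noise), which requires enough genetic variance on the causal
    allele. Effects are planted only in the assayable genome: regions inside
    the pericentromeric (``peri_bp``) or subtelomeric (``subtel_bp``)
    exclusion zones that the coverage module will mask are ineligible.

    Returns the region frame with added columns baseline, is_meqtl,
    mechanism ("cpg_snp" | "binding" | "none"), causal_snp, effect_size
    (per-alt-allele shift in expected methylated-fragment rate).
    """
    if n_cpg_snp_effects < 0 or n_binding_effects < 0:
        raise ConfigError("effect counts must be non-negative")
    rng = np.random.default_rng(seed)
    truth = (methylation_regions(ref) if regions is None else regions).copy()
    snps = genotypes.snps

    state = truth["state"].astype(str)
    group = np.where(state.isin(_HIGH_STATES), "high",
                     np.where(state.isin(_LOW_STATES), "low", "mid"))
    baseline = np.empty(len(truth))
    for g, (a, b) in _BASELINE_BETA.items():
        m = group == g
        baseline[m] = rng.beta(a, b, size=int(m.sum()))
    truth["baseline"] = baseline
    truth["is_meqtl"] = False
    truth["mechanism"] = "none"
    truth["causal_snp"] = ""
    truth["effect_size"] = 0.0

    is_cpg_snp = snps["is_cpg_snp"].to_numpy().astype(bool)
    common = snps["maf"].to_numpy() >= min_causal_maf
    cpg_near = _snps_near(truth, snps, is_cpg_snp & common, flank)
    cpg_near_any = _snps_near(truth, snps, is_cpg_snp, flank)
    other_near = _snps_near(truth, snps, ~is_cpg_snp & common, causal_window)

    assayable = np.ones(len(truth), dtype=bool)
    if peri_bp or subtel_bp:
        for i in range(len(truth)):
            chrom = truth["chrom"].iat[i]
            L = ref.lengths[chrom]
            s, e = truth["start"].iat[i], truth["end"].iat[i]
            cs, ce = ref.centromeres[chrom]
            if (s < subtel_bp or e > L - subtel_bp or
                    (s < ce + peri_bp and e > cs - peri_bp)):
                assayable[i] = False

    # --- CpG-SNP mechanism -------------------------------------------------
    elig_cpg = [i for i in range(len(truth))
                if assayable[i] and state.iat[i] in set(cpg_snp_states)
                and cpg_near[i]]
    if len(elig_cpg) < n_cpg_snp_effects:
        raise ShortfallError(
            f"requested {n_cpg_snp_effects} cpg_snp effects but only "
            f"{len(elig_cpg)} eligible regions "
            f"(states {tuple(cpg_snp_states)} containing a CpG-SNP within {flank} bp)")
    chosen_cpg = list(rng.choice(elig_cpg, size=n_cpg_snp_effects, replace=False)) \
        if n_cpg_snp_effects else []
    for i in chosen_cpg:
        j = int(rng.choice(cpg_near[i]))
        truth.loc[truth.index[i], ["is_meqtl", "mechanism", "causal_snp"]] = \
            (True, "cpg_snp", snps["snp"].iat[j])
        # alt allele abolishes the CpG: each CpG-bearing (ref) allele
        # contributes baseline/2 of the region's methylated-fragment rate
        truth.loc[truth.index[i], "effect_size"] = -truth["baseline"].iat[i] / 2.0

    # --- binding mechanism -------------------------------------------------
    taken = set(chosen_cpg)
    bstates = list(binding_states)
    elig_bind = {s: [i for i in range(len(truth))
                     if assayable[i] and state.iat[i] == s and other_near[i]
                     and not cpg_near_any[i] and i not in taken]
                 for s in bstates}
    n_elig = sum(len(v) for v in elig_bind.values())
    if n_elig < n_binding_effects:
        raise ShortfallError(
            f"requested {n_binding_effects} binding effects but only {n_elig} "
            f"eligible regions (states {tuple(bstates)} with a nearby non-CpG-SNP "
            f"and no CpG-SNP)")
    dist = effect_size_dist or _default_effect_dist
    betas = np.asarray(dist(rng, n_binding_effects), dtype=float)
    if betas.shape != (n_binding_effects,):
        raise ConfigError("effect_size_dist must return one value per effect")
    # round-robin over binding states so each is represented
    chosen_bind = []
    k = 0
    while len(chosen_bind) < n_binding_effects:
        s = bstates[k % len(bstates)]
        k += 1
        if elig_bind[s]:
            pick = int(rng.choice(len(elig_bind[s])))
            chosen_bind.append(elig_bind[s].pop(pick))
    for i, beta in zip(chosen_bind, betas):
        j = int(rng.choice(other_near[i]))
        idx = truth.index[i]
        truth.loc[idx, ["is_meqtl", "mechanism", "causal_snp"]] = \
            (True, "binding", snps["snp"].iat[j])
        # contested methylation at an active site: mid-range baseline so the
        # allele-dependent shift has room in both directions
        truth.loc[idx, "baseline"] = rng.uniform(0.25, 0.55)
        truth.loc[idx, "effect_size"] = float(beta)

    return truth


def latent_methylation(truth: pd.DataFrame,
                       genotypes: GenotypeMatrix) -> np.ndarray:
    """Noise-free per-subject, per-region methylation implied by the truth
    table (before confounding): the simulator's latent state, exposed for
    oracle checks.
    """
    snp_col = {s: j for j, s in enumerate(genotypes.snps["snp"])}
    n, R = genotypes.n_subjects, len(truth)
    m = np.tile(truth["baseline"].to_numpy(), (n, 1))
    for r in range(R):
        if not truth["is_meqtl"].iat[r]:
            continue
        d = genotypes.dosages[:, snp_col[truth["causal_snp"].iat[r]]]
        base = truth["baseline"].iat[r]
        if truth["mechanism"].iat[r] == "cpg_snp":
            m[:, r] = base * (2.0 - d) / 2.0
        else:
            m[:, r] = np.clip(base + truth["effect_size"].iat[r] * (d - 1.0), 0.0, 1.0)
    return m
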