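"""Simulated reference genomes with planted CpG maps and chromatin states.

The simulated genome is the annotation universe for everything downstream:
CpG positions (and hence CpG-SNP contexts), centromeres for the
pericentromeric mask, per-cell-type 18-state chromatin segmentations and a
GWAS-catalog-like point track.
"""
from __future__ import annotations

from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ..datatypes import (A, C, G, T, STATE_ALPHABET, AnnotationTrack,
                         ReferenceModel)
from ..errors import ConfigError

#: Genome-wide state frequencies used unless overridden: quiescent chromatin
#: dominates, heterochromatin and weak transcription are common, promoter and
#: enhancer states are rare — the broad shape of blood-cell segmentations.
DEFAULT_STATE_FREQS: Dict[str, float] = {
    "TssA": 0.015, "TssFlnk": 0.01, "TssFlnkU": 0.005, "TssFlnkD": 0.005,
    "Tx": 0.05, "TxWk": 0.10, "EnhG1": 0.005, "EnhG2": 0.005,
    "EnhA1": 0.02, "EnhA2": 0.01, "EnhWk": 0.03, "ZNF_Rpts": 0.005,
    "Het": 0.10, "TssBiv": 0.005, "EnhBiv": 0.005, "ReprPC": 0.02,
    "ReprPCWk": 0.06, "Quies": 0.55,
}


def _plant_sequence(length: int, cpg_density: float, rng: np.random.Generator,
                    isolated_frac: float = 0.002, isolation_clearance: int = 1000):
    """Random ACGT sequence whose only CG dinucleotides are planted ones.

    Most CpGs are planted iid over 2-bp tiles (expected count
    cpg_density*length), but a small fraction is placed as deliberately
    *isolated* CpGs with ``isolation_clearance`` bp kept CpG-free on both
    sides — the CpG-desert singletons that empirical fragment-size
    estimation anchors on. Accidental CGs elsewhere are destroyed by
    replacing the G, which cannot create a new CG.
    """
    seq = np.frombuffer(b"ACGT", np.uint8)[rng.integers(0, 4, size=length)].copy()
    n_blocks = length // 2

    # isolated component on a jittered grid with enforced clearance
    n_iso = int(round(cpg_density * length * isolated_frac))
    step = length // max(1, n_iso)
    if n_iso and step < 2 * isolation_clearance + 4:
        n_iso = max(0, length // (2 * isolation_clearance + 4))
        step = length // max(1, n_iso)
    if n_iso:
        jitter = rng.integers(0, max(1, step - 2 * isolation_clearance - 2), size=n_iso)
        iso = (np.arange(n_iso) * step + isolation_clearance + jitter) & ~np.int64(1)
        iso = iso[iso + 1 < length]
    else:
        iso = np.empty(0, dtype=np.int64)

    # compensate the dense-CpG probability for the genome share cleared
    # around isolated CpGs, keeping E[total CpGs] = cpg_density * length
    cleared = min(0.9, iso.size * 2.0 * isolation_clearance / length)
    p_dense = min(1.0, 2.0 * cpg_density * (1.0 - isolated_frac) / (1.0 - cleared))
    dense = np.flatnonzero(rng.random(n_blocks) < p_dense) * 2
    if iso.size:
        # keep the clearance window around isolated CpGs CpG-free
        near = np.searchsorted(iso, dense)
        d_r = np.where(near < iso.size, iso[np.minimum(near, iso.size - 1)] - dense,
                       np.iinfo(np.int64).max)
        d_l = np.where(near > 0, dense - iso[np.maximum(near - 1, 0)],
                       np.iinfo(np.int64).max)
        dense = dense[np.minimum(np.abs(d_l), np.abs(d_r)) > isolation_clearance]
    planted = np.union1d(dense, iso)

    # destroy accidental CGs not at planted positions
    cg = np.flatnonzero((seq[:-1] == C) & (seq[1:] == G))
    mask = np.zeros(length, dtype=bool)
    mask[planted] = True
    stray = cg[~mask[cg]]
    seq[stray + 1] = np.where(rng.random(stray.size) < 0.5, A, T)
    seq[planted] = C
    seq[planted + 1] = G
    return seq, planted.astype(np.int64)


def _segment_states(length: int, freqs: np.ndarray, block_mean: float,
                    rng: np.random.Generator):
    """Contiguous state blocks with exponential lengths and iid labels."""
    n_guess = max(8, int(3 * length / block_mean))
    lens = np.maximum(1, rng.exponential(block_mean, size=n_guess).astype(np.int64))
    while lens.sum() < length:
        lens = np.concatenate([lens, np.maximum(
            1, rng.exponential(block_mean, size=n_guess).astype(np.int64))])
    starts = np.concatenate([[0], np.cumsum(lens)])
    starts = starts[starts < length]
    labels = rng.choice(len(STATE_ALPHABET), size=starts.size, p=freqs).astype(np.int8)
    return starts, labels


def simulate_reference(
    chrom_lengths: Mapping[str, int] | Sequence[int],
    cpg_density: float = 0.02,
    n_cell_types: int = 1,
    seed: int = 0,
    state_freqs: Optional[Mapping[str, float]] = None,
    state_block_mean: float = 10_000.0,
    centromere_frac: float = 0.02,
    gwas_points_per_mb: float = 50.0,
    subtelomeric_margin: int = 0,
) -> ReferenceModel:
    """Generate a deterministic synthetic reference genome.

    Parameters
    ----------
    chrom_lengths
        Mapping name -> length (bp), or a sequence of lengths which are named
        ``chr1..chrN``.
    cpg_density
        Expected CpGs per bp (human genome-wide is ~0.01; methylome studies
        oversample CpG-dense regions, so 0.02 is the default here).
    n_cell_types
        Number of independent chromatin-state segmentations to draw.
    state_block_mean
        Mean chromatin-state block length (bp).
    subtelomeric_margin
        Validation only: chromosomes must be at least twice this long.
    """
    if not isinstance(chrom_lengths, Mapping):
        chrom_lengths = {f"chr{i + 1}": int(l) for i, l in enumerate(chrom_lengths)}
    if len(chrom_lengths) == 0:
        raise ConfigError("at least one chromosome is required")
    for name, L in chrom_lengths.items():
        if L <= 0:
            raise ConfigError(f"chromosome {name} has non-positive length {L}")
        if L < 2 * subtelomeric_margin:
            raise ConfigError(
                f"chromosome {name} shorter than twice the subtelomeric margin")
    if not (0 < cpg_density <= 0.5):
        raise ConfigError("cpg_density must be in (0, 0.5]")
    if n_cell_types < 1:
        raise ConfigError("n_cell_types must be >= 1")

    freqs = dict(DEFAULT_STATE_FREQS if state_freqs is None else state_freqs)
    fvec = np.array([freqs.get(s, 0.0) for s in STATE_ALPHABET], dtype=float)
    if fvec.sum() <= 0:
        raise ConfigError("state frequencies must have positive mass")
    fvec = fvec / fvec.sum()

    rng = np.random.default_rng(seed)
    names = sorted(chrom_lengths)
    sequences, cpgs, centromeres = {}, {}, {}
    states = [dict() for _ in range(n_cell_types)]
    gwas: Dict[str, np.ndarray] = {}
    for name in names:
        L = int(chrom_lengths[name])
        seq, planted = _plant_sequence(L, cpg_density, rng)
        sequences[name] = seq
        cpgs[name] = planted
        half = max(1, int(L * centromere_frac / 2))
        centromeres[name] = (L // 2 - half, L // 2 + half)
        for ct in range(n_cell_types):
            states[ct][name] = _segment_states(L, fvec, state_block_mean, rng)
        n_pts = rng.poisson(gwas_points_per_mb * L / 1e6)
        gwas[name] = np.sort(rng.integers(0, L, size=n_pts).astype(np.int64))

    tracks = {"gwas_catalog": AnnotationTrack("gwas_catalog", "point", gwas)}
    return ReferenceModel(lengths={n: int(chrom_lengths[n]) for n in names},
                          sequences=sequences, cpg_positions=cpgs,
                          centromeres=centromeres, states=states, tracks=tracks)


def methylation_regions(ref: ReferenceModel, max_gap: int = 300,
                        max_cpgs: int = 5) -> pd.DataFrame:
    """Partition CpGs into piecewise-constant methylation regions.

    Consecutive CpGs join a region while the gap stays below ``max_gap`` and
    the region holds fewer than ``max_cpgs`` CpGs. Methylation in the
    simulator is constant within a region — the resolution of an
    enrichment-based assay is the fragment, not the single CpG.

    Returns a frame with columns region, chrom, start, end (half-open,
    spanning C of first CpG to G of last), cpg_lo/cpg_hi (global CpG index
    range, half-open), n_cpgs, state (cell-type-0 label at the midpoint).
    """
    rows = []
    offset = 0
    for chrom in ref.chrom_names:
        pos = ref.cpg_positions[chrom]
        if pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(pos) > max_gap) + 1
        runs = np.split(np.arange(pos.size), breaks)
        for run in runs:
            for i in range(0, run.size, max_cpgs):
                members = run[i:i + max_cpgs]
                start = int(pos[members[0]])
                end = int(pos[members[-1]]) + 2
                rows.append((chrom, start, end, offset + int(members[0]),
                             offset + int(members[-1]) + 1, members.size))
        offset += pos.size
    df = pd.DataFrame(rows, columns=["chrom", "start", "end",
                                     "cpg_lo", "cpg_hi", "n_cpgs"])
    mid = (df["start"] + df["end"]) // 2
    codes = np.concatenate([
        ref.state_at(c, mid[df["chrom"] == c].to_numpy())
        for c in ref.chrom_names if (df["chrom"] == c).any()
    ]) if len(df) else np.empty(0, np.int8)
    df["state"] = pd.Categorical.from_codes(codes, categories=list(STATE_ALPHABET))
    df.insert(0, "region", [f"r{i:06d}" for i in range(len(df))])
    return df
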