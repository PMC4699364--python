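"""MBD-seq methylation measures from aligned-read start positions.

The methylation measure at a CpG is the expected number of captured
fragments covering it: a fragment whose sequenced 50 bp covers the CpG
contributes a full unit; a fragment starting farther upstream contributes
the probability S(d) that it extends d bp past its 5' start. S is estimated
empirically from the pile-up of read starts around isolated CpGs, where
every nearby captured fragment must have covered the CpG itself.

Downstream reductions: adjacent highly-correlated CpG columns are collapsed
into methylation sites; sites below the 97.5th percentile of background
(non-CpG) coverage are dropped as unmethylated; pericentromeric,
subtelomeric and mappability-masked sites are flagged out.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .datatypes import CoverageMatrix, FragmentSizeModel, Reads
from .errors import ConfigError, EstimationError

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# fragment-size survival estimation
# ---------------------------------------------------------------------------

def find_isolated_cpgs(cpg_positions: np.ndarray, isolation_gap: int) -> np.ndarray:
    """CpGs (positions of the C) with no other CpG within ``isolation_gap`` bp.

    Input must be sorted ascending; the gap is measured between C positions.
    """
    pos = np.asarray(cpg_positions, dtype=np.int64)
    if pos.size and np.any(np.diff(pos) < 0):
        raise ConfigError("cpg positions must be sorted ascending")
    if pos.size == 0:
        return pos
    left = np.empty(pos.size, dtype=bool)
    right = np.empty(pos.size, dtype=bool)
    left[0] = True
    left[1:] = np.diff(pos) > isolation_gap
    right[-1] = True
    right[:-1] = np.diff(pos) > isolation_gap
    return pos[left & right]


def estimate_fragment_size_distribution(
    reads: Reads,
    isolated_cpgs: Mapping[str, np.ndarray],
    read_len: int = 50,
    d_max: int = 500,
    min_reads: int = 500,
) -> FragmentSizeModel:
    """Estimate S(d) from the read-start offset histogram at isolated CpGs.

    For a + strand read with 5' start s and an isolated CpG at p, the offset
    is d = p - s (mirrored on the - strand). The offset histogram is
    proportional to S(d) plus a flat noise floor from non-specific capture;
    the floor is estimated from wrong-side reads (5' starts *past* the CpG,
    whose implied fragments cannot cover it) and subtracted. The corrected
    histogram is normalized so the certain region d < read_len averages to 1,
    then constrained non-increasing by isotonic regression.
    """
    hist = np.zeros(d_max + 1, dtype=np.int64)
    wrong = np.zeros(d_max + 1, dtype=np.int64)
    for ci, chrom in enumerate(reads.chrom_names):
        iso = np.asarray(isolated_cpgs.get(chrom, ()), dtype=np.int64)
        if iso.size == 0:
            continue
        sel = reads.chrom_code == ci
        pos5 = reads.pos5[sel]
        strand = reads.strand[sel]
        for sgn in (1, -1):
            p = pos5[strand == sgn]
            # signal side: the CpG lies ahead of the 5' start (fragment
            # direction); wrong side: the CpG lies behind it
            for sign_of_d, h in ((sgn, hist), (-sgn, wrong)):
                if sign_of_d > 0:
                    idx = np.searchsorted(iso, p, side="left")
                    ok = idx < iso.size
                    d = iso[idx[ok]] - p[ok]
                else:
                    idx = np.searchsorted(iso, p, side="right") - 1
                    ok = idx >= 0
                    d = p[ok] - iso[idx[ok]]
                d = d[d <= d_max]
                np.add.at(h, d, 1)

    total = int(hist.sum())
    if total < min_reads:
        raise EstimationError(
            f"only {total} reads near isolated CpGs (need >= {min_reads})")
    # floor from small wrong-side offsets only: offsets beyond the isolation
    # clearance minus the maximum fragment length can carry spillover from
    # fragments anchored on the next CpG cluster, so stay close to the CpG
    floor = wrong[1:read_len].mean() if read_len > 1 else 0.0
    base = hist[:read_len].mean() - floor
    if base <= 0:
        raise EstimationError("no reads within the certain (read-length) window")
    s = (hist - floor) / base
    iso_fit = IsotonicRegression(increasing=False, y_min=0.0)
    s = iso_fit.fit_transform(np.arange(s.size), s)
    s = np.clip(s, 0.0, 1.0)
    s[:read_len] = 1.0
    return FragmentSizeModel(survival=s, read_len=read_len)


# ---------------------------------------------------------------------------
# the methylation measure
# ---------------------------------------------------------------------------

def _accumulate_measure(values: np.ndarray, targets: np.ndarray,
                        pos5: np.ndarray, strand: np.ndarray,
                        subject: np.ndarray, model: FragmentSizeModel,
                        col_offset: int, chunk: int = 2_000_000) -> None:
    """Add each read's coverage contribution to ``values`` in place.

    ``targets`` are sorted positions on one chromosome whose columns start at
    ``col_offset`` in the matrix.
    """
    d_max = model.d_max
    n_sub, n_col = values.shape
    for lo in range(0, pos5.size, chunk):
        p = pos5[lo:lo + chunk]
        st = strand[lo:lo + chunk]
        sub = subject[lo:lo + chunk]
        # window of target CpGs each read can touch, strand-aware
        left = np.where(st > 0, p, p - d_max)
        right = np.where(st > 0, p + d_max, p)
        a = np.searchsorted(targets, left, side="left")
        b = np.searchsorted(targets, right, side="right")
        counts = b - a
        if counts.sum() == 0:
            continue
        read_ix = np.repeat(np.arange(p.size), counts)
        tgt_ix = _ranges(a, counts)
        d = np.abs(targets[tgt_ix] - p[read_ix])
        w = np.where(d < model.read_len, 1.0, model.survival[np.minimum(d, d_max)])
        flat = sub[read_ix].astype(np.int64) * n_col + (col_offset + tgt_ix)
        values.ravel()[:] += np.bincount(flat, weights=w, minlength=values.size)


def _ranges(starts: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Concatenate arange(starts[i], starts[i]+counts[i]) without a loop."""
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    out = np.ones(total, dtype=np.int64)
    first = np.cumsum(counts) - counts
    nz = counts > 0
    s, f, c = starts[nz], first[nz], counts[nz]
    out[f] = np.concatenate([[s[0]], s[1:] - (s[:-1] + c[:-1] - 1)])
    return np.cumsum(out)


def compute_methylation_measure(
    reads: Reads,
    cpg_positions: Mapping[str, np.ndarray],
    model: FragmentSizeModel,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> CoverageMatrix:
    """Expected-fragment-coverage matrix (subjects x CpGs).

    A read contributes 1.0 to every CpG its sequenced part covers
    (offset d < read_len on the fragment's 5' side) and S(d) to CpGs within
    d_max farther along the implied fragment. Reads beyond chromosome bounds
    are skipped with a logged warning.
    """
    names = list(reads.chrom_names)
    chrom_codes, positions = [], []
    n_sub = reads.n_subjects
    cols_per_chrom = {}
    for ci, chrom in enumerate(names):
        t = np.asarray(cpg_positions.get(chrom, ()), dtype=np.int64)
        cols_per_chrom[chrom] = t
        chrom_codes.append(np.full(t.size, ci, dtype=np.int16))
        positions.append(t)
    chrom_code = np.concatenate(chrom_codes) if chrom_codes else np.empty(0, np.int16)
    pos_all = np.concatenate(positions) if positions else np.empty(0, np.int64)
    values = np.zeros((n_sub, pos_all.size))

    offset = 0
    for ci, chrom in enumerate(names):
        t = cols_per_chrom[chrom]
        sel = reads.chrom_code == ci
        if t.size and sel.any():
            p5 = reads.pos5[sel]
            st = reads.strand[sel]
            sub = reads.subject[sel]
            if chrom_lengths is not None:
                L = chrom_lengths[chrom]
                inb = (p5 >= 0) & (p5 < L)
                if not inb.all():
                    log.warning("%d reads beyond %s bounds skipped",
                                int((~inb).sum()), chrom)
                    p5, st, sub = p5[inb], st[inb], sub[inb]
            _accumulate_measure(values, t, p5, st, sub, model, offset)
        offset += t.size
    return CoverageMatrix(values=values, chrom_code=chrom_code, positions=pos_all,
                          chrom_names=names, subjects=list(reads.subjects))


# ---------------------------------------------------------------------------
# site reduction and filters
# ---------------------------------------------------------------------------

def collapse_adjacent_cpgs(
    cov: CoverageMatrix,
    r_min: float = 0.90,
    max_gap: int = 500,
) -> Tuple[pd.DataFrame, np.ndarray]:
    """Collapse adjacent, highly inter-correlated CpG columns into sites.

    Left-to-right agglomeration: the next CpG joins the open block iff the
    Pearson correlation between its subject vector and the block's running
    mean is >= ``r_min`` and the gap to the previous member is <= ``max_gap``.
    A zero-variance CpG column closes the block and becomes a singleton site.

    Returns (sites frame, subjects x sites matrix of member-column means).
    """
    n_sub = len(cov.subjects)
    if n_sub < 2:
        raise ConfigError("collapsing needs >= 2 subjects")
    V = cov.values
    centered = V - V.mean(axis=0)
    norms = np.sqrt((centered ** 2).sum(axis=0))

    sites: List[tuple] = []
    col_blocks: List[np.ndarray] = []

    def flush(block):
        if block:
            col_blocks.append(np.asarray(block))
            j0, j1 = block[0], block[-1]
            sites.append((int(cov.chrom_code[j0]), int(cov.positions[j0]),
                          int(cov.positions[j1]) + 2, len(block), j0, j1 + 1))

    for ci in range(len(cov.chrom_names)):
        cols = np.flatnonzero(cov.chrom_code == ci)
        block: List[int] = []
        bsum = None
        for j in cols:
            if norms[j] == 0:
                log.debug("zero-variance CpG column %d -> singleton site", j)
                flush(block)
                block, bsum = [], None
                flush([j])
                continue
            if block:
                gap = cov.positions[j] - cov.positions[block[-1]]
                mean = bsum / len(block)
                mc = mean - mean.mean()
                denom = np.sqrt((mc ** 2).sum()) * norms[j]
                r = (mc @ centered[:, j]) / denom if denom > 0 else 0.0
                if gap <= max_gap and r >= r_min:
                    block.append(j)
                    bsum = bsum + V[:, j]
                    continue
                flush(block)
            block = [j]
            bsum = V[:, j].copy()
        flush(block)

    site_matrix = np.empty((n_sub, len(sites)))
    for k, blk in enumerate(col_blocks):
        site_matrix[:, k] = V[:, blk].mean(axis=1)
    df = pd.DataFrame(sites, columns=["chrom_code", "start", "end",
                                      "n_cpgs", "cpg_lo", "cpg_hi"])
    df["chrom"] = [cov.chrom_names[c] for c in df["chrom_code"]]
    df.insert(0, "site", [f"ms{k:06d}" for k in range(len(df))])
    df["passed_background_filter"] = True
    df["masked"] = False
    return df[["site", "chrom", "chrom_code", "start", "end", "n_cpgs",
               "cpg_lo", "cpg_hi", "passed_background_filter", "masked"]], site_matrix


def sample_background_loci(
    cpg_positions: Mapping[str, np.ndarray],
    chrom_lengths: Mapping[str, int],
    non_cpg_gap: int = 400,
    n_background: int = 100_000,
    seed: int = 0,
) -> Dict[str, np.ndarray]:
    """Sample loci with no CpG within ``non_cpg_gap`` bp, per chromosome."""
    rng = np.random.default_rng(seed)
    total = sum(chrom_lengths.values())
    out: Dict[str, np.ndarray] = {}
    for chrom, L in sorted(chrom_lengths.items()):
        want = max(1, int(round(n_background * L / total)))
        cpg = np.asarray(cpg_positions.get(chrom, ()), dtype=np.int64)
        cand = rng.integers(0, L, size=min(4 * want + 64, 4 * L))
        if cpg.size:
            idx = np.searchsorted(cpg, cand)
            dist_r = np.where(idx < cpg.size, cpg[np.minimum(idx, cpg.size - 1)] - cand,
                              np.iinfo(np.int64).max)
            dist_l = np.where(idx > 0, cand - cpg[np.maximum(idx - 1, 0)],
                              np.iinfo(np.int64).max)
            ok = (np.minimum(dist_l, dist_r) >= non_cpg_gap)
            cand = cand[ok]
        out[chrom] = np.sort(np.unique(cand[:want]))
    if sum(v.size for v in out.values()) == 0:
        raise EstimationError("no background (non-CpG) loci available")
    return out


def background_filter(
    sites: pd.DataFrame,
    site_matrix: np.ndarray,
    reads: Reads,
    model: FragmentSizeModel,
    cpg_positions: Mapping[str, np.ndarray],
    chrom_lengths: Mapping[str, int],
    non_cpg_gap: int = 400,
    pct: float = 97.5,
    n_background: int = 100_000,
    seed: int = 0,
    pooled: bool = False,
) -> Tuple[pd.DataFrame, float]:
    """Flag sites at or below the background-coverage threshold.

    Background loci are positions >= ``non_cpg_gap`` bp from any CpG; the
    measure is computed there and the threshold is the ``pct``-th percentile
    (linear interpolation) of per-locus across-subject means (or of the
    pooled per-subject values when ``pooled``). Sites whose mean site value
    is strictly greater than the threshold pass.
    """
    bg = sample_background_loci(cpg_positions, chrom_lengths, non_cpg_gap,
                                n_background, seed)
    bg_cov = compute_methylation_measure(reads, bg, model)
    if bg_cov.values.size == 0:
        raise EstimationError("no background coverage could be computed")
    pool = bg_cov.values.ravel() if pooled else bg_cov.values.mean(axis=0)
    threshold = float(np.percentile(pool, pct))
    means = site_matrix.mean(axis=0)
    sites = sites.copy()
    sites["passed_background_filter"] = means > threshold
    return sites, threshold


def apply_region_masks(
    sites: pd.DataFrame,
    centromeres: Mapping[str, Tuple[int, int]],
    chrom_lengths: Mapping[str, int],
    mappability_mask: Optional[Mapping[str, Tuple[np.ndarray, np.ndarray]]] = None,
    peri: int = 5_000_000,
    subtel: int = 1_000_000,
) -> pd.DataFrame:
    """Flag sites in pericentromeric / subtelomeric / mappability-masked regions.

    A site is masked if it overlaps the centromere extended by ``peri`` bp,
    lies within ``subtel`` bp of either chromosome end, or intersects any
    mappability-mask interval (the mask is consumed as an input, never
    computed here).
    """
    sites = sites.copy()
    masked = np.zeros(len(sites), dtype=bool)
    for chrom, grp in sites.groupby("chrom", sort=False):
        L = chrom_lengths[chrom]
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        m = (s < subtel) | (e > L - subtel)
        if chrom in centromeres:
            cs, ce = centromeres[chrom]
            m |= (s < ce + peri) & (e > cs - peri)
        if mappability_mask and chrom in mappability_mask:
            ms, me = (np.asarray(a) for a in mappability_mask[chrom])
            order = np.argsort(ms)
            ms, me = ms[order], me[order]
            ends_sorted = np.sort(me)
            n_before = np.searchsorted(ends_sorted, s, side="right")
            n_start = np.searchsorted(ms, e, side="left")
            m |= (n_start - n_before) > 0
        masked[grp.index.to_numpy()] = m
    sites["masked"] = masked
    return sites
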