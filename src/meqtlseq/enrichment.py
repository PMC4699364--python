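"""Annotation logic and the two-layer enrichment machinery.

Fisher's exact test gives a first-pass enrichment p-value but assumes
independent sites; neighboring methylation sites are serially correlated,
which makes Fisher anticonservative. The circular-shift permutation rotates
the annotation vector along the genomic ordering — preserving the local
dependence structure — and scores the observed overlap against a Gaussian
fitted to the shifted overlap counts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import C, G, AnnotationTrack, ReferenceModel, STATE_ALPHABET
from .errors import ConfigError, DegenerateTestError

log = logging.getLogger(__name__)

_CODE = {"A": 65, "C": 67, "G": 71, "T": 84}


# ---------------------------------------------------------------------------
# CpG-SNP calling
# ---------------------------------------------------------------------------

def call_cpg_snps(snps: pd.DataFrame, ref: ReferenceModel) -> pd.DataFrame:
    """Flag SNPs whose alleles create or abolish a CpG dinucleotide.

    For each SNP, each allele is substituted into the +-1 bp sequence context
    and the CpG content compared: a CpG-SNP has a CpG under exactly one
    allele (C at the SNP with G to the right, or G at the SNP with C to the
    left). Reference-allele mismatches with the sequence are logged and the
    call proceeds by comparing the two constructed contexts.
    """
    out = snps[["snp", "chrom", "pos"]].copy() if "snp" in snps else snps[["chrom", "pos"]].copy()
    is_cpg = np.zeros(len(snps), dtype=bool)
    creates = np.array([""] * len(snps), dtype=object)
    abolishes = np.array([""] * len(snps), dtype=object)
    for chrom, grp in snps.groupby("chrom", sort=False):
        seq = ref.sequences[chrom]
        pos = grp["pos"].to_numpy()
        if pos.min() < 1 or pos.max() > seq.size - 2:
            raise ConfigError("reference must cover all SNP positions +-1 bp")
        left = seq[pos - 1]
        right = seq[pos + 1]
        ref_a = np.array([_CODE[a] for a in grp["ref"]], dtype=np.uint8)
        alt_a = np.array([_CODE[a] for a in grp["alt"]], dtype=np.uint8)
        mism = seq[pos] != ref_a
        if mism.any():
            log.warning("%d/%d SNPs on %s mismatch the reference base; "
                        "calling from constructed contexts",
                        int(mism.sum()), len(grp), chrom)

        def has_cpg(center):
            return ((center == C) & (right == G)) | ((left == C) & (center == G))

        with_ref = has_cpg(ref_a)
        with_alt = has_cpg(alt_a)
        flag = with_ref != with_alt
        idx = grp.index.to_numpy()
        is_cpg[idx] = flag
        creates[idx] = np.where(flag & with_alt, grp["alt"],
                                np.where(flag & with_ref, grp["ref"], ""))
        abolishes[idx] = np.where(flag & with_alt, grp["ref"],
                                  np.where(flag & with_ref, grp["alt"], ""))
    out["is_cpg_snp"] = is_cpg
    out["allele_creates_cpg"] = creates
    out["allele_abolishes_cpg"] = abolishes
    return out


# ---------------------------------------------------------------------------
# overlap conventions
# ---------------------------------------------------------------------------

def annotate_sites(sites: pd.DataFrame, track: AnnotationTrack,
                   convention: str = "any_overlap", flank: int = 250) -> np.ndarray:
    """Boolean indicator: does each site carry the annotation?

    Conventions: ``any_overlap`` (interval intersection), ``point_in_site``
    (point inside [start, end)), ``flank_250`` (point inside
    [start - flank, end + flank)).
    """
    if convention not in ("any_overlap", "point_in_site", "flank_250"):
        raise ConfigError(f"unknown overlap convention {convention!r}")
    if track.kind == "point" and convention == "any_overlap":
        convention = "point_in_site"  # the strict within-boundary convention
    hit = np.zeros(len(sites), dtype=bool)
    for chrom, grp in sites.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        idx = grp.index.to_numpy()
        if convention in ("point_in_site", "flank_250"):
            pts = track.chrom_points(chrom)
            pad = flank if convention == "flank_250" else 0
            n = np.searchsorted(pts, e + pad, side="left") - \
                np.searchsorted(pts, s - pad, side="left")
            hit[idx] = n > 0
        else:
            starts, ends = track.chrom_intervals(chrom)
            order = np.argsort(starts)
            starts = starts[order]
            ends_sorted = np.sort(ends)
            # intervals intersecting [s, e): start < e minus end <= s
            n = np.searchsorted(starts, e, side="left") - \
                np.searchsorted(ends_sorted, s, side="right")
            hit[idx] = n > 0
    return hit


# ---------------------------------------------------------------------------
# Fisher layer
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    a: int  # foreground & annotated
    b: int  # foreground & not annotated
    c: int  # annotated & not foreground
    d: int  # rest
    odds_ratio: float
    p: float
    degenerate: bool = False

    @classmethod
    def from_counts(cls, a: int, b: int, c: int, d: int) -> "FisherResult":
        degenerate = b * c == 0
        oratio = np.inf if degenerate and a * d > 0 else (
            np.nan if degenerate else (a * d) / (b * c))
        p = float(stats.fisher_exact([[a, b], [c, d]]).pvalue)
        return cls(a, b, c, d, float(oratio), p, degenerate)


def fisher_enrichment(foreground: np.ndarray, annotated: np.ndarray) -> FisherResult:
    """Two-sided Fisher exact test of annotation overlap.

    ``foreground`` and ``annotated`` are boolean vectors over the same
    background universe; the odds ratio is the sample cross-product a*d/(b*c).
    """
    fg = np.asarray(foreground, dtype=bool)
    an = np.asarray(annotated, dtype=bool)
    if fg.shape != an.shape:
        raise ConfigError("foreground and annotation vectors must align")
    a = int(np.sum(fg & an))
    b = int(np.sum(fg & ~an))
    c = int(np.sum(~fg & an))
    d = int(np.sum(~fg & ~an))
    return FisherResult.from_counts(a, b, c, d)


# ---------------------------------------------------------------------------
# circular-shift permutation layer
# ---------------------------------------------------------------------------

@dataclass
class ShiftResult:
    z: float
    p: float
    mu: float
    sigma: float
    observed: int
    n_offsets: int


def circular_shift_test(meqtl_flag: np.ndarray, annot_flag: np.ndarray,
                        exclusion_frac: float = 0.01,
                        subsample_frac: float = 1.0) -> ShiftResult:
    """Circular-shift permutation test on genome-ordered site flags.

    The annotation vector is rotated by every offset B that moves it by at
    least ``exclusion_frac`` of the sites in both directions (offsets are
    evenly subsampled by ``subsample_frac``); the observed overlap is scored
    as a z against a Gaussian fitted to the rotated overlap counts. Rotation
    preserves the serial correlation of both vectors, which is what keeps
    this test calibrated where Fisher's is not.
    """
    x = np.asarray(meqtl_flag, dtype=float)
    y = np.asarray(annot_flag, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("flag vectors must be 1-d and aligned")
    N = x.size
    if np.all(y == y[0]):
        raise DegenerateTestError("constant annotation flag: sigma would be 0")
    if np.all(x == x[0]):
        raise DegenerateTestError("constant meQTL flag: sigma would be 0")
    if not (0 < subsample_frac <= 1):
        raise ConfigError("subsample_frac must be in (0, 1]")
    b_min = int(np.ceil(exclusion_frac * N))
    offsets = np.arange(b_min, N - b_min + 1)
    if offsets.size < 10:
        raise ConfigError("too few eligible offsets for a permutation null")
    step = max(1, int(round(1.0 / subsample_frac)))
    offsets = offsets[::step]
    # all-offset overlap counts via circular cross-correlation
    counts = np.fft.irfft(np.conj(np.fft.rfft(x)) * np.fft.rfft(y), n=N)
    null = counts[offsets]
    observed = float(np.round(counts[0]))
    mu = float(null.mean())
    sigma = float(null.std(ddof=1))
    if sigma == 0:
        raise DegenerateTestError("degenerate permutation null: sigma is 0")
    z = (observed - mu) / sigma
    return ShiftResult(z=float(z), p=float(2.0 * stats.norm.sf(abs(z))),
                       mu=mu, sigma=sigma, observed=int(observed),
                       n_offsets=int(offsets.size))


# ---------------------------------------------------------------------------
# stratified driver
# ---------------------------------------------------------------------------

def state_tracks(ref: ReferenceModel, cell_type: int = 0) -> Dict[str, AnnotationTrack]:
    """One interval track per chromatin state for a given cell type."""
    tracks: Dict[str, AnnotationTrack] = {}
    for si, state in enumerate(STATE_ALPHABET):
        data = {}
        for chrom in ref.chrom_names:
            starts, labels = ref.states[cell_type][chrom]
            ends = np.append(starts[1:], ref.lengths[chrom])
            sel = labels == si
            if sel.any():
                data[chrom] = (starts[sel].astype(np.int64), ends[sel].astype(np.int64))
        tracks[state] = AnnotationTrack(state, "interval", data)
    return tracks


def stratified_enrichment(
    sites: pd.DataFrame,
    meqtl_flag: np.ndarray,
    cpg_snp_flag: np.ndarray,
    tracks: Mapping[str, AnnotationTrack],
    convention: str = "any_overlap",
    exclusion_frac: float = 0.01,
    subsample_frac: float = 1.0,
    alpha: float = 0.01,
    sets: Optional[Mapping[str, Tuple[np.ndarray, np.ndarray]]] = None,
) -> pd.DataFrame:
    """Fisher + circular-shift enrichment for each track and meQTL set.

    Default sets mirror the stratified design: all meQTLs against the full
    site universe, CpG-SNP meQTLs against all CpG-SNP sites, and
    non-CpG-SNP meQTLs against all sites lacking a CpG-SNP. ``sites`` must be
    in genome (chromosome name-sorted, position-sorted) order. BH q-values
    are computed across the whole batch of permutation p-values; rows whose
    permutation null is degenerate get NA and are logged.
    """
    meqtl = np.asarray(meqtl_flag, dtype=bool)
    cpg = np.asarray(cpg_snp_flag, dtype=bool)
    if sets is None:
        sets = {
            "all": (meqtl, np.ones(meqtl.size, dtype=bool)),
            "cpg_snp": (meqtl & cpg, cpg),
            "non_cpg_snp": (meqtl & ~cpg, ~cpg),
        }
    rows = []
    for tname, track in tracks.items():
        annot = annotate_sites(sites, track, convention=convention)
        for sname, (fg, bg) in sets.items():
            if bg.sum() == 0 or fg[bg].sum() == 0:
                log.warning("empty stratum for set=%s track=%s", sname, tname)
                rows.append({"track": tname, "set": sname,
                             "background_n": int(bg.sum()),
                             "foreground_n": int(fg[bg].sum())})
                continue
            fr = fisher_enrichment(fg[bg], annot[bg])
            row = {"track": tname, "set": sname,
                   "background_n": int(bg.sum()), "foreground_n": int(fg[bg].sum()),
                   "a": fr.a, "b": fr.b, "c": fr.c, "d": fr.d,
                   "odds_ratio": fr.odds_ratio, "fisher_p": fr.p}
            try:
                sr = circular_shift_test(fg[bg].astype(float), annot[bg].astype(float),
                                         exclusion_frac, subsample_frac)
                row.update(perm_mu=sr.mu, perm_sigma=sr.sigma, perm_z=sr.z,
                           perm_p=sr.p, perm_observed=sr.observed)
            except DegenerateTestError as exc:
                log.warning("degenerate shift test for set=%s track=%s: %s",
                            sname, tname, exc)
            rows.append(row)
    out = pd.DataFrame(rows)
    if "perm_p" in out:
        ok = out["perm_p"].notna()
        q = np.full(len(out), np.nan)
        if ok.any():
            q[ok.to_numpy()] = multipletests(out.loc[ok, "perm_p"], method="fdr_bh")[1]
        out["perm_q"] = q
        out["significant"] = (out["perm_q"] < alpha)
    return out
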