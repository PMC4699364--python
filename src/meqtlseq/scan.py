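"""The meQTL association scan.

Methylation site values are inverse-quantile-normal transformed, covariates
(lab variables, batch, ancestry dimensions and the top methylation PCs) are
regressed out of both dosages and methylation, and every SNP-site pair is
scored by the correlation of the residuals — algebraically identical to the
per-pair ordinary-least-squares t statistic for the genotype term, but
computed as one matrix product per chromosome pair.

Tests are stratified by SNP-site distance (local <= 1 Mb, distant same
chromosome, cross-chromosome) and the Benjamini-Hochberg threshold
P(k) <= (k/m) * alpha is applied within each stratum separately.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, ReplicationResult
from .errors import CollinearityError, ConfigError, DegenerateSiteError

STRATA = ("local", "distant_same_chr", "cross_chr")
LOCAL_WINDOW = 1_000_000
_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


# ---------------------------------------------------------------------------
# transforms and covariates
# ---------------------------------------------------------------------------

def inverse_quantile_normal(values: np.ndarray) -> np.ndarray:
    """Phi^-1((rank - 0.5)/n) of a vector, ties sharing their average rank."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ConfigError("need a 1-d vector with >= 3 values")
    if np.all(v == v[0]):
        raise DegenerateSiteError("constant vector cannot be rank-transformed")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - 0.5) / v.size)


def quantile_normalize_columns(matrix: np.ndarray,
                               on_constant: str = "raise") -> Tuple[np.ndarray, np.ndarray]:
    """Column-wise inverse quantile normal transform of a subjects x sites
    matrix. Returns (transformed matrix, boolean mask of kept columns);
    with ``on_constant="drop"`` degenerate columns are removed instead of
    raising."""
    M = np.asarray(matrix, dtype=float)
    const = np.all(M == M[0], axis=0)
    if const.any():
        if on_constant == "raise":
            raise DegenerateSiteError(
                f"{int(const.sum())} constant site columns; drop them first")
        M = M[:, ~const]
    ranks = stats.rankdata(M, method="average", axis=0)
    return stats.norm.ppf((ranks - 0.5) / M.shape[0]), ~const


def _design(covariates: Optional[pd.DataFrame | np.ndarray], n: int) -> Tuple[np.ndarray, List[str]]:
    if covariates is None:
        return np.empty((n, 0)), []
    if isinstance(covariates, pd.DataFrame):
        return covariates.to_numpy(dtype=float), list(covariates.columns)
    X = np.asarray(covariates, dtype=float)
    return X, [f"cov{i}" for i in range(X.shape[1])]


def residualize(values: np.ndarray,
                covariates: Optional[pd.DataFrame | np.ndarray]) -> np.ndarray:
    """Residuals of each column of ``values`` on covariates plus intercept."""
    n = values.shape[0]
    X, names = _design(covariates, n)
    X = np.column_stack([np.ones(n), X])
    q, r = np.linalg.qr(X)
    small = np.abs(np.diag(r)) < 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if small.any():
        bad = [(["intercept"] + names)[i] for i in np.flatnonzero(small)]
        raise CollinearityError(bad)
    return values - q @ (q.T @ values)


def compute_methylation_pcs(site_matrix: np.ndarray, k: int = 7
                            ) -> Tuple[np.ndarray, np.ndarray]:
    """Top-k principal-component scores of the subjects x sites matrix.

    Sites are centered; scores are U * Sigma (mutually orthogonal). Returns
    (scores, explained variance per PC for the scree).
    """
    n = site_matrix.shape[0]
    if k >= n:
        raise ConfigError(f"k={k} must be < n_subjects={n}")
    M = site_matrix - site_matrix.mean(axis=0)
    u, s, _ = np.linalg.svd(M, full_matrices=False)
    var = (s ** 2) / (n - 1)
    return u[:, :k] * s[:k], var


def pc_genotype_check(pc_scores: np.ndarray, genotypes: GenotypeMatrix,
                      covariates: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """GWAS each methylation PC against all SNPs; summarize inflation.

    Returns one row per PC: genomic-inflation lambda_GC
    (median chi-square / 0.4549) and the Bonferroni-adjusted minimum p —
    the sanity check that PCs regressed out of the methylation are not
    themselves under genetic control.
    """
    n, n_pcs = pc_scores.shape
    res = association_scan_matrix(genotypes.dosages, pc_scores, covariates)
    t, p = res
    rows = []
    for j in range(n_pcs):
        chi = stats.chi2.isf(np.clip(p[:, j], 1e-300, 1.0), 1)
        min_p = float(p[:, j].min())
        rows.append({
            "pc": j + 1,
            "lambda_gc": float(np.median(chi) / _CHI2_MEDIAN_1DF),
            "min_p": min_p,
            "min_p_bonferroni": min(1.0, min_p * genotypes.n_snps),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# the scan
# ---------------------------------------------------------------------------

def association_scan_matrix(dosages: np.ndarray, pheno: np.ndarray,
                            covariates: Optional[pd.DataFrame | np.ndarray] = None
                            ) -> Tuple[np.ndarray, np.ndarray]:
    """t statistics and two-sided p-values for every (SNP, phenotype) pair.

    Both sides are residualized on the covariates (with intercept), columns
    are scaled to unit norm and correlations are obtained as a single matrix
    product; t = r * sqrt(df / (1 - r^2)) with df = n - n_covariates - 2.
    """
    n = dosages.shape[0]
    if pheno.shape[0] != n:
        raise ConfigError("subject dimension mismatch")
    X, _ = _design(covariates, n)
    df = n - X.shape[1] - 2
    if df < 1:
        raise ConfigError("not enough degrees of freedom")
    G = residualize(np.asarray(dosages, dtype=float), covariates)
    M = residualize(np.asarray(pheno, dtype=float), covariates)
    gn = np.linalg.norm(G, axis=0)
    mn = np.linalg.norm(M, axis=0)
    gn[gn == 0] = np.inf
    mn[mn == 0] = np.inf
    r = (G / gn).T @ (M / mn)
    r = np.clip(r, -1.0, 1.0)
    t = r * np.sqrt(df / np.maximum(1.0 - r ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return t, p


def classify_stratum(snp_chrom, snp_pos: int, site_chrom, site_start: int,
                     site_end: int, window: int = LOCAL_WINDOW
                     ) -> Tuple[str, float]:
    """Stratum and bp distance for one SNP-site pair (inf across chromosomes).

    Distance is 0 inside the site interval, else bp to the nearest edge;
    local means same chromosome and distance <= window (inclusive).
    """
    if snp_chrom != site_chrom:
        return "cross_chr", float("inf")
    if snp_pos < site_start:
        d = site_start - snp_pos
    elif snp_pos >= site_end:
        d = snp_pos - site_end + 1
    else:
        d = 0
    return ("local" if d <= window else "distant_same_chr"), float(d)


def classify_strata(snp_chrom: np.ndarray, snp_pos: np.ndarray,
                    site_chrom: np.ndarray, site_start: np.ndarray,
                    site_end: np.ndarray, window: int = LOCAL_WINDOW
                    ) -> Tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`classify_stratum` over aligned pair arrays.

    Returns (stratum codes indexing :data:`STRATA`, distances)."""
    same = np.asarray(snp_chrom) == np.asarray(site_chrom)
    d = np.where(snp_pos < site_start, site_start - snp_pos,
                 np.where(snp_pos >= site_end, snp_pos - site_end + 1, 0)).astype(float)
    d[~same] = np.inf
    codes = np.where(~same, 2, np.where(d <= window, 0, 1)).astype(np.int8)
    return codes, d


def count_tests(genotypes: GenotypeMatrix, sites: pd.DataFrame,
                window: int = LOCAL_WINDOW) -> Dict[str, int]:
    """Exact per-stratum test counts (total = n_snps * n_sites).

    Local counts use position-sorted window counting per chromosome, so this
    scales to realistic SNP/site densities without enumerating pairs.
    """
    snps = genotypes.snps
    total = len(snps) * len(sites)
    local = 0
    same = 0
    for chrom, s_grp in sites.groupby("chrom", sort=False):
        pos = np.sort(snps.loc[snps["chrom"] == chrom, "pos"].to_numpy())
        same += pos.size * len(s_grp)
        if pos.size == 0:
            continue
        lo = np.searchsorted(pos, s_grp["start"].to_numpy() - window, side="left")
        hi = np.searchsorted(pos, s_grp["end"].to_numpy() - 1 + window, side="right")
        local += int((hi - lo).sum())
    return {"local": local, "distant_same_chr": same - local,
            "cross_chr": total - same, "total": total}


def association_scan(
    genotypes: GenotypeMatrix,
    site_matrix: np.ndarray,
    sites: pd.DataFrame,
    covariates: Optional[pd.DataFrame | np.ndarray] = None,
    window: int = LOCAL_WINDOW,
    p_keep: Optional[float] = None,
    snp_chunk: int = 512,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Scan every SNP against every site.

    ``site_matrix`` must already be quantile-normalized. Returns
    (pair frame, per-stratum test counts). With ``p_keep`` set, only pairs
    with p <= p_keep are materialized (exact counts are still returned for
    FDR); the Benjamini-Hochberg threshold must then land below ``p_keep``,
    which holds whenever alpha * (retained fraction) is comfortably smaller.
    """
    snps = genotypes.snps
    n = genotypes.n_subjects
    if site_matrix.shape[0] != n:
        raise ConfigError("subject dimension mismatch between genotypes and sites")
    site_chrom = sites["chrom"].to_numpy()
    site_start = sites["start"].to_numpy()
    site_end = sites["end"].to_numpy()
    counts = count_tests(genotypes, sites, window)

    chunks = []
    for lo in range(0, genotypes.n_snps, snp_chunk):
        sl = slice(lo, min(lo + snp_chunk, genotypes.n_snps))
        t, p = association_scan_matrix(genotypes.dosages[:, sl], site_matrix,
                                       covariates)
        snp_idx, site_idx = np.nonzero(p <= p_keep) if p_keep is not None else \
            (np.repeat(np.arange(t.shape[0]), t.shape[1]),
             np.tile(np.arange(t.shape[1]), t.shape[0]))
        snp_idx_g = snp_idx + lo
        codes, dist = classify_strata(
            snps["chrom"].to_numpy()[snp_idx_g], snps["pos"].to_numpy()[snp_idx_g],
            site_chrom[site_idx], site_start[site_idx], site_end[site_idx], window)
        chunks.append(pd.DataFrame({
            "snp": snps["snp"].to_numpy()[snp_idx_g],
            "site": sites["site"].to_numpy()[site_idx],
            "snp_index": snp_idx_g, "site_index": site_idx,
            "distance": dist,
            "stratum": pd.Categorical.from_codes(codes, categories=list(STRATA)),
            "t": t[snp_idx, site_idx], "p": p[snp_idx, site_idx],
        }))
    results = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame(
        columns=["snp", "site", "snp_index", "site_index", "distance",
                 "stratum", "t", "p"])
    return results, counts


# ---------------------------------------------------------------------------
# FDR, replication, reporting
# ---------------------------------------------------------------------------

@dataclass
class FdrResult:
    """Per-stratum Benjamini-Hochberg outcome."""
    stratum: str
    m: int
    alpha: float
    k: int
    p_threshold: float  # NaN when k == 0 or the stratum is empty

    def as_dict(self):
        return self.__dict__.copy()


def bh_threshold(p: np.ndarray, m: int, alpha: float) -> Tuple[int, float]:
    """max k with P(k) <= (k/m) alpha over the (possibly truncated) sorted
    p-values; returns (k, P(k)) with (0, nan) when nothing passes."""
    ps = np.sort(np.asarray(p, dtype=float))
    k_idx = np.flatnonzero(ps <= (np.arange(1, ps.size + 1) / m) * alpha)
    if k_idx.size == 0:
        return 0, float("nan")
    k = int(k_idx[-1]) + 1
    return k, float(ps[k - 1])


def stratified_bh_fdr(
    p: np.ndarray,
    strata: Sequence[str] | np.ndarray,
    alpha: float = 0.01,
    m_per_stratum: Optional[Mapping[str, int]] = None,
) -> Tuple[List[FdrResult], np.ndarray]:
    """Benjamini-Hochberg within each stratum with that stratum's own m.

    ``m_per_stratum`` supplies the true test counts when ``p`` holds only a
    p-value-thresholded subset of the tests (unretained tests can only sit
    above the BH threshold, so the procedure is unchanged).
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ConfigError("p-values must lie in [0, 1]")
    strata = np.asarray(strata)
    flags = np.zeros(p.size, dtype=bool)
    out = []
    for s in STRATA:
        sel = strata == s
        m = int(m_per_stratum.get(s, sel.sum())) if m_per_stratum \
            else int(sel.sum())
        if m == 0:
            out.append(FdrResult(s, 0, alpha, 0, float("nan")))
            continue
        k, thr = bh_threshold(p[sel], m, alpha)
        if k > 0:
            flags[sel] = p[sel] <= thr
        out.append(FdrResult(s, m, alpha, k, thr))
    return out, flags


def pi1_replication(replication_p: np.ndarray, lambda_: float = 0.5
                    ) -> ReplicationResult:
    """Storey-style pi1 = 1 - pi0 with pi0 = #{p > lambda} / ((1-lambda) m)."""
    p = np.asarray(replication_p, dtype=float)
    if p.size == 0:
        raise ConfigError("no carried-forward pairs to replicate")
    if not (0 < lambda_ < 1):
        raise ConfigError("lambda must be in (0, 1)")
    pi0 = np.sum(p > lambda_) / ((1.0 - lambda_) * p.size)
    return ReplicationResult(pi1=float(np.clip(1.0 - pi0, 0.0, 1.0)),
                             lambda_=lambda_, n_pairs=int(p.size))


def summarize_results(
    results: pd.DataFrame,
    fdr: List[FdrResult],
    counts: Mapping[str, int],
    sites: pd.DataFrame,
    genotypes: GenotypeMatrix,
    truth: Optional[pd.DataFrame] = None,
    flank: int = 250,
) -> pd.DataFrame:
    """Table-1-shaped per-stratum report.

    Rows: test counts, BH threshold, significant pair counts, unique SNPs and
    unique sites with meQTLs, and the CpG-SNP composition of meQTL sites
    (share with a CpG-SNP within +-``flank`` bp, with only other SNPs, or
    with no SNP). With ``truth``, adds planted-effect power and the realized
    site-level false discovery proportion.
    """
    sig = results.loc[results["significant"].astype(bool)] \
        if "significant" in results else results.iloc[0:0]
    snp_pos = {c: g["pos"].to_numpy() for c, g in genotypes.snps.groupby("chrom")}
    cpg_flag = {c: g["is_cpg_snp"].to_numpy().astype(bool)
                for c, g in genotypes.snps.groupby("chrom")}

    def site_snp_class(site_rows: pd.DataFrame) -> np.ndarray:
        """0: has CpG-SNP in flank, 1: other SNP only, 2: no SNP."""
        cls = np.full(len(site_rows), 2, dtype=int)
        for i, (_, r) in enumerate(site_rows.iterrows()):
            pos = snp_pos.get(r["chrom"])
            if pos is None:
                continue
            lo = np.searchsorted(pos, r["start"] - flank, side="left")
            hi = np.searchsorted(pos, r["end"] + flank, side="left")
            if hi > lo:
                cls[i] = 0 if cpg_flag[r["chrom"]][lo:hi].any() else 1
        return cls

    rows = []
    for fr in fdr:
        s = fr.stratum
        sub = sig[sig["stratum"] == s]
        u_sites = sub["site"].unique()
        site_rows = sites[sites["site"].isin(u_sites)]
        cls = site_snp_class(site_rows)
        row = {
            "stratum": s,
            "n_tests": counts[s],
            "p_threshold": fr.p_threshold,
            "n_significant": int(len(sub)),
            "unique_snps": int(sub["snp"].nunique()),
            "unique_sites": int(len(u_sites)),
            "pct_sites_with_cpg_snp": 100.0 * np.mean(cls == 0) if len(cls) else np.nan,
            "pct_sites_with_other_snp": 100.0 * np.mean(cls == 1) if len(cls) else np.nan,
            "pct_sites_without_snp": 100.0 * np.mean(cls == 2) if len(cls) else np.nan,
        }
        if truth is not None and s == "local":
            planted = truth[truth["is_meqtl"]]
            hit = 0
            for _, reg in planted.iterrows():
                olap = site_rows[(site_rows["chrom"] == reg["chrom"]) &
                                 (site_rows["start"] < reg["end"]) &
                                 (site_rows["end"] > reg["start"])]
                hit += int(len(olap) > 0)
            row["power"] = hit / max(1, len(planted))
            true_regions = planted[["chrom", "start", "end"]]
            false = 0
            for _, sr in site_rows.iterrows():
                near = true_regions[(true_regions["chrom"] == sr["chrom"]) &
                                    (true_regions["start"] < sr["end"] + flank) &
                                    (true_regions["end"] > sr["start"] - flank)]
                false += int(len(near) == 0)
            row["site_fdp"] = false / max(1, len(site_rows))
        rows.append(row)
    return pd.DataFrame(rows)
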