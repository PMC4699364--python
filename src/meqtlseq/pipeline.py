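"""Pipeline orchestration: configuration, stage wiring, provenance.

``run_pipeline`` executes simulate -> coverage -> scan -> enrich -> report,
each stage communicating only through serialized files in the run directory,
and records a manifest (config hash, per-stage seeds, versions, timings) so
a rerun with the same config reproduces every deterministic output.
``end_to_end`` composes the same library calls in memory for programmatic
use and for the test suite.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import coverage as cov
from . import enrichment as enr
from . import io as mio
from . import scan as sc
from . import simulate as sim
from .datatypes import CovariateTable, GenotypeMatrix, Reads
from .dists import FragmentLengthDistribution
from .errors import ConfigError, MeqtlseqError

log = logging.getLogger(__name__)

STAGES = ("simulate", "coverage", "scan", "enrich", "report")


@dataclass
class RunConfig:
    """Every knob of the pipeline, defaulting to the study-scale constants
    (1 Mb local window, FDR 1%, 7 methylation PCs, 250 bp CpG-SNP flank,
    97.5th-percentile background filter over non-CpG loci 400 bp from any
    CpG, 5 Mb pericentromeric / 1 Mb subtelomeric exclusion)."""

    seed: int = 0
    # simulate
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chr1": 2_000_000, "chr2": 2_000_000})
    cpg_density: float = 0.02
    n_cell_types: int = 1
    n_subjects: int = 100
    n_snps: int = 2000
    block_len: float = 20_000.0
    maf_range: Tuple[float, float] = (0.05, 0.5)
    n_founders: int = 12
    cpg_snp_frac: float = 0.3
    n_cpg_snp_effects: int = 25
    n_binding_effects: int = 25
    cpg_snp_states: Tuple[str, ...] = ("Quies",)
    binding_states: Tuple[str, ...] = ("TssA", "EnhA1")
    depth: int = 400_000
    read_len: int = 50
    frag_median: float = 125.0
    n_batches: int = 3
    confounding_strength: float = 1.0
    # coverage
    isolation_gap: int = 500
    d_max: int = 500
    r_min: float = 0.90
    collapse_max_gap: int = 500
    background_gap_bp: int = 400
    background_pct: float = 97.5
    n_background: int = 20_000
    peri_bp: int = 5_000_000
    subtel_bp: int = 1_000_000
    # scan
    window_bp: int = 1_000_000
    alpha: float = 0.01
    n_pcs: int = 7
    lambda_pi1: float = 0.5
    p_keep: Optional[float] = 1e-3
    # enrich
    flank_bp: int = 250
    exclusion_frac: float = 0.01
    perm_subsample: float = 1.0
    stages: List[str] = field(default_factory=lambda: list(STAGES))

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**data)
        if isinstance(cfg.maf_range, list):
            cfg.maf_range = tuple(cfg.maf_range)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def stage_seeds(self) -> Dict[str, int]:
        """Fan the top-level seed out to one independent seed per stage."""
        children = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return {s: int(c.generate_state(1)[0] % (2 ** 31))
                for s, c in zip(STAGES, children)}


# ---------------------------------------------------------------------------
# in-memory composition
# ---------------------------------------------------------------------------

def simulate_dataset(cfg: RunConfig):
    """Reference, genotypes, covariates, truth and fragments for a config."""
    seeds = cfg.stage_seeds()
    rs = np.random.SeedSequence(seeds["simulate"]).spawn(5)
    sub = [int(s.generate_state(1)[0] % (2 ** 31)) for s in rs]
    ref = sim.simulate_reference(cfg.chrom_lengths, cfg.cpg_density,
                                 cfg.n_cell_types, seed=sub[0])
    geno = sim.simulate_genotypes(ref, cfg.n_subjects, n_snps=cfg.n_snps,
                                  block_len=cfg.block_len, maf_range=cfg.maf_range,
                                  n_founders=cfg.n_founders,
                                  cpg_snp_frac=cfg.cpg_snp_frac, seed=sub[1])
    covt = sim.simulate_covariates(cfg.n_subjects, cfg.n_batches,
                                   cfg.confounding_strength, seed=sub[2])
    truth = sim.plant_meqtls(ref, geno, cfg.n_cpg_snp_effects,
                             cfg.n_binding_effects, seed=sub[3],
                             flank=cfg.flank_bp,
                             cpg_snp_states=tuple(cfg.cpg_snp_states),
                             binding_states=tuple(cfg.binding_states),
                             peri_bp=cfg.peri_bp, subtel_bp=cfg.subtel_bp)
    frags = sim.simulate_fragments(
        ref, truth, geno, covt, depth=cfg.depth,
        frag_len_dist=FragmentLengthDistribution.gamma(median=cfg.frag_median),
        read_len=cfg.read_len, seed=sub[4])
    return ref, geno, covt, truth, frags


def coverage_stage(cfg: RunConfig, ref, frags) -> tuple:
    """Reads -> fragment-size model -> measure -> sites (+filters)."""
    seeds = cfg.stage_seeds()
    reads = frags.to_reads()
    iso = {c: cov.find_isolated_cpgs(ref.cpg_positions[c], cfg.isolation_gap)
           for c in ref.chrom_names}
    model = cov.estimate_fragment_size_distribution(
        reads, iso, read_len=cfg.read_len, d_max=cfg.d_max)
    matrix = cov.compute_methylation_measure(reads, ref.cpg_positions, model,
                                             ref.lengths)
    sites, site_matrix = cov.collapse_adjacent_cpgs(matrix, cfg.r_min,
                                                    cfg.collapse_max_gap)
    sites, threshold = cov.background_filter(
        sites, site_matrix, reads, model, ref.cpg_positions, ref.lengths,
        cfg.background_gap_bp, cfg.background_pct, cfg.n_background,
        seed=seeds["coverage"])
    sites = cov.apply_region_masks(sites, ref.centromeres, ref.lengths,
                                   peri=cfg.peri_bp, subtel=cfg.subtel_bp)
    return model, matrix, sites, site_matrix, threshold


def scan_stage(cfg: RunConfig, geno: GenotypeMatrix, covt: CovariateTable,
               sites: pd.DataFrame, site_matrix: np.ndarray,
               truth: Optional[pd.DataFrame] = None) -> dict:
    """Filter sites, transform, PCs, scan, stratified FDR, summary."""
    keep = (sites["passed_background_filter"] & ~sites["masked"]).to_numpy()
    kept = sites.loc[keep].reset_index(drop=True)
    M = site_matrix[:, keep]
    Mq, ok = sc.quantile_normalize_columns(M, on_constant="drop")
    kept = kept.loc[ok].reset_index(drop=True)
    pcs, scree = sc.compute_methylation_pcs(Mq, k=cfg.n_pcs)
    base_cov = covt.design_matrix()
    pc_check = sc.pc_genotype_check(pcs, geno, base_cov)
    design = pd.concat([base_cov, pd.DataFrame(
        pcs, index=base_cov.index, columns=[f"meth_pc{i+1}" for i in range(pcs.shape[1])])],
        axis=1)
    results, counts = sc.association_scan(geno, Mq, kept, design,
                                          window=cfg.window_bp, p_keep=cfg.p_keep)
    fdr, flags = sc.stratified_bh_fdr(results["p"].to_numpy(),
                                      results["stratum"].astype(str).to_numpy(),
                                      alpha=cfg.alpha, m_per_stratum=counts)
    results["significant"] = flags
    summary = sc.summarize_results(results, fdr, counts, kept, geno,
                                   truth=truth, flank=cfg.flank_bp)
    return {"sites": kept, "matrix_qn": Mq, "pcs": pcs, "scree": scree,
            "pc_check": pc_check, "results": results, "counts": counts,
            "fdr": fdr, "summary": summary, "design": design}


def enrich_stage(cfg: RunConfig, ref, geno: GenotypeMatrix,
                 scan_out: dict) -> pd.DataFrame:
    """Stratified chromatin-state + GWAS-track enrichment of meQTL sites."""
    kept = scan_out["sites"]
    results = scan_out["results"]
    sig = results[results["significant"] & (results["stratum"] == "local")]
    meqtl = np.zeros(len(kept), dtype=bool)
    meqtl[np.unique(sig["site_index"].to_numpy())] = True

    cpg_snp_pos = {
        c: np.sort(g.loc[g["is_cpg_snp"], "pos"].to_numpy())
        for c, g in geno.snps.groupby("chrom")}
    from .datatypes import AnnotationTrack
    cpg_track = AnnotationTrack("cpg_snps", "point", cpg_snp_pos)
    site_has_cpg_snp = enr.annotate_sites(kept, cpg_track, "flank_250",
                                          flank=cfg.flank_bp)
    tracks = dict(enr.state_tracks(ref, cell_type=0))
    tracks["gwas_catalog"] = ref.tracks["gwas_catalog"]
    return enr.stratified_enrichment(
        kept, meqtl, site_has_cpg_snp, tracks,
        exclusion_frac=cfg.exclusion_frac, subsample_frac=cfg.perm_subsample,
        alpha=cfg.alpha)


def end_to_end(cfg: RunConfig) -> dict:
    """Full in-memory run; returns every intermediate keyed by name."""
    ref, geno, covt, truth, frags = simulate_dataset(cfg)
    model, matrix, sites, site_matrix, threshold = coverage_stage(cfg, ref, frags)
    scan_out = scan_stage(cfg, geno, covt, sites, site_matrix, truth=truth)
    enrich = enrich_stage(cfg, ref, geno, scan_out)
    return {"config": cfg, "ref": ref, "genotypes": geno, "covariates": covt,
            "truth": truth, "fragments": frags, "fragment_model": model,
            "coverage": matrix, "sites_all": sites, "site_matrix": site_matrix,
            "background_threshold": threshold, "enrichment": enrich, **scan_out}


# ---------------------------------------------------------------------------
# file-based stages
# ---------------------------------------------------------------------------

def _frag_bed(frags) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": np.array(frags.chrom_names, dtype=object)[frags.chrom_code],
        "start": frags.start,
        "end": frags.start + frags.length,
        "name": np.array(frags.subjects, dtype=object)[frags.subject],
        "score": frags.length,
        "strand": np.where(frags.strand > 0, "+", "-"),
    })


def _reads_from_bed(df: pd.DataFrame, chrom_names, subjects, read_len) -> Reads:
    code = pd.Categorical(df["chrom"], categories=chrom_names).codes.astype(np.int16)
    sub = pd.Categorical(df["field4"], categories=subjects).codes.astype(np.int32)
    strand = np.where(df["field6"].to_numpy() == "+", 1, -1).astype(np.int8)
    start = df["start"].to_numpy()
    length = df["end"].to_numpy() - start
    pos5 = np.where(strand > 0, start, start + length - 1)
    return Reads(code, pos5.astype(np.int64), strand, sub,
                 list(chrom_names), list(subjects), read_len)


def run_pipeline(cfg: RunConfig, outdir: str) -> Path:
    """Execute the configured stages against a run directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    logf = logging.FileHandler(out / "pipeline.log")
    logging.getLogger().addHandler(logf)
    manifest = {"config": cfg.to_dict(), "config_hash": cfg.digest(),
                "stage_seeds": cfg.stage_seeds(), "timings": {},
                "version": __import__("meqtlseq").__version__}
    state: dict = {}
    try:
        for stage in STAGES:
            if stage not in cfg.stages:
                continue
            t0 = time.time()
            try:
                _run_stage(stage, cfg, out, state)
            except MeqtlseqError:
                raise
            except Exception as exc:
                raise MeqtlseqError(
                    f"stage {stage!r} failed ({exc}); see {out / 'pipeline.log'}"
                ) from exc
            manifest["timings"][stage] = round(time.time() - t0, 2)
            log.info("stage %s done in %.1fs", stage, manifest["timings"][stage])
    finally:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        logging.getLogger().removeHandler(logf)
    return out


def _require(out: Path, *names: str) -> None:
    missing = [n for n in names if not (out / n).exists()]
    if missing:
        raise ConfigError(f"missing inputs {missing}; enable earlier stages "
                          "or place the files in the run directory")


def _run_stage(stage: str, cfg: RunConfig, out: Path, state: dict) -> None:
    if stage == "simulate":
        ref, geno, covt, truth, frags = simulate_dataset(cfg)
        mio.write_fasta(ref.sequences, out / "reference.fa")
        cpgs = pd.concat([pd.DataFrame({"chrom": c, "start": p, "end": p + 2})
                          for c, p in sorted(ref.cpg_positions.items())])
        mio.write_bed(cpgs, out / "cpgs.bed")
        cen = pd.DataFrame([(c, s, e) for c, (s, e) in sorted(ref.centromeres.items())],
                           columns=["chrom", "start", "end"])
        mio.write_bed(cen, out / "centromeres.bed")
        for ct in range(ref.n_cell_types):
            rows = []
            for chrom in ref.chrom_names:
                starts, labels = ref.states[ct][chrom]
                ends = np.append(starts[1:], ref.lengths[chrom])
                from .datatypes import STATE_ALPHABET
                for s, e, l in zip(starts, ends, labels):
                    rows.append((chrom, s, e, STATE_ALPHABET[l]))
            mio.write_bed(pd.DataFrame(rows, columns=["chrom", "start", "end", "state"]),
                          out / f"chromatin_states.ct{ct}.bed",
                          columns=("chrom", "start", "end", "state"))
        gw = ref.tracks["gwas_catalog"]
        gwas = pd.concat([pd.DataFrame({"chrom": c, "start": gw.chrom_points(c),
                                        "end": gw.chrom_points(c) + 1})
                          for c in ref.chrom_names])
        mio.write_bed(gwas, out / "gwas_catalog.bed")
        mio.write_vcf(geno, str(out / "genotypes.vcf"), ref.lengths)
        mio.write_tsv(covt.table.reset_index(names="subject"), out / "covariates.tsv")
        mio.write_tsv(truth, out / "truth.tsv")
        mio.write_bed(_frag_bed(frags), out / "fragments.bed",
                      columns=("chrom", "start", "end", "name", "score", "strand"))
        with open(out / "genome.json", "w") as fh:
            json.dump({"lengths": ref.lengths, "read_len": cfg.read_len,
                       "subjects": geno.subjects}, fh)
        state["ref"] = ref
    elif stage == "coverage":
        _require(out, "fragments.bed", "cpgs.bed", "genome.json")
        ref = state.get("ref") or _load_ref(out)
        with open(out / "genome.json") as fh:
            meta = json.load(fh)
        bed = mio.read_bed(out / "fragments.bed", meta["lengths"], min_fields=6)
        frag_like = _reads_from_bed(bed, sorted(meta["lengths"]), meta["subjects"],
                                    meta["read_len"])
        seeds = cfg.stage_seeds()
        iso = {c: cov.find_isolated_cpgs(ref.cpg_positions[c], cfg.isolation_gap)
               for c in ref.chrom_names}
        model = cov.estimate_fragment_size_distribution(
            frag_like, iso, read_len=meta["read_len"], d_max=cfg.d_max)
        matrix = cov.compute_methylation_measure(frag_like, ref.cpg_positions,
                                                 model, ref.lengths)
        sites, smat = cov.collapse_adjacent_cpgs(matrix, cfg.r_min,
                                                 cfg.collapse_max_gap)
        sites, thr = cov.background_filter(
            sites, smat, frag_like, model, ref.cpg_positions, ref.lengths,
            cfg.background_gap_bp, cfg.background_pct, cfg.n_background,
            seed=seeds["coverage"])
        sites = cov.apply_region_masks(sites, ref.centromeres, ref.lengths,
                                       peri=cfg.peri_bp, subtel=cfg.subtel_bp)
        mio.write_tsv(sites, out / "sites.tsv")
        mio.write_matrix_tsv(smat, matrix.subjects, sites["site"], out / "site_matrix.tsv")
        np.savetxt(out / "fragment_survival.tsv", model.survival)
        with open(out / "coverage_meta.json", "w") as fh:
            json.dump({"background_threshold": thr}, fh)
        state.update(sites=sites, smat=smat)
    elif stage == "scan":
        _require(out, "sites.tsv", "site_matrix.tsv", "genotypes.vcf",
                 "covariates.tsv")
        geno = mio.read_vcf(str(out / "genotypes.vcf"))
        covdf = mio.read_tsv(out / "covariates.tsv").set_index("subject")
        covt = CovariateTable(covdf, np.zeros((len(covdf), 1)), 0.0)
        sites = mio.read_tsv(out / "sites.tsv")
        smat, _, _ = mio.read_matrix_tsv(out / "site_matrix.tsv")
        truth = mio.read_tsv(out / "truth.tsv") if (out / "truth.tsv").exists() else None
        res = scan_stage(cfg, geno, covt, sites, smat, truth=truth)
        mio.write_tsv(res["results"].sort_values(["stratum", "p"]),
                      out / "associations.tsv")
        mio.write_tsv(pd.DataFrame([f.as_dict() for f in res["fdr"]]),
                      out / "fdr.tsv")
        mio.write_tsv(res["pc_check"], out / "pc_genotype_check.tsv")
        mio.write_tsv(res["summary"], out / "summary.tsv")
        mio.write_tsv(res["sites"], out / "sites_kept.tsv")
        state["scan"] = res
        state["geno"] = geno
    elif stage == "enrich":
        _require(out, "sites_kept.tsv", "associations.tsv",
                 "chromatin_states.ct0.bed", "genotypes.vcf")
        ref = state.get("ref") or _load_ref(out)
        geno = state.get("geno") or mio.read_vcf(str(out / "genotypes.vcf"))
        if "scan" in state:
            res = state["scan"]
        else:
            sites = mio.read_tsv(out / "sites_kept.tsv")
            results = mio.read_tsv(out / "associations.tsv")
            res = {"sites": sites, "results": results}
        table = enrich_stage(cfg, ref, geno, res)
        mio.write_tsv(table, out / "enrichment.tsv")
        state["enrichment"] = table
    elif stage == "report":
        report = {}
        if (out / "summary.tsv").exists():
            report["scan_summary"] = mio.read_tsv(out / "summary.tsv").to_dict("records")
        if (out / "enrichment.tsv").exists():
            enr_table = mio.read_tsv(out / "enrichment.tsv")
            if "significant" in enr_table.columns:
                enr_table = enr_table[enr_table["significant"].fillna(False)]
            report["enrichment_calls"] = enr_table.to_dict("records")
        if (out / "coverage_meta.json").exists():
            with open(out / "coverage_meta.json") as fh:
                report.update(json.load(fh))
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)


def _load_ref(out: Path):
    """Rebuild the reference model from its serialized pieces."""
    from .datatypes import AnnotationTrack, ReferenceModel, STATE_ALPHABET
    seqs = mio.read_fasta(out / "reference.fa")
    lengths = {c: int(s.size) for c, s in seqs.items()}
    cpgs_bed = mio.read_bed(out / "cpgs.bed", lengths)
    cpgs = {c: g["start"].to_numpy() for c, g in cpgs_bed.groupby("chrom")}
    cen_bed = mio.read_bed(out / "centromeres.bed", lengths)
    cen = {r["chrom"]: (int(r["start"]), int(r["end"])) for _, r in cen_bed.iterrows()}
    states = []
    ct = 0
    while (out / f"chromatin_states.ct{ct}.bed").exists():
        df = mio.read_bed(out / f"chromatin_states.ct{ct}.bed", lengths)
        d = {}
        for chrom, grp in df.groupby("chrom"):
            starts = grp["start"].to_numpy()
            labels = np.array([STATE_ALPHABET.index(s) for s in grp["field4"]],
                              dtype=np.int8)
            d[chrom] = (starts, labels)
        states.append(d)
        ct += 1
    gwas_bed = mio.read_bed(out / "gwas_catalog.bed", lengths)
    gwas = {c: g["start"].to_numpy() for c, g in gwas_bed.groupby("chrom")}
    tracks = {"gwas_catalog": AnnotationTrack("gwas_catalog", "point", gwas)}
    return ReferenceModel(lengths=lengths, sequences=seqs, cpg_positions=cpgs,
                          centromeres=cen, states=states, tracks=tracks)
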