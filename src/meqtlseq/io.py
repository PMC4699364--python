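"""On-disk formats: BED (0-based half-open), bedGraph, VCF (GT+DS), TSV.

Readers validate eagerly and report 1-based line numbers on malformed input;
writers emit plain text so every artifact diffs and round-trips.
"""
from __future__ import annotations

import os
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .datatypes import AnnotationTrack, GenotypeMatrix
from .errors import FormatError


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, np.ndarray], path: str) -> None:
    recs = [SeqRecord(Seq(seq.tobytes().decode("ascii")), id=name, description="")
            for name, seq in sorted(sequences.items())]
    SeqIO.write(recs, path, "fasta")


def read_fasta(path: str) -> Dict[str, np.ndarray]:
    return {rec.id: np.frombuffer(str(rec.seq).upper().encode("ascii"), dtype=np.uint8).copy()
            for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# BED / bedGraph
# ---------------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path: str,
              columns: Sequence[str] = ("chrom", "start", "end")) -> None:
    df.loc[:, list(columns)].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str, chrom_lengths: Optional[Mapping[str, int]] = None,
             require_sorted: bool = False, min_fields: int = 3) -> pd.DataFrame:
    """Validating BED reader; extra columns are kept as strings."""
    rows = []
    n_extra = 0
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < min_fields:
                raise FormatError(f"expected >= {min_fields} fields, got {len(parts)}",
                                  line=ln, path=path)
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError("non-integer coordinates", line=ln, path=path)
            if start < 0 or end <= start:
                raise FormatError(f"invalid interval [{start}, {end})",
                                  line=ln, path=path)
            if chrom_lengths is not None:
                if chrom not in chrom_lengths:
                    raise FormatError(f"unknown chromosome {chrom!r}", line=ln, path=path)
                if end > chrom_lengths[chrom]:
                    raise FormatError(
                        f"interval end {end} beyond chromosome length "
                        f"{chrom_lengths[chrom]} (1-based input declared as BED?)",
                        line=ln, path=path)
            n_extra = max(n_extra, len(parts) - 3)
            rows.append((chrom, start, end, *parts[3:]))
    cols = ["chrom", "start", "end"] + [f"field{i + 4}" for i in range(n_extra)]
    df = pd.DataFrame([r + ("",) * (len(cols) - len(r)) for r in rows], columns=cols)
    if len(df):
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
    if require_sorted:
        for chrom, grp in df.groupby("chrom", sort=False):
            if np.any(np.diff(grp["start"].to_numpy()) < 0):
                raise FormatError(f"BED not position-sorted on {chrom}", path=path)
    return df


def write_bedgraph(chrom: str, positions: np.ndarray, values: np.ndarray,
                   path: str, span: int = 1) -> None:
    with open(path, "w") as fh:
        for p, v in zip(positions, values):
            fh.write(f"{chrom}\t{p}\t{p + span}\t{v:.6g}\n")


def track_from_bed(name: str, df: pd.DataFrame, kind: str = "interval") -> AnnotationTrack:
    data = {}
    for chrom, grp in df.groupby("chrom", sort=True):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        data[chrom] = np.sort(s) if kind == "point" else \
            (s[np.argsort(s)], e[np.argsort(s)])
    return AnnotationTrack(name, kind, data)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path: str,
              chrom_lengths: Optional[Mapping[str, int]] = None) -> None:
    """Write dosages as an uncompressed VCF with GT (rounded) and DS fields."""
    header = pysam.VariantHeader()
    chroms = sorted(set(genotypes.snps["chrom"]))
    for c in chroms:
        header.contigs.add(c, length=None if chrom_lengths is None
                           else int(chrom_lengths[c]))
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DS", 1, "Float", "Alternate allele dosage")
    header.info.add("CPGSNP", 0, "Flag", "Alleles create or abolish a CpG")
    for s in genotypes.subjects:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for j, row in genotypes.snps.iterrows():
            rec = vcf.new_record(contig=row["chrom"], start=int(row["pos"]),
                                 stop=int(row["pos"]) + 1, id=row["snp"],
                                 alleles=(row["ref"], row["alt"]))
            if bool(row.get("is_cpg_snp", False)):
                rec.info["CPGSNP"] = True
            ds = genotypes.dosages[:, j]
            for i, s in enumerate(genotypes.subjects):
                hard = int(round(ds[i]))
                rec.samples[s]["GT"] = ((0, 0), (0, 1), (1, 1))[min(2, max(0, hard))]
                rec.samples[s]["DS"] = float(ds[i])
            vcf.write(rec)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a VCF back into a dosage matrix (DS preferred, GT fallback)."""
    with pysam.VariantFile(path) as vcf:
        subjects = list(vcf.header.samples)
        rows, cols = [], []
        for rec in vcf:
            rows.append((rec.id, rec.contig, rec.start, rec.ref, rec.alts[0],
                         "CPGSNP" in rec.info))
            col = np.empty(len(subjects))
            for i, s in enumerate(subjects):
                smp = rec.samples[s]
                if "DS" in smp and smp["DS"] is not None:
                    col[i] = float(smp["DS"])
                else:
                    col[i] = sum(a or 0 for a in smp["GT"])
            cols.append(col)
    snps = pd.DataFrame(rows, columns=["snp", "chrom", "pos", "ref", "alt",
                                       "is_cpg_snp"])
    dosages = np.column_stack(cols) if cols else np.empty((len(subjects), 0))
    freq = dosages.mean(axis=0) / 2.0 if len(cols) else np.empty(0)
    snps["maf"] = np.minimum(freq, 1.0 - freq)
    return GenotypeMatrix(dosages=dosages, snps=snps, subjects=subjects)


# ---------------------------------------------------------------------------
# TSV helpers
# ---------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path: str, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_matrix_tsv(matrix: np.ndarray, rows: Sequence[str],
                     cols: Sequence[str], path: str) -> None:
    pd.DataFrame(matrix, index=list(rows), columns=list(cols)).to_csv(path, sep="\t")


def read_matrix_tsv(path: str) -> Tuple[np.ndarray, List[str], List[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.index), list(df.columns)
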