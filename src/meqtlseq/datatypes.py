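"""Shared in-memory containers for the meQTL pipeline.

Coordinates are 0-based, half-open everywhere; BED is the on-disk mirror.
Chromosomes are always handled in name-sorted order so that concatenated
(genome-order) indices are reproducible across modules.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

#: Roadmap-style 18-state chromatin alphabet (active TSS through quiescent).
STATE_ALPHABET: Tuple[str, ...] = (
    "TssA", "TssFlnk", "TssFlnkU", "TssFlnkD", "Tx", "TxWk",
    "EnhG1", "EnhG2", "EnhA1", "EnhA2", "EnhWk", "ZNF_Rpts",
    "Het", "TssBiv", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)

ACTIVE_STATES = frozenset(STATE_ALPHABET[:12])
INACTIVE_STATES = frozenset(STATE_ALPHABET[12:])

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
A, C, G, T = (int(b) for b in _BASES)


@dataclass
class AnnotationTrack:
    """A named annotation: genomic points (single bp) or intervals.

    ``data`` maps chromosome name to either a sorted position array
    (kind="point") or a ``(starts, ends)`` pair of sorted-by-start arrays
    (kind="interval").
    """

    name: str
    kind: str  # "point" | "interval"
    data: Dict[str, object]

    def __post_init__(self):
        if self.kind not in ("point", "interval"):
            raise ValueError(f"unknown track kind {self.kind!r}")

    def chrom_points(self, chrom: str) -> np.ndarray:
        if self.kind != "point":
            raise ValueError("not a point track")
        return np.asarray(self.data.get(chrom, np.empty(0, dtype=np.int64)))

    def chrom_intervals(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        if self.kind != "interval":
            raise ValueError("not an interval track")
        starts, ends = self.data.get(chrom, (np.empty(0, np.int64), np.empty(0, np.int64)))
        return np.asarray(starts), np.asarray(ends)


@dataclass
class ReferenceModel:
    """Simulated genome: sequences, CpG map, centromeres, chromatin states.

    ``states[cell_type][chrom]`` is a ``(block_starts, label_codes)`` pair
    where ``block_starts[0] == 0`` and labels index :data:`STATE_ALPHABET`;
    block *i* covers ``[block_starts[i], block_starts[i+1])`` (the last block
    runs to the chromosome end), so every base carries exactly one state per
    cell type.
    """

    lengths: Dict[str, int]
    sequences: Dict[str, np.ndarray]        # uint8 ASCII ACGT
    cpg_positions: Dict[str, np.ndarray]    # position of the C of each CpG
    centromeres: Dict[str, Tuple[int, int]]
    states: List[Dict[str, Tuple[np.ndarray, np.ndarray]]]
    tracks: Dict[str, AnnotationTrack] = field(default_factory=dict)

    @property
    def chrom_names(self) -> List[str]:
        return sorted(self.lengths)

    @property
    def n_cell_types(self) -> int:
        return len(self.states)

    def sequence_str(self, chrom: str) -> str:
        return self.sequences[chrom].tobytes().decode("ascii")

    def state_at(self, chrom: str, pos, cell_type: int = 0) -> np.ndarray:
        """Chromatin-state codes at position(s) ``pos``."""
        starts, labels = self.states[cell_type][chrom]
        idx = np.searchsorted(starts, np.asarray(pos), side="right") - 1
        return labels[idx]

    def all_cpg_positions(self) -> Tuple[np.ndarray, np.ndarray]:
        """(chrom_code, position) for every CpG in genome (name-sorted) order."""
        codes, pos = [], []
        for i, c in enumerate(self.chrom_names):
            p = self.cpg_positions[c]
            codes.append(np.full(p.size, i, dtype=np.int16))
            pos.append(p)
        return np.concatenate(codes), np.concatenate(pos)


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive dosages plus a per-SNP annotation table.

    ``snps`` columns: snp, chrom, pos, ref, alt, maf, is_cpg_snp.
    Dosages count copies of the alt allele and lie in [0, 2].
    """

    dosages: np.ndarray
    snps: pd.DataFrame
    subjects: List[str]

    def __post_init__(self):
        if self.dosages.shape != (len(self.subjects), len(self.snps)):
            raise ValueError("dosage matrix shape does not match subjects/snps")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_snps(self) -> int:
        return len(self.snps)


@dataclass
class CovariateTable:
    """Observed covariates plus the latent cell-type mixture that generated
    the confounding (the mixture is never handed to the scan)."""

    table: pd.DataFrame                  # sex, batch, lab_*, mds1..mds4
    cell_mixture: np.ndarray             # n_subjects x n_cell_components, rows sum to 1
    confounding_strength: float = 0.0

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def design_matrix(self) -> pd.DataFrame:
        """Numeric design matrix (batch one-hot with first level dropped)."""
        df = self.table.copy()
        batch = pd.get_dummies(df.pop("batch"), prefix="batch", drop_first=True, dtype=float)
        return pd.concat([df.astype(float), batch], axis=1)


@dataclass
class FragmentSet:
    """Captured (methylated) MBD fragments, column-wise for speed.

    ``start`` is the leftmost base of the fragment; on the + strand the 5'
    sequencing start equals ``start``, on the - strand it is
    ``start + length - 1`` and the fragment extends toward lower coordinates.
    """

    chrom_code: np.ndarray   # int16, indexes chrom_names
    start: np.ndarray        # int64 leftmost base
    length: np.ndarray       # int32
    strand: np.ndarray       # int8: +1 / -1
    subject: np.ndarray      # int32 index into subjects
    chrom_names: List[str]
    subjects: List[str]
    read_len: int = 50

    def __len__(self) -> int:
        return self.start.size

    def to_reads(self) -> "Reads":
        pos5 = np.where(self.strand > 0, self.start, self.start + self.length - 1)
        return Reads(self.chrom_code, pos5.astype(np.int64), self.strand,
                     self.subject, self.chrom_names, self.subjects, self.read_len)


@dataclass
class Reads:
    """Aligned single-end reads; ``pos5`` is the 5' alignment start (for
    - strand reads this is the rightmost covered base)."""

    chrom_code: np.ndarray
    pos5: np.ndarray
    strand: np.ndarray
    subject: np.ndarray
    chrom_names: List[str]
    subjects: List[str]
    read_len: int = 50

    def __len__(self) -> int:
        return self.pos5.size

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)


@dataclass
class CoverageMatrix:
    """Expected-fragment-coverage methylation measures.

    ``values[i, j]`` is subject *i*'s expected number of captured fragments
    covering CpG *j*; CpGs are in genome (name-sorted chromosome) order.
    """

    values: np.ndarray            # n_subjects x n_cpgs
    chrom_code: np.ndarray        # per CpG
    positions: np.ndarray         # per CpG
    chrom_names: List[str]
    subjects: List[str]

    @property
    def n_cpgs(self) -> int:
        return self.positions.size


@dataclass
class FragmentSizeModel:
    """Empirical fragment-size survival: S(d) = P(fragment extends >= d bp
    beyond its 5' start). The sequenced read makes d < read_len certain."""

    survival: np.ndarray
    read_len: int

    def __post_init__(self):
        s = np.asarray(self.survival, dtype=float)
        if s.ndim != 1 or s.size < self.read_len:
            raise ValueError("survival must cover at least the read length")
        if abs(s[0] - 1.0) > 1e-9 or np.any(np.diff(s) > 1e-9):
            raise ValueError("survival must start at 1 and be non-increasing")
        if np.any(s[: self.read_len] < 1.0 - 1e-9):
            raise ValueError("survival must be 1 within the sequenced read")
        self.survival = s

    @property
    def d_max(self) -> int:
        return self.survival.size - 1

    def prob_covers(self, d) -> np.ndarray:
        """P(fragment with 5' start d bp from the CpG covers it); 0 beyond d_max."""
        d = np.asarray(d)
        out = np.zeros(d.shape, dtype=float)
        ok = (d >= 0) & (d <= self.d_max)
        out[ok] = self.survival[d[ok]]
        return out


@dataclass
class ReplicationResult:
    """pi1 = estimated fraction of true positives among carried-forward pairs."""

    pi1: float
    lambda_: float
    n_pairs: int
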