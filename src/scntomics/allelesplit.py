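"""SNP-based assignment of reads to the maternal or paternal allele.

A read votes for an allele at every usable informative SNP it covers.  In
bisulfite mode a SNP is unusable on a given strand when conversion chemistry
can mimic the other allele: C/T SNPs (either orientation) for original-top
reads and G/A SNPs for original-bottom reads, because unmethylated C reads
as T on the top strand and as A (reference frame G) on the bottom strand.
On a usable SNP, allele C additionally matches a read T on the top strand
and allele G matches a read A on the bottom strand, since the converted base
is still diagnostic when the other allele cannot produce it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .reads import A, C, G, ReadSet, STRAND_BOTTOM, STRAND_TOP, T
from .variants import InformativeSnp, build_snp_index


class Verdict(str, Enum):
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    UNASSIGNED = "unassigned"
    CONFLICTING = "conflicting"


MODES = ("dna", "rna", "bisulfite")


@dataclass
class AlleleAssignment:
    read_id: str
    verdict: Verdict
    n_maternal: int
    n_paternal: int
    n_mismatch: int = 0  # SNP overlaps where the read base matched neither allele


def _usable(mat: int, pat: int, strand: int, mode: str) -> bool:
    if mode != "bisulfite":
        return True
    pair = {mat, pat}
    if strand == STRAND_TOP:
        return pair != {C, T}
    return pair != {G, A}


def _matches(base: int, allele: int, strand: int, mode: str) -> bool:
    if base == allele:
        return True
    if mode != "bisulfite":
        return False
    if strand == STRAND_TOP and allele == C and base == T:
        return True
    if strand == STRAND_BOTTOM and allele == G and base == A:
        return True
    return False


_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


def classify_read(
    chrom: str,
    start: int,
    seq: str,
    snp_index: dict,
    mode: str = "dna",
    strand: int = STRAND_TOP,
    cigar: str | None = None,
    read_id: str = "read",
) -> AlleleAssignment:
    """Classify a single aligned read (``start`` 0-based; spliced N gaps ok)."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if chrom not in snp_index:
        raise ValueError(f"read {read_id} on unknown chromosome {chrom}")
    snp_map, mat, pat = snp_index[chrom]
    # expand CIGAR into (ref_pos, query_pos) pairs over M/=/X blocks
    pairs: list[tuple[int, int]] = []
    if cigar is None:
        pairs = [(start + i, i) for i in range(len(seq))]
    else:
        rpos, qpos = start, 0
        for length, op in ((int(n), op) for n, op in _CIGAR_RE.findall(cigar)):
            if op in "M=X":
                pairs.extend((rpos + i, qpos + i) for i in range(length))
                rpos += length
                qpos += length
            elif op in "DN":
                rpos += length
            elif op in "IS":
                qpos += length
            # H/P consume nothing relevant
    n_m = n_p = n_mm = 0
    for rpos, qpos in pairs:
        if rpos >= len(snp_map):
            continue
        ordinal = snp_map[rpos]
        if ordinal < 0:
            continue
        m_al, p_al = int(mat[ordinal]), int(pat[ordinal])
        if not _usable(m_al, p_al, strand, mode):
            continue
        base = ord(seq[qpos].upper())
        hit_m = _matches(base, m_al, strand, mode)
        hit_p = _matches(base, p_al, strand, mode)
        if hit_m and not hit_p:
            n_m += 1
        elif hit_p and not hit_m:
            n_p += 1
        elif not hit_m and not hit_p:
            n_mm += 1
    return AlleleAssignment(read_id, _verdict(n_m, n_p), n_m, n_p, n_mm)


def _verdict(n_m: int, n_p: int) -> Verdict:
    if n_m > 0 and n_p > 0:
        return Verdict.CONFLICTING
    if n_m > 0:
        return Verdict.MATERNAL
    if n_p > 0:
        return Verdict.PATERNAL
    return Verdict.UNASSIGNED


@dataclass
class SplitResult:
    verdicts: np.ndarray  # per-read verdict value strings ("maternal", ...)
    n_maternal: np.ndarray
    n_paternal: np.ndarray
    n_mismatch: np.ndarray
    partitions: dict[Verdict, ReadSet]

    def summary(self) -> pd.DataFrame:
        rows = [(v.value, len(p)) for v, p in self.partitions.items()]
        rows.append(("mismatched_base_events", int(self.n_mismatch.sum())))
        return pd.DataFrame(rows, columns=["category", "count"])


def split_dataset(reads: ReadSet, snps: list[InformativeSnp], mode: str = "dna") -> SplitResult:
    """Partition a read set into maternal / paternal / unassigned / conflicting.

    Vectorized over the whole set; partitions are disjoint and exhaustive.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    n, L = len(reads), reads.read_length
    n_m = np.zeros(n, dtype=np.int32)
    n_p = np.zeros(n, dtype=np.int32)
    n_mm = np.zeros(n, dtype=np.int32)
    index = build_snp_index(snps, reads.ref_names, reads.ref_lengths)
    offs = np.arange(L)
    for ci, chrom in enumerate(reads.ref_names):
        rmask = np.flatnonzero(reads.chrom_idx == ci)
        if rmask.size == 0:
            continue
        snp_map, mat, pat = index[chrom]
        if mat.size == 0:
            continue
        pos = reads.start[rmask, None] + offs[None, :]
        ordinal = snp_map[pos]
        has = ordinal >= 0
        if not has.any():
            continue
        ordc = np.where(has, ordinal, 0)
        mat_al = mat[ordc]
        pat_al = pat[ordc]
        strand = reads.strand[rmask, None]
        base = reads.seq[rmask]
        if mode == "bisulfite":
            is_ct = ((mat_al == C) & (pat_al == T)) | ((mat_al == T) & (pat_al == C))
            is_ga = ((mat_al == G) & (pat_al == A)) | ((mat_al == A) & (pat_al == G))
            usable = np.where(strand == STRAND_TOP, ~is_ct, ~is_ga)
            conv_m = ((strand == STRAND_TOP) & (mat_al == C) & (base == T)) | (
                (strand == STRAND_BOTTOM) & (mat_al == G) & (base == A)
            )
            conv_p = ((strand == STRAND_TOP) & (pat_al == C) & (base == T)) | (
                (strand == STRAND_BOTTOM) & (pat_al == G) & (base == A)
            )
            hit_m = (base == mat_al) | conv_m
            hit_p = (base == pat_al) | conv_p
        else:
            usable = np.ones_like(has)
            hit_m = base == mat_al
            hit_p = base == pat_al
        use = has & usable
        n_m[rmask] += (use & hit_m & ~hit_p).sum(axis=1)
        n_p[rmask] += (use & hit_p & ~hit_m).sum(axis=1)
        n_mm[rmask] += (use & ~hit_m & ~hit_p).sum(axis=1)
    verdicts = np.empty(n, dtype="<U11")
    verdicts[(n_m > 0) & (n_p > 0)] = Verdict.CONFLICTING.value
    verdicts[(n_m > 0) & (n_p == 0)] = Verdict.MATERNAL.value
    verdicts[(n_m == 0) & (n_p > 0)] = Verdict.PATERNAL.value
    verdicts[(n_m == 0) & (n_p == 0)] = Verdict.UNASSIGNED.value
    partitions = {v: reads.subset(verdicts == v.value) for v in Verdict}
    return SplitResult(verdicts, n_m, n_p, n_mm, partitions)


def allelic_fraction(
    reads: ReadSet,
    verdicts: np.ndarray,
    features: pd.DataFrame,
    min_reads: int = 10,
) -> pd.DataFrame:
    """Maternal fraction per feature from assigned reads.

    ``features`` needs columns gene_id, chrom, start, end (0-based
    half-open).  A read counts toward a feature when its aligned interval
    overlaps the feature interval.  Features with fewer than ``min_reads``
    assigned (maternal+paternal) reads are reported with ``evaluable=False``
    and a NaN fraction.
    """
    L = reads.read_length
    is_m = verdicts == Verdict.MATERNAL.value
    is_p = verdicts == Verdict.PATERNAL.value
    name_to_idx = {name: i for i, name in enumerate(reads.ref_names)}
    rows = []
    for f in features.itertuples():
        ci = name_to_idx.get(f.chrom)
        if ci is None:
            rows.append((f.gene_id, 0, 0, np.nan, False))
            continue
        overlap = (reads.chrom_idx == ci) & (reads.start < f.end) & (reads.start + L > f.start)
        nm = int((overlap & is_m).sum())
        np_ = int((overlap & is_p).sum())
        total = nm + np_
        evaluable = total >= min_reads
        frac = nm / total if total > 0 else np.nan
        rows.append((f.gene_id, nm, np_, frac if evaluable else np.nan, evaluable))
    return pd.DataFrame(
        rows, columns=["gene_id", "n_maternal", "n_paternal", "maternal_fraction", "evaluable"]
    )
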