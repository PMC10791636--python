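"""Informative-SNP selection and reference masking for a hybrid cross.

In a hybrid embryo every read that covers a site where the two parents are
homozygous for *different* alleles reveals its parental origin.  This module
hard-filters parental variant calls with the standard GATK-style inequality
set, keeps exactly the homozygous-divergent sites, and N-masks the reference
at those sites so downstream alignment/assignment carries no reference bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._coords import point_to_bed
from .reads import N, seq_to_array

#: (annotation, operator, cutoff): a record FAILS if annotation OP cutoff.
HARD_FILTERS: tuple[tuple[str, str, float], ...] = (
    ("QD", "<", 2.0),
    ("MQ", "<", 40.0),
    ("FS", ">", 60.0),
    ("SOR", ">", 3.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
)


@dataclass
class VariantRecord:
    """A biallelic site with parental genotypes and quality annotations."""

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    genotype_parent1: tuple[str, str] | None  # maternal
    genotype_parent2: tuple[str, str] | None  # paternal
    QD: float | None = None
    MQ: float | None = None
    FS: float | None = None
    SOR: float | None = None
    MQRankSum: float | None = None
    ReadPosRankSum: float | None = None

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: REF equals ALT ({self.ref_allele})")


@dataclass(frozen=True)
class InformativeSnp:
    """A homozygous-divergent parental site usable for allele assignment."""

    chrom: str
    pos: int  # 1-based
    maternal_allele: str
    paternal_allele: str

    def __post_init__(self) -> None:
        if self.maternal_allele == self.paternal_allele:
            raise ValueError(f"{self.chrom}:{self.pos}: alleles identical, not informative")


@dataclass
class FilterResult:
    passed: list[VariantRecord]
    failed: list[VariantRecord]
    fail_reasons: dict[int, list[str]] = field(default_factory=dict)  # index into input list
    missing_annotation: list[int] = field(default_factory=list)


def hard_filter_variants(records: list[VariantRecord]) -> FilterResult:
    """Apply the six-inequality hard filter; a record fails iff any holds.

    A missing annotation cannot satisfy its inequality, so the record passes
    that sub-filter but is flagged as ``missing_annotation`` (rank-sum
    annotations are routinely absent at sites without heterozygous calls).
    """
    result = FilterResult(passed=[], failed=[])
    for i, rec in enumerate(records):
        reasons: list[str] = []
        missing = False
        for name, op, cutoff in HARD_FILTERS:
            value = getattr(rec, name)
            if value is None:
                missing = True
                continue
            if (op == "<" and value < cutoff) or (op == ">" and value > cutoff):
                reasons.append(name)
        if missing:
            result.missing_annotation.append(i)
        if reasons:
            result.failed.append(rec)
            result.fail_reasons[i] = reasons
        else:
            result.passed.append(rec)
    return result


def select_informative_snps(passed: list[VariantRecord]) -> list[InformativeSnp]:
    """Keep exactly the sites where both parents are homozygous for
    different alleles; sorted by (chrom, pos)."""
    out: list[InformativeSnp] = []
    for rec in passed:
        g1, g2 = rec.genotype_parent1, rec.genotype_parent2
        if g1 is None or g2 is None:
            continue
        if g1[0] != g1[1] or g2[0] != g2[1]:
            continue  # heterozygous in either parent
        if g1[0] == g2[0]:
            continue  # same allele: uninformative
        out.append(InformativeSnp(rec.chrom, rec.pos, maternal_allele=g1[0], paternal_allele=g2[0]))
    return sorted(out, key=lambda s: (s.chrom, s.pos))


def snps_to_bed(snps: list[InformativeSnp]) -> pd.DataFrame:
    """Informative SNPs as single-base BED records (0-based half-open)."""
    rows = []
    for s in snps:
        start, end = point_to_bed(s.pos)
        rows.append((s.chrom, start, end, f"{s.maternal_allele}/{s.paternal_allele}"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def snps_to_table(snps: list[InformativeSnp]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.chrom, s.pos, s.maternal_allele, s.paternal_allele) for s in snps],
        columns=["chrom", "pos", "maternal_allele", "paternal_allele"],
    )


def snps_from_table(df: pd.DataFrame) -> list[InformativeSnp]:
    return [
        InformativeSnp(r.chrom, int(r.pos), r.maternal_allele, r.paternal_allele)
        for r in df.itertuples()
    ]


def mask_genome(
    reference: dict[str, str], snps: list[InformativeSnp]
) -> tuple[dict[str, str], pd.DataFrame]:
    """Replace every informative-SNP base with N; return (masked, BED).

    Masking is idempotent: positions already N stay N, all other bases are
    byte-identical to the input.
    """
    arrays = {name: seq_to_array(seq) for name, seq in reference.items()}
    for s in snps:
        if s.chrom not in arrays:
            raise ValueError(f"SNP {s.chrom}:{s.pos} on unknown chromosome")
        arr = arrays[s.chrom]
        if not (1 <= s.pos <= len(arr)):
            raise ValueError(f"SNP {s.chrom}:{s.pos} outside chromosome of length {len(arr)}")
        arr[s.pos - 1] = N
    masked = {name: arr.tobytes().decode("ascii") for name, arr in arrays.items()}
    return masked, snps_to_bed(snps)


def build_snp_index(snps: list[InformativeSnp], ref_names: list[str], ref_lengths: list[int]):
    """Dense per-chromosome SNP lookup used by vectorized allele splitting.

    Returns {chrom: (snp_map, mat, pat)} where ``snp_map`` maps a 0-based
    position to a SNP ordinal (-1 where no SNP) and mat/pat are uint8 allele
    codes per ordinal.
    """
    by_chrom: dict[str, list[InformativeSnp]] = {}
    for s in snps:
        by_chrom.setdefault(s.chrom, []).append(s)
    index = {}
    for name, length in zip(ref_names, ref_lengths):
        chrom_snps = sorted(by_chrom.get(name, []), key=lambda s: s.pos)
        snp_map = np.full(length, -1, dtype=np.int32)
        mat = np.array([ord(s.maternal_allele) for s in chrom_snps], dtype=np.uint8)
        pat = np.array([ord(s.paternal_allele) for s in chrom_snps], dtype=np.uint8)
        for ordinal, s in enumerate(chrom_snps):
            snp_map[s.pos - 1] = ordinal
        index[name] = (snp_map, mat, pat)
    return index
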