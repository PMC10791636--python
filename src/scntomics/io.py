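"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython, SAM through :mod:`scntomics.reads` (pysam),
VCF through pysam's VariantFile.  BED is strictly 0-based half-open; VCF and
SAM are 1-based.  All conversions between the two conventions are delegated
to :mod:`scntomics._coords`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class MalformedFileError(ValueError):
    """Raised with file, line number and offending text on parse failure."""

    def __init__(self, path: str, lineno: int, text: str, why: str):
        super().__init__(f"{path}:{lineno}: {why}: {text!r}")
        self.path, self.lineno, self.text = path, lineno, text


# ------------------------------------------------------------------- FASTA


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an ordered {name: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str, sequences: dict[str, str], width: int = 70) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# --------------------------------------------------------------------- BED

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_bed(path: str) -> pd.DataFrame:
    """Read BED3-BED6 into a DataFrame (start/end 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise MalformedFileError(path, lineno, line, "BED needs >= 3 columns")
            try:
                row = [parts[0], int(parts[1]), int(parts[2])]
            except ValueError:
                raise MalformedFileError(path, lineno, line, "non-integer BED coordinates") from None
            row += parts[3:6] + [None] * (6 - len(parts))
            rows.append(row[:6])
    df = pd.DataFrame(rows, columns=BED_COLUMNS)
    if (df["end"] <= df["start"]).any():
        bad = df[df["end"] <= df["start"]].iloc[0]
        raise ValueError(f"empty/inverted BED interval {bad['chrom']}:{bad['start']}-{bad['end']} in {path}")
    return df


def write_bed(path: str, df: pd.DataFrame) -> None:
    cols = [c for c in BED_COLUMNS if c in df.columns]
    out = df[cols].copy()
    # drop trailing all-missing optional columns so BED3 stays BED3
    while len(out.columns) > 3 and out[out.columns[-1]].isna().all():
        out = out.drop(columns=out.columns[-1])
    out.to_csv(path, sep="\t", header=False, index=False)


# --------------------------------------------------------------------- VCF


def read_vcf_subset(path: str) -> list:
    """Read a two-sample VCF into :class:`scntomics.variants.VariantRecord` rows.

    The subset understood here: CHROM, POS, REF, ALT, INFO keys
    QD/MQ/FS/SOR/MQRankSum/ReadPosRankSum, and per-sample GT for exactly the
    two parents (first sample = parent1/maternal, second = parent2/paternal).
    Multi-allelic records are skipped with a warning counter (see the
    variants module design notes).
    """
    import pysam

    from .variants import VariantRecord

    records: list[VariantRecord] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 2:
            raise ValueError(f"{path}: expected exactly 2 samples (parents), found {len(samples)}")
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue  # multi-allelic or ALT-less: excluded by design
            info = rec.info

            def fval(key):
                v = info.get(key)
                if v is None:
                    return None
                return float(v[0] if isinstance(v, tuple) else v)

            def gt(sample):
                alleles = rec.samples[sample].alleles
                if alleles is None or any(a is None for a in alleles):
                    return None
                return tuple(alleles)

            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    genotype_parent1=gt(samples[0]),
                    genotype_parent2=gt(samples[1]),
                    QD=fval("QD"),
                    MQ=fval("MQ"),
                    FS=fval("FS"),
                    SOR=fval("SOR"),
                    MQRankSum=fval("MQRankSum"),
                    ReadPosRankSum=fval("ReadPosRankSum"),
                )
            )
    return records


VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="Quality by depth">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=FS,Number=1,Type=Float,Description="FisherStrand phred">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Strand odds ratio">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQ rank sum">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Read pos rank sum">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf_subset(path: str, records: list, contig_lengths: dict[str, int]) -> None:
    """Write VariantRecords as a minimal two-sample VCF."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for name, length in contig_lengths.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tparent1\tparent2\n")
        for r in records:
            info_parts = []
            for key in ("QD", "MQ", "FS", "SOR", "MQRankSum", "ReadPosRankSum"):
                v = getattr(r, key)
                if v is not None:
                    info_parts.append(f"{key}={v:g}")
            info = ";".join(info_parts) if info_parts else "."
            alleles = [r.ref_allele, r.alt_allele]

            def gt_str(gt):
                if gt is None:
                    return "./."
                return "/".join(str(alleles.index(a)) for a in gt)

            fh.write(
                f"{r.chrom}\t{r.pos}\t.\t{r.ref_allele}\t{r.alt_allele}\t.\t.\t{info}"
                f"\tGT\t{gt_str(r.genotype_parent1)}\t{gt_str(r.genotype_parent2)}\n"
            )


# --------------------------------------------------------------------- GTF


def read_gtf_subset(path: str) -> pd.DataFrame:
    """Read gene and exon features from a GTF subset into a gene-model table.

    Returns a DataFrame with columns gene_id, chrom, start (0-based), end
    (half-open), strand, exon_starts, exon_ends (comma-joined, 0-based
    half-open).  Genes without exon lines get a single exon spanning the
    gene body.
    """
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise MalformedFileError(path, lineno, line, "GTF needs 9 columns")
            chrom, _, feature, start1, end1, _, strand, _, attrs = parts[:9]
            if feature not in ("gene", "exon"):
                continue
            try:
                start0, end = int(start1) - 1, int(end1)
            except ValueError:
                raise MalformedFileError(path, lineno, line, "non-integer GTF coordinates") from None
            gene_id = None
            for chunk in attrs.split(";"):
                chunk = chunk.strip()
                if chunk.startswith("gene_id"):
                    gene_id = chunk.split(None, 1)[1].strip('"')
                    break
            if gene_id is None:
                raise MalformedFileError(path, lineno, line, "missing gene_id attribute")
            entry = genes.setdefault(
                gene_id, {"chrom": chrom, "start": start0, "end": end, "strand": strand, "exons": []}
            )
            if feature == "gene":
                entry.update(chrom=chrom, start=start0, end=end, strand=strand)
            else:
                entry["exons"].append((start0, end))
    rows = []
    for gid, e in genes.items():
        exons = sorted(e["exons"]) or [(e["start"], e["end"])]
        rows.append(
            {
                "gene_id": gid,
                "chrom": e["chrom"],
                "start": e["start"],
                "end": e["end"],
                "strand": e["strand"],
                "exon_starts": ",".join(str(s) for s, _ in exons),
                "exon_ends": ",".join(str(x) for _, x in exons),
            }
        )
    return pd.DataFrame(rows).sort_values(["chrom", "start"], ignore_index=True)


def gene_exonic_lengths(gene_models: pd.DataFrame) -> pd.Series:
    """Total exonic bp per gene (for FPKM)."""
    out = {}
    for row in gene_models.itertuples():
        starts = [int(s) for s in str(row.exon_starts).split(",")]
        ends = [int(s) for s in str(row.exon_ends).split(",")]
        out[row.gene_id] = sum(e - s for s, e in zip(starts, ends))
    return pd.Series(out, name="length_bp")


# --------------------------------------------------------------------- TSV


def read_tsv_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv_table(path: str, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


# ----------------------------------------------------------------- bedGraph


def write_bedgraph(path: str, cpg_table: pd.DataFrame) -> None:
    """Write a CpG table (chrom, pos 1-based, meth, unmeth) as bedGraph levels."""
    cov = cpg_table["meth"] + cpg_table["unmeth"]
    out = pd.DataFrame(
        {
            "chrom": cpg_table["chrom"],
            "start": cpg_table["pos"] - 1,
            "end": cpg_table["pos"],
            "level": (cpg_table["meth"] / cov.where(cov > 0)).round(6),
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


# ------------------------------------------------------------------- misc


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing sample in a run manifest."""

    sample_id: str
    group: str  # ICSI | SCNT | SCNT-TR
    tissue: str  # blastocyst | trophoblast | EAYT | placenta | STB | oocyte | fibroblast | sperm
    replicate: int

    def key(self) -> tuple[str, str, int]:
        return (self.group, self.tissue, self.replicate)


def check_manifest(samples: list[SampleMeta]) -> None:
    keys = [s.key() for s in samples]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (group, tissue, replicate) in sample manifest")


def sha256_file(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
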