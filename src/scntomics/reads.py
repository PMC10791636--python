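"""Array-backed container for aligned read records (SAM subset).

Reads are stored column-wise in NumPy arrays so that methylation calling and
allele assignment stay vectorized even at whole-genome simulated depth.  All
reads in a set share one read length; sequences are kept on the reference
top-strand frame regardless of bisulfite strand, which keeps coordinate
arithmetic trivial (match-only CIGARs).

SAM round-trip conventions (plain-text SAM only):

* FLAG is always 0 (sequences are reference-frame).
* CIGAR is ``<L>M``.
* ``ZS:A`` carries the bisulfite strand: ``+`` for original-top, ``-`` for
  original-bottom.
* ``XA:A`` carries the simulation truth allele (``M``/``P``) when known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

# uint8 ASCII codes used throughout
A, C, G, T, N = (ord(b) for b in "ACGTN")

STRAND_TOP = 0  # original-top (OT): C->T conversion visible on reference C's
STRAND_BOTTOM = 1  # original-bottom (OB): G->A on the reference frame

ALLELE_UNKNOWN = -1
ALLELE_MATERNAL = 0
ALLELE_PATERNAL = 1

_ALLELE_TAG = {ALLELE_MATERNAL: "M", ALLELE_PATERNAL: "P"}
_TAG_ALLELE = {"M": ALLELE_MATERNAL, "P": ALLELE_PATERNAL}


def seq_to_array(seq: str) -> np.ndarray:
    """ASCII-encode a sequence string as uint8."""
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


@dataclass
class ReadSet:
    """Column-wise store of same-length aligned reads.

    Attributes
    ----------
    ref_names, ref_lengths
        The reference dictionary (order defines ``chrom_idx`` codes).
    chrom_idx
        int32 per-read reference index.
    start
        int64 per-read 0-based leftmost reference position.
    strand
        uint8 per-read bisulfite strand (``STRAND_TOP`` / ``STRAND_BOTTOM``).
        For DNA/RNA reads the field is kept at ``STRAND_TOP``.
    seq
        uint8 matrix of shape (n_reads, read_length), reference frame.
    allele_truth
        int8 simulation ground truth (-1 when unknown).
    """

    ref_names: list[str]
    ref_lengths: list[int]
    chrom_idx: np.ndarray
    start: np.ndarray
    strand: np.ndarray
    seq: np.ndarray
    allele_truth: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.start)
        if self.allele_truth is None:
            self.allele_truth = np.full(n, ALLELE_UNKNOWN, dtype=np.int8)
        if not (len(self.chrom_idx) == n == len(self.strand) == self.seq.shape[0] == len(self.allele_truth)):
            raise ValueError("inconsistent ReadSet column lengths")

    def __len__(self) -> int:
        return len(self.start)

    @property
    def read_length(self) -> int:
        return self.seq.shape[1]

    def subset(self, mask_or_index: np.ndarray) -> "ReadSet":
        return ReadSet(
            ref_names=self.ref_names,
            ref_lengths=self.ref_lengths,
            chrom_idx=self.chrom_idx[mask_or_index],
            start=self.start[mask_or_index],
            strand=self.strand[mask_or_index],
            seq=self.seq[mask_or_index],
            allele_truth=self.allele_truth[mask_or_index],
        )

    @staticmethod
    def concatenate(parts: list["ReadSet"]) -> "ReadSet":
        first = parts[0]
        for p in parts[1:]:
            if p.ref_names != first.ref_names:
                raise ValueError("cannot concatenate ReadSets over different references")
        return ReadSet(
            ref_names=first.ref_names,
            ref_lengths=first.ref_lengths,
            chrom_idx=np.concatenate([p.chrom_idx for p in parts]),
            start=np.concatenate([p.start for p in parts]),
            strand=np.concatenate([p.strand for p in parts]),
            seq=np.vstack([p.seq for p in parts]),
            allele_truth=np.concatenate([p.allele_truth for p in parts]),
        )

    # ---------------------------------------------------------------- SAM IO

    def _header(self) -> pysam.AlignmentHeader:
        return pysam.AlignmentHeader.from_references(self.ref_names, self.ref_lengths)

    def write_sam(self, path: str) -> None:
        header = self._header()
        L = self.read_length
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i in range(len(self)):
                rec = pysam.AlignedSegment(header)
                rec.query_name = f"read{i}"
                rec.flag = 0
                rec.reference_id = int(self.chrom_idx[i])
                rec.reference_start = int(self.start[i])
                rec.mapping_quality = 60
                rec.cigarstring = f"{L}M"
                rec.query_sequence = array_to_seq(self.seq[i])
                tags = [("ZS", "+" if self.strand[i] == STRAND_TOP else "-")]
                if self.allele_truth[i] != ALLELE_UNKNOWN:
                    tags.append(("XA", _ALLELE_TAG[int(self.allele_truth[i])]))
                rec.set_tags(tags)
                out.write(rec)

    @staticmethod
    def read_sam(path: str) -> "ReadSet":
        with pysam.AlignmentFile(str(path), "r") as fh:
            ref_names = list(fh.references)
            ref_lengths = list(fh.lengths)
            chrom_idx, start, strand, seqs, allele = [], [], [], [], []
            for rec in fh:
                if rec.is_unmapped:
                    continue
                chrom_idx.append(rec.reference_id)
                start.append(rec.reference_start)
                zs = rec.get_tag("ZS") if rec.has_tag("ZS") else "+"
                strand.append(STRAND_TOP if zs == "+" else STRAND_BOTTOM)
                seqs.append(seq_to_array(rec.query_sequence))
                xa = rec.get_tag("XA") if rec.has_tag("XA") else None
                allele.append(_TAG_ALLELE.get(xa, ALLELE_UNKNOWN))
        if not start:
            raise ValueError(f"no aligned records in {path}")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("mixed read lengths are not supported")
        return ReadSet(
            ref_names=ref_names,
            ref_lengths=ref_lengths,
            chrom_idx=np.asarray(chrom_idx, dtype=np.int32),
            start=np.asarray(start, dtype=np.int64),
            strand=np.asarray(strand, dtype=np.uint8),
            seq=np.vstack(seqs),
            allele_truth=np.asarray(allele, dtype=np.int8),
        )
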