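"""Differentially methylated region calling between two conditions.

Per-CpG differences are tested with Fisher's exact test on the 2x2 count
table, then sign-consistent significant CpGs are chained into candidate
regions (gap-limited), and candidates are filtered on three criteria at
once: a minimum number of covered CpGs, a minimum number of significantly
different CpGs, and a minimum absolute mean methylation difference.
Direction is reported relative to condition B minus condition A, i.e. with
A = control (ICSI) and B = test (SCNT), ``hypo`` means lower methylation in
SCNT and ``hyper`` means higher.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: relative tolerance when comparing hypergeometric point masses (two-sided
#: Fisher sums all tables whose probability does not exceed the observed one;
#: the epsilon absorbs floating-point noise in ties, as in common practice)
_REL_EPS = 1e-7


def cpg_test(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    """Two-sided Fisher exact p for one CpG's 2x2 table."""
    return float(
        cpg_test_array(
            np.array([meth_a]), np.array([unmeth_a]), np.array([meth_b]), np.array([unmeth_b])
        )[0]
    )


def cpg_test_array(meth_a, unmeth_a, meth_b, unmeth_b) -> np.ndarray:
    """Vectorized two-sided Fisher exact test over many 2x2 tables.

    For each table the p-value is the sum of hypergeometric point
    probabilities not exceeding that of the observed table (the standard
    two-sided definition).  Implemented via broadcast ``hypergeom.logpmf``
    over the shared support, which keeps whole-genome CpG testing vectorized.
    """
    a = np.asarray(meth_a, dtype=np.int64)
    b = np.asarray(unmeth_a, dtype=np.int64)
    c = np.asarray(meth_b, dtype=np.int64)
    d = np.asarray(unmeth_b, dtype=np.int64)
    if np.any((a < 0) | (b < 0) | (c < 0) | (d < 0)):
        raise ValueError("negative counts in 2x2 table")
    n_tot = a + b + c + d
    if np.any(n_tot == 0):
        raise ValueError("all-zero 2x2 table")
    row1 = a + b  # condition A total
    col1 = a + c  # methylated total
    kmin = np.maximum(0, row1 + col1 - n_tot)
    kmax = np.minimum(row1, col1)
    width = int((kmax - kmin).max()) + 1
    ks = kmin[:, None] + np.arange(width)[None, :]
    valid = ks <= kmax[:, None]
    ksafe = np.where(valid, ks, kmin[:, None])
    logpmf = stats.hypergeom.logpmf(ksafe, n_tot[:, None], col1[:, None], row1[:, None])
    pmf = np.where(valid, np.exp(logpmf), 0.0)
    obs = pmf[np.arange(len(a)), (a - kmin)]
    keep = pmf <= obs[:, None] * (1 + _REL_EPS)
    return np.minimum((pmf * keep).sum(axis=1), 1.0)


@dataclass
class DMRCallParams:
    """Region-calling thresholds.

    The two 25s mirror the region contract (>= 25 covered CpGs and >= 25
    significantly different CpGs); ``min_mean_diff`` is the 25% methylation
    difference floor.  All three are enforced together and independently
    configurable.
    """

    min_cpgs: int = 25
    min_sig_cpgs: int = 25
    min_mean_diff: float = 0.25
    alpha: float = 0.05  # per-CpG, unadjusted
    max_gap_bp: int = 1000
    #: consecutive qualifying CpGs may be separated by at most this many
    #: covered-but-non-qualifying CpGs.  The bp gap allowance alone would
    #: happily bridge a dense stretch of clearly-unchanged CpGs to reach an
    #: isolated per-CpG false positive; this companion constraint keeps runs
    #: locally supported.  Interior gaps up to 2 tolerate occasional power
    #: losses inside a genuine region without splitting it.
    max_gap_cpgs: int = 2
    #: run *ends* are held to a stricter standard than the interior: a
    #: terminal qualifying CpG separated from its inner neighbour by 2+
    #: non-qualifying CpGs is overwhelmingly an attached false positive and
    #: is trimmed, so called boundaries track the true region edges.
    max_end_gap_cpgs: int = 1

    def __post_init__(self) -> None:
        if self.min_cpgs < 1:
            raise ValueError("min_cpgs must be >= 1")
        if not (0 < self.min_mean_diff <= 1):
            raise ValueError("min_mean_diff must be in (0, 1]")


@dataclass
class DMR:
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    n_cpgs: int
    n_sig_cpgs: int
    mean_diff: float  # test - control, signed
    direction: str = field(init=False)

    def __post_init__(self) -> None:
        self.direction = "hypo" if self.mean_diff < 0 else "hyper"

    @property
    def length_bp(self) -> int:
        return self.end - self.start


def _join_tables(table_a: pd.DataFrame, table_b: pd.DataFrame) -> pd.DataFrame:
    if len(table_a) and len(table_b):
        if not set(table_a["chrom"]) & set(table_b["chrom"]):
            raise ValueError("CpG tables share no chromosome; are they on the same reference?")
    merged = table_a.merge(table_b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    cov_a = merged["meth_a"] + merged["unmeth_a"]
    cov_b = merged["meth_b"] + merged["unmeth_b"]
    merged = merged[(cov_a > 0) & (cov_b > 0)].reset_index(drop=True)
    return merged


def segment_dmrs(
    table_a: pd.DataFrame, table_b: pd.DataFrame, params: DMRCallParams | None = None
) -> list[DMR]:
    """Call DMRs of B (test) relative to A (control).

    CpG tables carry chrom, pos (1-based), meth, unmeth.  A CpG qualifies
    when its Fisher p < alpha and its level difference is sign-consistent
    with the run being built; runs break when the gap between consecutive
    qualifying CpGs exceeds ``max_gap_bp`` or the sign flips.  A run becomes
    a DMR when it holds >= min_cpgs covered CpGs, >= min_sig_cpgs qualifying
    CpGs, and |mean level difference| over all covered CpGs in its span
    >= min_mean_diff.  Coordinates span the first to last covered CpG of the
    run (half-open end = last pos + 1... of the qualifying extent).
    """
    params = params or DMRCallParams()
    merged = _join_tables(table_a, table_b)
    if merged.empty:
        return []
    p = cpg_test_array(
        merged["meth_a"].to_numpy(),
        merged["unmeth_a"].to_numpy(),
        merged["meth_b"].to_numpy(),
        merged["unmeth_b"].to_numpy(),
    )
    level_a = merged["meth_a"] / (merged["meth_a"] + merged["unmeth_a"])
    level_b = merged["meth_b"] / (merged["meth_b"] + merged["unmeth_b"])
    diff = (level_b - level_a).to_numpy()
    sig = (p < params.alpha) & (diff != 0)
    sign = np.sign(diff)
    dmrs: list[DMR] = []
    for chrom, sub in merged.groupby("chrom", sort=True):
        idx = sub.index.to_numpy()
        pos = sub["pos"].to_numpy()
        for run in _runs(idx, pos, sig, sign, params.max_gap_bp, params.max_gap_cpgs):
            run = _trim_ends(run, idx, params.max_end_gap_cpgs)
            first, last = run[0], run[-1]
            span = idx[(idx >= first) & (idx <= last)]
            n_cpgs = len(span)
            n_sig = len(run)
            mean_diff = float(diff[span].mean())
            if (
                n_cpgs >= params.min_cpgs
                and n_sig >= params.min_sig_cpgs
                and abs(mean_diff) >= params.min_mean_diff
            ):
                start0 = int(pos[np.searchsorted(idx, first)] - 1)
                end = int(pos[np.searchsorted(idx, last)])
                dmrs.append(DMR(chrom, start0, end, n_cpgs, n_sig, mean_diff))
    return dmrs


def _trim_ends(run: list[int], idx: np.ndarray, max_end_gap_cpgs: int) -> list[int]:
    """Iteratively drop terminal qualifying CpGs separated from the run
    interior by more than ``max_end_gap_cpgs`` covered non-qualifying CpGs."""
    ranks = list(np.searchsorted(idx, run))
    lo, hi = 0, len(run) - 1
    while lo < hi and ranks[lo + 1] - ranks[lo] - 1 > max_end_gap_cpgs:
        lo += 1
    while hi > lo and ranks[hi] - ranks[hi - 1] - 1 > max_end_gap_cpgs:
        hi -= 1
    return run[lo : hi + 1]


def _runs(
    idx: np.ndarray,
    pos: np.ndarray,
    sig: np.ndarray,
    sign: np.ndarray,
    max_gap_bp: int,
    max_gap_cpgs: int,
):
    """Yield lists of global indices of sign-consistent qualifying CpGs.

    A run breaks when the sign flips, the genomic gap between consecutive
    qualifying CpGs exceeds ``max_gap_bp``, or more than ``max_gap_cpgs``
    covered-but-non-qualifying CpGs intervene.
    """
    current: list[int] = []
    cur_sign = 0.0
    last_pos = None
    last_rank = None
    for rank, gi in enumerate(idx):
        if not sig[gi]:
            continue
        s = sign[gi]
        p = pos[rank]
        if current and (
            s != cur_sign or p - last_pos > max_gap_bp or rank - last_rank - 1 > max_gap_cpgs
        ):
            yield current
            current = []
        current.append(gi)
        cur_sign = s
        last_pos = p
        last_rank = rank
    if current:
        yield current


# -------------------------------------------------------------- annotation

FEATURE_PRIORITY = ("promoter", "exon", "intron", "TTS", "intergenic")
PROMOTER_UP = 1000
PROMOTER_DOWN = 100


def annotate_dmrs(dmrs: list[DMR], gene_models: pd.DataFrame) -> list[str]:
    """Genomic-context category of each DMR by its midpoint.

    Priority promoter > exon > intron > TTS > intergenic.  The promoter is
    [-1000, +100] bp around the strand-aware gene start; the TTS window is
    the mirror image at the gene end.  ``gene_models`` is the table produced
    by :func:`scntomics.io.read_gtf_subset`.
    """
    categories = []
    for d in dmrs:
        mid = (d.start + d.end) // 2
        categories.append(_categorize_point(d.chrom, mid, gene_models))
    return categories


def _categorize_point(chrom: str, point: int, gene_models: pd.DataFrame) -> str:
    hits = {"promoter": False, "exon": False, "intron": False, "TTS": False}
    for g in gene_models.itertuples():
        if g.chrom != chrom:
            continue
        if g.strand == "+":
            prom = (g.start - PROMOTER_UP, g.start + PROMOTER_DOWN)
            tts = (g.end - PROMOTER_DOWN, g.end + PROMOTER_UP)
        else:
            prom = (g.end - PROMOTER_DOWN, g.end + PROMOTER_UP)
            tts = (g.start - PROMOTER_UP, g.start + PROMOTER_DOWN)
        if prom[0] <= point < prom[1]:
            hits["promoter"] = True
        if tts[0] <= point < tts[1]:
            hits["TTS"] = True
        if g.start <= point < g.end:
            in_exon = False
            for s, e in zip(str(g.exon_starts).split(","), str(g.exon_ends).split(",")):
                if int(s) <= point < int(e):
                    in_exon = True
                    break
            hits["exon" if in_exon else "intron"] = True
    for cat in FEATURE_PRIORITY[:-1]:
        if hits[cat]:
            return cat
    return "intergenic"


def dmr_summary(dmrs: list[DMR]) -> pd.DataFrame:
    """Counts and mean/median length (bp) per direction."""
    rows = []
    for direction in ("hypo", "hyper"):
        lengths = [d.length_bp for d in dmrs if d.direction == direction]
        rows.append(
            {
                "direction": direction,
                "count": len(lengths),
                "mean_length_bp": float(np.mean(lengths)) if lengths else 0.0,
                "median_length_bp": float(np.median(lengths)) if lengths else 0.0,
            }
        )
    return pd.DataFrame(rows)


def map_genes_to_dmrs(
    genes: pd.DataFrame, dmrs: list[DMR], window_bp: int = 10_000
) -> dict[str, list[int]]:
    """Genes whose body extended by ``window_bp`` overlaps at least one DMR.

    Returns {gene_id: [dmr indices]} for associated genes only.
    """
    out: dict[str, list[int]] = {}
    for g in genes.itertuples():
        lo, hi = g.start - window_bp, g.end + window_bp
        hit = [i for i, d in enumerate(dmrs) if d.chrom == g.chrom and d.start < hi and d.end > lo]
        if hit:
            out[g.gene_id] = hit
    return out


def dmrs_to_bed(dmrs: list[DMR]) -> pd.DataFrame:
    """DMRs as BED6 (name=direction, score=1000*|mean_diff| clipped)."""
    return pd.DataFrame(
        [
            (
                d.chrom,
                d.start,
                d.end,
                d.direction,
                int(min(1000, round(1000 * abs(d.mean_diff)))),
                ".",
            )
            for d in dmrs
        ],
        columns=["chrom", "start", "end", "name", "score", "strand"],
    )
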