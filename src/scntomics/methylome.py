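"""Per-CpG methylation calling and summaries from aligned bisulfite reads.

A CpG site is identified on the reference top strand (the C of a C-G
dinucleotide).  Original-top reads report the C itself (C = methylated,
T = unmethylated); original-bottom reads report the paired G one base
downstream (G = methylated, A = unmethylated) and are merged to the
top-strand coordinate by default, the usual symmetric-CpG treatment.
Positions are 1-based in the CpG table, matching the SAM/VCF side of the
coordinate convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reads import A, C, G, ReadSet, STRAND_BOTTOM, STRAND_TOP, T, seq_to_array

CPG_COLUMNS = ["chrom", "pos", "meth", "unmeth"]


def _accumulate(reads: ReadSet, reference: dict[str, str], cpg_only: bool, merge_symmetric: bool):
    """Shared counting core: returns {(chrom[, strand]): {pos: [meth, unmeth]}} arrays."""
    out_frames = []
    offs = np.arange(reads.read_length)
    for ci, chrom in enumerate(reads.ref_names):
        if not np.any(reads.chrom_idx == ci):
            continue
        if chrom not in reference:
            raise ValueError(f"reference is missing chromosome {chrom}")
        ref = seq_to_array(reference[chrom])
        clen = len(ref)
        is_c = ref == C
        is_g = ref == G
        if cpg_only:
            c_site = np.zeros(clen, dtype=bool)
            c_site[:-1] = is_c[:-1] & is_g[1:]
            g_site = np.zeros(clen, dtype=bool)
            g_site[1:] = is_g[1:] & is_c[:-1]
        else:  # all cytosine contexts (used for spike-in conversion estimation)
            c_site, g_site = is_c, is_g
        def strand_counts(strand_val, site_mask, meth_base, unmeth_base):
            rows = np.flatnonzero((reads.chrom_idx == ci) & (reads.strand == strand_val))
            if rows.size == 0:
                z = np.zeros(clen, dtype=np.int64)
                return z, z.copy()
            pos = reads.start[rows, None] + offs[None, :]
            inb = pos < clen
            posc = np.where(inb, pos, 0)
            at = inb & site_mask[posc]
            base = reads.seq[rows]
            meth = np.bincount(posc[at & (base == meth_base)], minlength=clen)
            unmeth = np.bincount(posc[at & (base == unmeth_base)], minlength=clen)
            return meth, unmeth

        # top-strand evidence at C sites; bottom-strand evidence at G sites
        # (the latter shifts -1 onto the C coordinate on merge)
        m_top, u_top = strand_counts(STRAND_TOP, c_site, C, T)
        m_bot, u_bot = strand_counts(STRAND_BOTTOM, g_site, G, A)
        if merge_symmetric and cpg_only:
            # shift bottom-strand G counts onto the C coordinate
            m = m_top.copy()
            u = u_top.copy()
            m[:-1] += m_bot[1:]
            u[:-1] += u_bot[1:]
            covered = np.flatnonzero(m + u)
            out_frames.append(
                pd.DataFrame(
                    {"chrom": chrom, "pos": covered + 1, "meth": m[covered], "unmeth": u[covered]}
                )
            )
        else:
            covered_t = np.flatnonzero(m_top + u_top)
            covered_b = np.flatnonzero(m_bot + u_bot)
            frames = []
            if covered_t.size:
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": covered_t + 1,
                            "meth": m_top[covered_t],
                            "unmeth": u_top[covered_t],
                            "strand": "+",
                        }
                    )
                )
            if covered_b.size:
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": chrom,
                            "pos": covered_b + 1,
                            "meth": m_bot[covered_b],
                            "unmeth": u_bot[covered_b],
                            "strand": "-",
                        }
                    )
                )
            if frames:
                out_frames.append(pd.concat(frames, ignore_index=True))
    if not out_frames:
        cols = CPG_COLUMNS if merge_symmetric and cpg_only else CPG_COLUMNS + ["strand"]
        return pd.DataFrame(columns=cols)
    return pd.concat(out_frames, ignore_index=True).sort_values(["chrom", "pos"], ignore_index=True)


def call_cpg_methylation(
    reads: ReadSet, reference: dict[str, str], merge_symmetric: bool = True
) -> pd.DataFrame:
    """Count methylated/unmethylated calls per CpG.

    Returns a table (chrom, pos 1-based, meth, unmeth[, strand]).  With
    ``merge_symmetric`` (default) the bottom-strand G evidence is pooled onto
    the top-strand C coordinate; merging never changes the genome-wide total
    of meth+unmeth calls.
    """
    return _accumulate(reads, reference, cpg_only=True, merge_symmetric=merge_symmetric)


def add_level(cpg_table: pd.DataFrame) -> pd.DataFrame:
    cov = cpg_table["meth"] + cpg_table["unmeth"]
    out = cpg_table.copy()
    out["coverage"] = cov
    out["level"] = cpg_table["meth"] / cov.where(cov > 0)
    return out


@dataclass
class ConversionEstimate:
    efficiency: float | None
    n_converted: int
    n_total: int
    status: str  # "ok" | "no_coverage"


def conversion_efficiency(
    reads: ReadSet, reference: dict[str, str], spike_contig: str = "lambda_spike"
) -> ConversionEstimate:
    """Bisulfite conversion efficiency from the unmethylated spike-in contig.

    Pooled over *all* cytosine contexts of the spike-in:
    efficiency = converted / (converted + unconverted).  Since the spike-in
    carries no methylation, every retained C (or reference-frame G on bottom
    strand reads) is a conversion failure.
    """
    if spike_contig not in reads.ref_names:
        raise ValueError(f"spike-in contig {spike_contig!r} absent from read set reference")
    ci = reads.ref_names.index(spike_contig)
    sub = reads.subset(reads.chrom_idx == ci)
    if len(sub) == 0:
        return ConversionEstimate(None, 0, 0, "no_coverage")
    table = _accumulate(
        sub, {spike_contig: reference[spike_contig]}, cpg_only=False, merge_symmetric=False
    )
    if table.empty:
        return ConversionEstimate(None, 0, 0, "no_coverage")
    unconverted = int(table["meth"].sum())  # C retained = conversion failure
    converted = int(table["unmeth"].sum())
    total = converted + unconverted
    if total == 0:
        return ConversionEstimate(None, 0, 0, "no_coverage")
    return ConversionEstimate(converted / total, converted, total, "ok")


def window_levels(
    cpg_table: pd.DataFrame,
    window_size: int = 10_000,
    min_cpgs: int = 1,
    min_coverage: int = 1,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Tile the genome in fixed windows; per-window unweighted mean CpG level.

    Only CpGs with coverage >= ``min_coverage`` enter a window; windows with
    fewer than ``min_cpgs`` qualifying CpGs are omitted.  Terminal partial
    windows are emitted and flagged (``partial=True``) when chromosome
    lengths are supplied.
    """
    t = add_level(cpg_table)
    t = t[t["coverage"] >= min_coverage]
    if t.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "end", "mean_level", "n_cpgs", "total_coverage", "partial"]
        )
    t = t.assign(win=(t["pos"] - 1) // window_size)
    grouped = t.groupby(["chrom", "win"], sort=True)
    agg = grouped.agg(
        mean_level=("level", "mean"), n_cpgs=("level", "size"), total_coverage=("coverage", "sum")
    ).reset_index()
    agg = agg[agg["n_cpgs"] >= min_cpgs]
    agg["start"] = agg["win"] * window_size
    agg["end"] = agg["start"] + window_size
    agg["partial"] = False
    if chrom_lengths is not None:
        for chrom, length in chrom_lengths.items():
            sel = agg["chrom"] == chrom
            agg.loc[sel & (agg["end"] > length), "partial"] = True
            agg.loc[sel, "end"] = np.minimum(agg.loc[sel, "end"], length)
    return agg[["chrom", "start", "end", "mean_level", "n_cpgs", "total_coverage", "partial"]].reset_index(
        drop=True
    )


def global_level(cpg_table: pd.DataFrame) -> dict[str, float]:
    """Genome-wide methylation: coverage-weighted and per-CpG unweighted means."""
    t = add_level(cpg_table)
    t = t[t["coverage"] > 0]
    if t.empty:
        return {"weighted": float("nan"), "unweighted": float("nan"), "n_cpgs": 0}
    weighted = float(t["meth"].sum() / t["coverage"].sum())
    return {"weighted": weighted, "unweighted": float(t["level"].mean()), "n_cpgs": int(len(t))}


def compare_window_sets(values_a, values_b, exact_max_n: int = 50) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum comparison of two window-level sets.

    Uses the exact null distribution for small tie-free samples and the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both window sets must be non-empty")
    no_ties = np.unique(np.concatenate([a, b])).size == a.size + b.size
    method = "exact" if (a.size + b.size < exact_max_n and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "p_value": float(res.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "method": method,
    }


@dataclass
class MetaProfile:
    """Mean methylation over scaled region bodies with fixed-width flanks."""

    bin_means: np.ndarray  # length flank_bins + body_bins + flank_bins
    bin_counts: np.ndarray  # CpG observations per bin
    body_bins: int
    flank_bins: int
    flank_bp: int
    region_set: str = ""

    @property
    def n_bins(self) -> int:
        return 2 * self.flank_bins + self.body_bins


def region_metaprofile(
    regions: pd.DataFrame,
    cpg_table: pd.DataFrame,
    body_bins: int = 20,
    flank_bp: int = 5000,
    flank_bins: int = 10,
    region_set: str = "",
) -> MetaProfile:
    """Average CpG methylation across regions, body rescaled, flanks in bp.

    ``regions`` needs chrom/start/end (0-based half-open).  Per-bin value is
    the unweighted mean of per-CpG levels pooled over all regions.
    """
    if ((regions["end"] - regions["start"]) <= 0).any():
        raise ValueError("degenerate region (end <= start)")
    t = add_level(cpg_table)
    t = t[t["coverage"] > 0]
    n_bins = 2 * flank_bins + body_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for reg in regions.itertuples():
        sel = t[(t["chrom"] == reg.chrom)]
        if sel.empty:
            continue
        pos0 = sel["pos"].to_numpy() - 1
        level = sel["level"].to_numpy()
        length = reg.end - reg.start
        # upstream flank
        rel = pos0 - (reg.start - flank_bp)
        in_up = (rel >= 0) & (pos0 < reg.start)
        bins_up = np.minimum((rel[in_up] * flank_bins) // flank_bp, flank_bins - 1)
        np.add.at(sums, bins_up.astype(int), level[in_up])
        np.add.at(counts, bins_up.astype(int), 1)
        # body, rescaled
        in_body = (pos0 >= reg.start) & (pos0 < reg.end)
        bins_body = flank_bins + np.minimum(
            ((pos0[in_body] - reg.start) * body_bins) // length, body_bins - 1
        )
        np.add.at(sums, bins_body.astype(int), level[in_body])
        np.add.at(counts, bins_body.astype(int), 1)
        # downstream flank
        rel_d = pos0 - reg.end
        in_down = (rel_d >= 0) & (rel_d < flank_bp)
        bins_down = flank_bins + body_bins + np.minimum((rel_d[in_down] * flank_bins) // flank_bp, flank_bins - 1)
        np.add.at(sums, bins_down.astype(int), level[in_down])
        np.add.at(counts, bins_down.astype(int), 1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return MetaProfile(means, counts, body_bins, flank_bins, flank_bp, region_set)
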