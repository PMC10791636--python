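"""Expression quantification, differential expression and imprinting calls.

The differential-expression engine is a self-contained negative-binomial
Wald test: median-of-ratios size factors, method-of-moments dispersion with
a floor, and a t-referenced Wald statistic on the log2 fold change of
normalized group means.  The contract is threshold semantics (p < 0.01,
fold change > 2, baseMean > 10), not bit-compatibility with any external
engine.

The imprinted-gene filtration cascade proceeds:

1. candidate imprinted genes expressed in both groups (FPKM > 1 in each);
2. of those, genes associated with a DMR (gene body +/- window);
3. of those, genes with an aberrant FPKM ratio (fold change > 2 or < 0.5).

A parallel route intersects the DEG set with the candidate list and then
applies the DMR-association filter.  Loss of imprinting (LOI) is called for
a gene whose expression is monoallelic in the control but biallelic in the
test group, or whose control-side maternal methylation bias is lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .dmr import DMR, map_genes_to_dmrs

DISPERSION_FLOOR = 0.01


def packaged_imprint_list() -> pd.DataFrame:
    """The bundled candidate imprinted-gene table.

    A synthetic stand-in that mimics the structure of public imprinted-gene
    catalogues (gene, status, expressed allele); substitute a real catalogue
    TSV with the same columns for production use.
    """
    from importlib import resources

    with resources.files("scntomics.data").joinpath("imprint_candidates_synthetic.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# ------------------------------------------------------------------- FPKM


def compute_fpkm(
    counts: pd.DataFrame, gene_lengths: pd.Series, library_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """FPKM = count / (exonic kb x mapped millions), per gene x sample.

    ``counts`` is genes x samples.  ``library_sizes`` defaults to the column
    sums of the count matrix.
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = lengths.index[lengths.isna() | (lengths <= 0)][0]
        raise ValueError(f"missing or non-positive exonic length for gene {bad!r}")
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    denom = np.outer(lengths / 1e3, library_sizes / 1e6)
    return counts / denom


# --------------------------------------------------- differential expression


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (genes with all-positive counts)."""
    log_counts = np.log(counts.where(counts > 0))
    log_geomean = log_counts.mean(axis=1)
    usable = log_geomean.notna() & np.isfinite(log_geomean) & counts.gt(0).all(axis=1)
    if not usable.any():
        raise ValueError("no gene has positive counts in every sample; cannot normalize")
    ratios = log_counts.loc[usable].sub(log_geomean[usable], axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


def _mom_dispersion(norm_a: pd.DataFrame, norm_b: pd.DataFrame) -> pd.Series:
    """Moderated method-of-moments NB dispersion.

    Per-gene dispersion is the within-group pooled method-of-moments
    estimate, floored at ``DISPERSION_FLOOR``; because that estimate is very
    noisy at the usual 2-3 replicates, each gene is then raised to at least
    the across-gene median (an empirical-Bayes-style sharing of dispersion
    information, in the spirit of the standard count-model engines), which
    keeps Wald false-positive rates near nominal without sacrificing power.
    """
    parts, weights = [], []
    for grp in (norm_a, norm_b):
        mu = grp.mean(axis=1)
        var = grp.var(axis=1, ddof=1)
        alpha = (var - mu) / mu.pow(2)
        parts.append(alpha)
        weights.append(grp.shape[1] - 1)
    pooled = (parts[0] * weights[0] + parts[1] * weights[1]) / sum(weights)
    pooled = pooled.clip(lower=DISPERSION_FLOOR).fillna(DISPERSION_FLOOR)
    expressed = (norm_a.mean(axis=1) + norm_b.mean(axis=1)) / 2 > 1
    prior = float(pooled[expressed].median()) if expressed.any() else DISPERSION_FLOOR
    return pooled.clip(lower=prior)


def differential_expression(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    sf: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB Wald test (B versus A) on jointly normalized counts.

    Returns a table indexed by gene with baseMean, log2FC, p_value,
    dispersion, and an ``excluded`` flag for all-zero genes.  The Wald
    statistic uses a delta-method standard error on the log2 ratio of group
    means with moderated NB dispersion (see :func:`_mom_dispersion`); the
    moderation is what keeps the normal reference honest at 2-3 replicates.
    """
    if counts_a.shape[1] < 2 or counts_b.shape[1] < 2:
        raise ValueError("need >= 2 replicates per group")
    all_counts = pd.concat([counts_a, counts_b], axis=1)
    if sf is None:
        sf = size_factors(all_counts)
    norm = all_counts / sf
    norm_a = norm[counts_a.columns]
    norm_b = norm[counts_b.columns]
    base_mean = norm.mean(axis=1)
    excluded = (all_counts.sum(axis=1) == 0)
    mu_a = norm_a.mean(axis=1)
    mu_b = norm_b.mean(axis=1)
    alpha = _mom_dispersion(norm_a, norm_b)
    c = pseudocount
    # pseudocount only where a group mean vanishes, so the fold change of an
    # expressed gene is the exact ratio of normalized group means
    both_pos = (mu_a > 0) & (mu_b > 0)
    log2fc = np.where(both_pos, np.log2(mu_b.where(mu_b > 0) / mu_a.where(mu_a > 0)),
                      np.log2((mu_b + c) / (mu_a + c)))
    log2fc = pd.Series(log2fc, index=mu_a.index)
    var_a = (mu_a + c) + alpha * (mu_a + c) ** 2
    var_b = (mu_b + c) + alpha * (mu_b + c) ** 2
    n_a, n_b = norm_a.shape[1], norm_b.shape[1]
    se = np.sqrt(var_a / (n_a * (mu_a + c) ** 2) + var_b / (n_b * (mu_b + c) ** 2)) / np.log(2)
    wald = log2fc / se
    p = 2 * stats.norm.sf(np.abs(wald))
    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "log2FC": log2fc,
            "p_value": p,
            "dispersion": alpha,
            "excluded": excluded,
        }
    )
    out.loc[excluded, ["log2FC", "p_value"]] = np.nan
    return out


def deg_flags(
    de: pd.DataFrame, p_cutoff: float = 0.01, fc_cutoff: float = 2.0, basemean_cutoff: float = 10.0
) -> pd.DataFrame:
    """Attach per-threshold pass flags (p, fold change, baseMean) to a DE table."""
    out = de.copy()
    out["pass_p"] = (de["p_value"] < p_cutoff).fillna(False)
    out["pass_fc"] = (np.abs(de["log2FC"]) > np.log2(fc_cutoff)).fillna(False)
    out["pass_basemean"] = de["baseMean"] > basemean_cutoff
    out["is_deg"] = out["pass_p"] & out["pass_fc"] & out["pass_basemean"] & ~de["excluded"]
    return out


# ------------------------------------------------------------ allelic status


@dataclass(frozen=True)
class AllelicBands:
    """Maternal-fraction bands for allelic expression status calls.

    fraction <= ``mono_low``  -> paternal;  fraction >= ``mono_high`` ->
    maternal; within [bi_low, bi_high] -> biallelic; anything else (or too
    few informative reads) -> not_evaluable.
    """

    mono_low: float = 0.15
    mono_high: float = 0.85
    bi_low: float = 0.30
    bi_high: float = 0.70
    min_informative: int = 10


def call_allelic_status(
    maternal_fraction: float, n_informative: int, bands: AllelicBands | None = None
) -> str:
    bands = bands or AllelicBands()
    if n_informative < bands.min_informative or not np.isfinite(maternal_fraction):
        return "not_evaluable"
    if maternal_fraction <= bands.mono_low:
        return "paternal"
    if maternal_fraction >= bands.mono_high:
        return "maternal"
    if bands.bi_low <= maternal_fraction <= bands.bi_high:
        return "biallelic"
    return "not_evaluable"


# ----------------------------------------------------------------- cascade


@dataclass
class CascadeParams:
    fpkm_floor: float = 1.0
    fc_high: float = 2.0
    fc_low: float = 0.5
    dmr_window_bp: int = 10_000
    deg_p: float = 0.01
    deg_fc: float = 2.0
    deg_basemean: float = 10.0


@dataclass
class ImprintCall:
    gene_id: str
    stage: str  # expressed_candidate | dmr_associated | fold_change_aberrant | de_imprinted
    allelic_control: str = "not_evaluable"
    allelic_test: str = "not_evaluable"
    loi: bool = False
    dmr_ids: list[int] = field(default_factory=list)


@dataclass
class CascadeResult:
    stage1: set[str]  # expressed candidates (FPKM > floor in both groups)
    stage2: set[str]  # DMR-associated
    stage3: set[str]  # aberrant fold change
    deg_route: set[str]  # DEG intersect candidates, DMR-associated
    calls: dict[str, ImprintCall]


def candidate_cascade(
    imprint_list: list[str],
    fpkm_control: pd.Series,
    fpkm_test: pd.Series,
    dmrs: list[DMR],
    gene_models: pd.DataFrame,
    de_results: pd.DataFrame | None = None,
    params: CascadeParams | None = None,
) -> CascadeResult:
    """Run the imprinted-gene filtration cascade.

    ``fpkm_control``/``fpkm_test`` are mean FPKM per gene per group.  The
    fold change at stage 3 is the FPKM ratio test/control (the control group
    level set to 1).  ``de_results`` (a :func:`deg_flags`-annotated table)
    feeds the parallel DEG route when given.
    """
    params = params or CascadeParams()
    candidates = [g for g in imprint_list if g in fpkm_control.index and g in fpkm_test.index]
    stage1 = {
        g
        for g in candidates
        if fpkm_control[g] > params.fpkm_floor and fpkm_test[g] > params.fpkm_floor
    }
    genes_sub = gene_models[gene_models["gene_id"].isin(stage1)]
    assoc = map_genes_to_dmrs(genes_sub, dmrs, window_bp=params.dmr_window_bp)
    stage2 = set(assoc)
    stage3 = set()
    for g in stage2:
        ratio = fpkm_test[g] / fpkm_control[g] if fpkm_control[g] > 0 else np.inf
        if ratio > params.fc_high or ratio < params.fc_low:
            stage3.add(g)
    deg_route: set[str] = set()
    if de_results is not None:
        flagged = deg_flags(
            de_results, p_cutoff=params.deg_p, fc_cutoff=params.deg_fc, basemean_cutoff=params.deg_basemean
        ) if "is_deg" not in de_results.columns else de_results
        degs = set(flagged.index[flagged["is_deg"]])
        deg_candidates = degs & set(imprint_list)
        genes_deg = gene_models[gene_models["gene_id"].isin(deg_candidates)]
        deg_route = set(map_genes_to_dmrs(genes_deg, dmrs, window_bp=params.dmr_window_bp))
    calls: dict[str, ImprintCall] = {}
    for g in stage1:
        if g in stage3:
            stage = "fold_change_aberrant"
        elif g in stage2:
            stage = "dmr_associated"
        else:
            stage = "expressed_candidate"
        calls[g] = ImprintCall(g, stage, dmr_ids=assoc.get(g, []))
    for g in deg_route:
        if g in calls:
            calls[g].stage = "de_imprinted"
        else:
            calls[g] = ImprintCall(g, "de_imprinted")
    return CascadeResult(stage1, stage2, stage3, deg_route, calls)


def call_loi(
    status_control: str,
    status_test: str,
    meth_bias_control: float | None = None,
    meth_bias_test: float | None = None,
    bias_loss_threshold: float = 0.3,
) -> bool:
    """Loss-of-imprinting decision for one gene.

    True when the control is monoallelic and the test is biallelic, or when
    a maternal-allele methylation bias (maternal minus paternal DMR level)
    present in the control (>= threshold) collapses in the test (< half the
    threshold).
    """
    expression_loi = status_control in ("maternal", "paternal") and status_test == "biallelic"
    meth_loi = False
    if meth_bias_control is not None and meth_bias_test is not None:
        meth_loi = (
            meth_bias_control >= bias_loss_threshold
            and meth_bias_test < bias_loss_threshold / 2
        )
    return expression_loi or meth_loi


def annotate_loi(
    cascade: CascadeResult,
    allelic_control: pd.DataFrame,
    allelic_test: pd.DataFrame,
    bands: AllelicBands | None = None,
    meth_bias_control: pd.Series | None = None,
    meth_bias_test: pd.Series | None = None,
) -> CascadeResult:
    """Fill allelic status and the LOI flag for every cascade gene.

    ``allelic_control``/``allelic_test`` are :func:`scntomics.allelesplit.
    allelic_fraction` tables indexed by their gene_id column.
    """
    bands = bands or AllelicBands()
    ctl = allelic_control.set_index("gene_id")
    tst = allelic_test.set_index("gene_id")
    for g, call in cascade.calls.items():
        if g in ctl.index:
            row = ctl.loc[g]
            call.allelic_control = call_allelic_status(
                row["maternal_fraction"], int(row["n_maternal"] + row["n_paternal"]), bands
            )
        if g in tst.index:
            row = tst.loc[g]
            call.allelic_test = call_allelic_status(
                row["maternal_fraction"], int(row["n_maternal"] + row["n_paternal"]), bands
            )
        bias_c = meth_bias_control.get(g) if meth_bias_control is not None else None
        bias_t = meth_bias_test.get(g) if meth_bias_test is not None else None
        call.loi = call_loi(call.allelic_control, call.allelic_test, bias_c, bias_t)
    return cascade


def calls_to_table(cascade: CascadeResult) -> pd.DataFrame:
    rows = [
        {
            "gene_id": c.gene_id,
            "stage": c.stage,
            "allelic_control": c.allelic_control,
            "allelic_test": c.allelic_test,
            "loi": c.loi,
            "dmr_ids": ",".join(str(i) for i in c.dmr_ids),
        }
        for c in cascade.calls.values()
    ]
    return pd.DataFrame(rows).sort_values("gene_id", ignore_index=True)
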