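"""Synthetic-data generator: every pipeline input with known ground truth.

The generator emulates the hybrid-cross study design: two parental genomes
homozygous-divergent at random SNPs, allele-specific CpG methylation with
planted maternally imprinted and somatic-memory DMRs, directional bisulfite
reads with configurable conversion efficiency and an always-unmethylated
lambda spike-in, negative-binomial RNA counts with allelic reads, placenta
slide images with calcified particles, and two-group gestation outcome
tables.

All randomness flows from one integer seed; each stage draws from its own
deterministic substream, so adding or re-running a stage never perturbs any
other stage's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reads import (
    A,
    ALLELE_MATERNAL,
    ALLELE_PATERNAL,
    C,
    G,
    ReadSet,
    STRAND_BOTTOM,
    STRAND_TOP,
    T,
)

LAMBDA_CONTIG = "lambda_spike"
CONTROL = "icsi"
TEST = "scnt"

_BASES = np.array([A, C, G, T], dtype=np.uint8)

_STAGE_IDS = {"genomes": 0, "bisulfite": 1, "rnaseq": 2, "slides": 4, "gestation": 5}


def stage_rng(seed: int, stage: str, substream: int = 0) -> np.random.Generator:
    """Deterministic per-stage random substream derived from the global seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STAGE_IDS[stage], substream)))


# ------------------------------------------------------------------ config


@dataclass
class DmrSpec:
    """One planted differentially methylated region.

    ``kind`` semantics (levels are CpG methylation probabilities):

    * ``maternal_imprint`` - control: maternal allele at ``level_high``,
      paternal at ``level_low``; test: imprint collapses to ``level_low`` on
      both alleles when ``lost_in_test`` (the default), otherwise preserved.
    * ``somatic_hypo`` - both alleles at ``level_high`` in control,
      ``level_low`` in test (lower in the cloned condition).
    * ``somatic_hyper`` - the mirror image.
    """

    kind: str
    length_bp: int
    level_high: float = 0.9
    level_low: float = 0.1
    lost_in_test: bool = True

    KINDS = ("maternal_imprint", "somatic_hypo", "somatic_hyper")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown DMR kind {self.kind!r}")
        if self.length_bp <= 0:
            raise ValueError("DMR length must be positive")
        for lv in (self.level_high, self.level_low):
            if not 0 <= lv <= 1:
                raise ValueError("methylation levels must be in [0, 1]")

    def levels(self, condition: str) -> tuple[float, float]:
        """(maternal, paternal) methylation probability under a condition."""
        if self.kind == "maternal_imprint":
            if condition == TEST and self.lost_in_test:
                return self.level_low, self.level_low
            return self.level_high, self.level_low
        if self.kind == "somatic_hypo":
            lv = self.level_high if condition == CONTROL else self.level_low
            return lv, lv
        lv = self.level_low if condition == CONTROL else self.level_high
        return lv, lv


@dataclass
class SimulationConfig:
    """Study-condition parameters of the whole synthetic experiment."""

    genome_length: int = 200_000  # bp per chromosome
    n_chromosomes: int = 1
    snp_rate: float = 2e-3  # per-bp homozygous-divergent SNP probability
    cpg_retention: float = 0.2  # fraction of raw CpG dinucleotides kept (CpG depletion)
    background_meth: float = 0.5  # CpG methylation probability outside DMRs
    dmr_specs: list[DmrSpec] = field(default_factory=list)
    depth: float = 30.0  # mean read coverage
    read_length: int = 100
    conversion_efficiency: float = 0.99
    lambda_fraction: float = 0.01
    lambda_length: int = 5_000
    rng_seed: int = 0
    allow_cpg_snps: bool = False
    non_directional: bool = False  # PBAT-style four-strand model when True

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")
        if self.depth <= 0 or self.read_length <= 0:
            raise ValueError("depth and read_length must be positive")
        if self.read_length > self.genome_length:
            raise ValueError("read_length exceeds genome_length")
        for name in (
            "snp_rate",
            "cpg_retention",
            "background_meth",
            "conversion_efficiency",
            "lambda_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]


@dataclass
class TruthSet:
    """Ground truth of one simulated experiment."""

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    snps: pd.DataFrame  # chrom, pos (1-based), maternal_allele, paternal_allele
    dmrs: pd.DataFrame  # chrom, start, end (0-based half-open), kind, spec index
    dmr_specs: list[DmrSpec]

    def methylome(self, condition: str) -> dict[str, np.ndarray]:
        """Per-chromosome (2, L) arrays of per-allele methylation probability.

        Row 0 is the maternal allele, row 1 paternal.  Values apply at CpG
        cytosines; non-CpG cytosines are always unmethylated.
        """
        bg = self._background
        probs = {
            name: np.full((2, self.chrom_lengths[name]), bg, dtype=np.float32)
            for name in self.chrom_names
        }
        for row in self.dmrs.itertuples():
            mat, pat = self.dmr_specs[row.spec_index].levels(condition)
            probs[row.chrom][0, row.start : row.end] = mat
            probs[row.chrom][1, row.start : row.end] = pat
        return probs

    _background: float = 0.5


# ----------------------------------------------------------------- genomes


def gen_hybrid_genomes(config: SimulationConfig):
    """Generate maternal/paternal haplotypes plus a lambda spike-in contig.

    Returns (maternal, paternal, truth) where the haplotype dicts map contig
    name to sequence string.  The haplotypes differ exactly at the truth SNP
    positions; unless ``allow_cpg_snps`` is set, no SNP touches a CpG
    dinucleotide on either haplotype (so bisulfite conversion can never be
    confounded with a variant by accident).
    """
    rng = stage_rng(config.rng_seed, "genomes")
    maternal: dict[str, np.ndarray] = {}
    paternal: dict[str, np.ndarray] = {}
    snp_rows = []
    for chrom in config.chrom_names:
        L = config.genome_length
        seq = _BASES[rng.integers(0, 4, size=L)]
        _deplete_cpgs(seq, config.cpg_retention, rng)
        pat = seq.copy()
        if config.snp_rate > 0:
            cand = np.flatnonzero(rng.random(L) < config.snp_rate)
            # keep SNPs >= 2 bp apart so neighbours cannot interact
            if cand.size > 1:
                keep = np.concatenate([[True], np.diff(cand) >= 2])
                cand = cand[keep]
            for i in cand:
                ref = seq[i]
                if not config.allow_cpg_snps:
                    if _in_cpg(seq, i):
                        continue
                    choices = [b for b in _BASES if b != ref and not _creates_cpg(seq, i, b)]
                else:
                    choices = [b for b in _BASES if b != ref]
                if not choices:
                    continue
                alt = choices[rng.integers(0, len(choices))]
                pat[i] = alt
                snp_rows.append((chrom, i + 1, chr(ref), chr(alt)))
        maternal[chrom] = seq
        paternal[chrom] = pat
    lam = _BASES[rng.integers(0, 4, size=config.lambda_length)]
    maternal[LAMBDA_CONTIG] = lam
    paternal[LAMBDA_CONTIG] = lam.copy()
    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "maternal_allele", "paternal_allele"])
    truth = TruthSet(
        chrom_names=config.chrom_names,
        chrom_lengths={c: config.genome_length for c in config.chrom_names},
        snps=snps,
        dmrs=_place_dmrs(config),
        dmr_specs=config.dmr_specs,
    )
    truth._background = config.background_meth
    mat_str = {k: v.tobytes().decode("ascii") for k, v in maternal.items()}
    pat_str = {k: v.tobytes().decode("ascii") for k, v in paternal.items()}
    return mat_str, pat_str, truth


def _deplete_cpgs(seq: np.ndarray, retention: float, rng: np.random.Generator) -> None:
    """Disrupt a fraction of CpG dinucleotides in place.

    Vertebrate genomes are strongly CpG-depleted (observed/expected roughly
    0.2); an i.i.d. sequence would carry one CpG per 16 bp, which distorts
    every density-dependent step downstream (gap-limited DMR chaining in
    particular).  Each raw CpG survives with probability ``retention``;
    disrupted CpGs have their G replaced by A or T, which can never create a
    new CpG.
    """
    if retention >= 1:
        return
    cpg_c = np.flatnonzero((seq[:-1] == C) & (seq[1:] == G))
    drop = cpg_c[rng.random(cpg_c.size) >= retention]
    repl = np.where(rng.random(drop.size) < 0.5, A, T).astype(np.uint8)
    seq[drop + 1] = repl


def _in_cpg(seq: np.ndarray, i: int) -> bool:
    if seq[i] == C and i + 1 < len(seq) and seq[i + 1] == G:
        return True
    if seq[i] == G and i > 0 and seq[i - 1] == C:
        return True
    return False


def _creates_cpg(seq: np.ndarray, i: int, alt: int) -> bool:
    if alt == C and i + 1 < len(seq) and seq[i + 1] == G:
        return True
    if alt == G and i > 0 and seq[i - 1] == C:
        return True
    return False


def _place_dmrs(config: SimulationConfig) -> pd.DataFrame:
    """Deterministic, evenly spaced, non-overlapping DMR placement.

    Each spec gets one slot; slots are distributed round-robin over
    chromosomes and the region is centered in its slot, keeping generous
    flanks for metaprofiles and gap-limited segmentation.
    """
    n = len(config.dmr_specs)
    rows = []
    if n == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "kind", "spec_index"])
    per_chrom = -(-n // config.n_chromosomes)  # ceil
    for si, spec in enumerate(config.dmr_specs):
        ci, slot = divmod(si, per_chrom)
        slot_size = config.genome_length // per_chrom
        if spec.length_bp > slot_size:
            raise ValueError(f"DMR spec {si} ({spec.length_bp} bp) does not fit its slot")
        start = slot * slot_size + (slot_size - spec.length_bp) // 2
        rows.append((config.chrom_names[ci], start, start + spec.length_bp, spec.kind, si))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "kind", "spec_index"])


# --------------------------------------------------------- bisulfite reads


def simulate_bisulfite_reads(
    maternal: dict[str, str],
    paternal: dict[str, str],
    truth: TruthSet,
    config: SimulationConfig,
    condition: str = CONTROL,
) -> ReadSet:
    """Directional bisulfite reads with ground-truth origin tags.

    Read count = depth x genome / read_length (rounded), a ``lambda_fraction``
    of which come from the fully unmethylated spike-in contig.  Original-top
    reads convert unmethylated Cs to T with probability
    ``conversion_efficiency``; original-bottom reads convert reference-frame
    Gs to A.  Methylation at CpG cytosines follows the truth methylome of
    the requested condition and allele; every other cytosine is unmethylated.
    """
    sub = {CONTROL: 0, TEST: 1}[condition]
    rng = stage_rng(config.rng_seed, "bisulfite", sub)
    L = config.read_length
    chroms = truth.chrom_names
    genome_total = sum(truth.chrom_lengths.values())
    n_total = int(round(config.depth * genome_total / L))
    n_lambda = int(round(config.lambda_fraction * n_total))
    n_genomic = n_total - n_lambda
    probs = truth.methylome(condition)

    ref_names = chroms + [LAMBDA_CONTIG]
    ref_lengths = [truth.chrom_lengths[c] for c in chroms] + [len(maternal[LAMBDA_CONTIG])]
    hap_arr = {
        0: {name: np.frombuffer(maternal[name].encode(), dtype=np.uint8) for name in ref_names},
        1: {name: np.frombuffer(paternal[name].encode(), dtype=np.uint8) for name in ref_names},
    }

    lengths = np.array([truth.chrom_lengths[c] for c in chroms], dtype=float)
    chrom_idx = rng.choice(len(chroms), size=n_genomic, p=lengths / lengths.sum())
    lam_idx = np.full(n_lambda, len(chroms), dtype=np.int64)
    chrom_idx = np.concatenate([chrom_idx, lam_idx]).astype(np.int32)
    max_start = np.array([ref_lengths[i] - L for i in range(len(ref_names))])
    start = (rng.random(n_total) * (max_start[chrom_idx] + 1)).astype(np.int64)
    strand = (rng.random(n_total) < 0.5).astype(np.uint8)  # 0 top, 1 bottom
    allele = (rng.random(n_total) < 0.5).astype(np.int8)  # 0 maternal, 1 paternal

    # A cytosine converts iff it is unmethylated AND conversion succeeds, so
    # the per-base conversion probability collapses to ce * (1 - p_meth);
    # precomputing that per position (per allele and strand) finishes each
    # read group with one uniform draw and two gathers.
    seq = np.empty((n_total, L), dtype=np.uint8)
    offs = np.arange(L, dtype=np.int64)
    ce = np.float32(config.conversion_efficiency)
    for ci, name in enumerate(ref_names):
        for al in (0, 1):
            hap = hap_arr[al][name]
            if name == LAMBDA_CONTIG:
                conv_top = np.full(len(hap), ce, dtype=np.float32)
                conv_bot = conv_top
            else:
                parr = probs[name][al]
                # CpG context on this haplotype (SNPs avoid CpG by default,
                # so context agrees across haplotypes)
                is_c = hap == C
                is_g = hap == G
                cpg_c = np.zeros(len(hap), dtype=bool)
                cpg_c[:-1] = is_c[:-1] & is_g[1:]
                cpg_g = np.zeros(len(hap), dtype=bool)
                cpg_g[1:] = is_g[1:] & is_c[:-1]
                p_top = np.zeros(len(hap), dtype=np.float32)
                p_top[cpg_c] = parr[cpg_c]
                # bottom-strand G of a CpG carries the symmetric state of its C
                p_bot = np.zeros(len(hap), dtype=np.float32)
                p_bot[cpg_g] = parr[np.flatnonzero(cpg_g) - 1]
                conv_top = ce * (1.0 - p_top)
                conv_bot = ce * (1.0 - p_bot)
            for st, conv_arr, from_base, to_base in (
                (STRAND_TOP, conv_top, C, T),
                (STRAND_BOTTOM, conv_bot, G, A),
            ):
                sel = np.flatnonzero((chrom_idx == ci) & (allele == al) & (strand == st))
                if sel.size == 0:
                    continue
                pos = start[sel, None] + offs[None, :]
                block = hap[pos]
                u = rng.random((sel.size, L), dtype=np.float32)
                block[(block == from_base) & (u < conv_arr[pos])] = to_base
                seq[sel] = block
    return ReadSet(
        ref_names=ref_names,
        ref_lengths=ref_lengths,
        chrom_idx=chrom_idx,
        start=start,
        strand=strand,
        seq=seq,
        allele_truth=allele,
    )


def reference_genome(maternal: dict[str, str]) -> dict[str, str]:
    """The analysis reference: the maternal haplotype plus the spike-in."""
    return dict(maternal)


# ----------------------------------------------------------------- RNA-seq


@dataclass
class GeneExpressionSpec:
    """Per-gene truth for RNA simulation."""

    gene_id: str
    mean_control: float
    mean_test: float
    dispersion: float = 0.1
    maternal_fraction_control: float = 0.5
    maternal_fraction_test: float = 0.5
    n_allelic_reads: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for f in (self.maternal_fraction_control, self.maternal_fraction_test):
            if not 0 <= f <= 1:
                raise ValueError("maternal fraction must be in [0, 1]")


def make_gene_models(config: SimulationConfig, n_genes: int, gene_length: int = 2_000) -> pd.DataFrame:
    """Evenly spaced single-exon genes over the synthetic chromosomes."""
    rows = []
    per_chrom = -(-n_genes // config.n_chromosomes)
    slot = config.genome_length // per_chrom
    if gene_length > slot:
        raise ValueError("genes do not fit the genome at this count/length")
    for gi in range(n_genes):
        ci, s = divmod(gi, per_chrom)
        start = s * slot + (slot - gene_length) // 2
        rows.append(
            {
                "gene_id": f"gene{gi + 1}",
                "chrom": config.chrom_names[ci],
                "start": start,
                "end": start + gene_length,
                "strand": "+" if gi % 2 == 0 else "-",
                "exon_starts": str(start),
                "exon_ends": str(start + gene_length),
            }
        )
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion < 1e-9:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean / shape, size=size)
    return rng.poisson(lam)


def simulate_rnaseq(
    gene_models: pd.DataFrame,
    expression_specs: list[GeneExpressionSpec],
    config: SimulationConfig,
    truth: TruthSet | None = None,
    maternal: dict[str, str] | None = None,
    paternal: dict[str, str] | None = None,
    n_replicates: int = 3,
):
    """Negative-binomial counts per group plus SNP-overlapping allelic reads.

    Returns (counts, allelic_reads): ``counts`` maps condition to a genes x
    replicates DataFrame; ``allelic_reads`` maps condition to a ReadSet of
    reads placed over informative SNPs inside each gene (empty dict when
    haplotypes or truth are not supplied or no gene requests allelic reads).
    Gene models must not overlap on a strand (checked).
    """
    _check_nonoverlapping(gene_models)
    rng = stage_rng(config.rng_seed, "rnaseq")
    gene_ids = [s.gene_id for s in expression_specs]
    counts = {}
    for cond, attr in ((CONTROL, "mean_control"), (TEST, "mean_test")):
        mat = np.vstack(
            [_nb_draw(rng, getattr(s, attr), s.dispersion, n_replicates) for s in expression_specs]
        )
        counts[cond] = pd.DataFrame(
            mat, index=gene_ids, columns=[f"{cond}_rep{i + 1}" for i in range(n_replicates)]
        )
    allelic: dict[str, ReadSet] = {}
    if truth is not None and maternal is not None and paternal is not None:
        models = gene_models.set_index("gene_id")
        for cond, attr in ((CONTROL, "maternal_fraction_control"), (TEST, "maternal_fraction_test")):
            parts = []
            for s in expression_specs:
                if s.n_allelic_reads <= 0 or s.gene_id not in models.index:
                    continue
                g = models.loc[s.gene_id]
                part = _allelic_reads_for_gene(
                    rng, g, getattr(s, attr), s.n_allelic_reads, truth, maternal, paternal, config
                )
                if part is not None:
                    parts.append(part)
            if parts:
                allelic[cond] = ReadSet.concatenate(parts)
    return counts, allelic


def _check_nonoverlapping(gene_models: pd.DataFrame) -> None:
    for (_, _), sub in gene_models.groupby(["chrom", "strand"]):
        s = sub.sort_values("start")
        if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
            raise ValueError("gene models overlap on one strand")


def _allelic_reads_for_gene(rng, gene, mat_frac, n_reads, truth, maternal, paternal, config):
    chrom = gene["chrom"]
    in_gene = truth.snps[
        (truth.snps["chrom"] == chrom)
        & (truth.snps["pos"] - 1 >= gene["start"])
        & (truth.snps["pos"] - 1 < gene["end"])
    ]
    if in_gene.empty:
        return None
    L = config.read_length
    clen = truth.chrom_lengths[chrom]
    snp_pos0 = in_gene["pos"].to_numpy() - 1
    choice = rng.integers(0, len(snp_pos0), size=n_reads)
    anchor = snp_pos0[choice]
    offset = rng.integers(0, L, size=n_reads)
    start = np.clip(anchor - offset, 0, clen - L)
    allele = (rng.random(n_reads) < (1 - mat_frac)).astype(np.int8)  # 0 maternal
    hap = {
        0: np.frombuffer(maternal[chrom].encode(), dtype=np.uint8),
        1: np.frombuffer(paternal[chrom].encode(), dtype=np.uint8),
    }
    seq = np.empty((n_reads, L), dtype=np.uint8)
    offs = np.arange(L)
    for al in (0, 1):
        sel = np.flatnonzero(allele == al)
        if sel.size:
            seq[sel] = hap[al][start[sel, None] + offs[None, :]]
    ref_names = truth.chrom_names + [LAMBDA_CONTIG]
    ref_lengths = [truth.chrom_lengths[c] for c in truth.chrom_names] + [len(maternal[LAMBDA_CONTIG])]
    ci = ref_names.index(chrom)
    return ReadSet(
        ref_names=ref_names,
        ref_lengths=ref_lengths,
        chrom_idx=np.full(n_reads, ci, dtype=np.int32),
        start=start.astype(np.int64),
        strand=np.zeros(n_reads, dtype=np.uint8),
        seq=seq,
        allele_truth=allele,
    )


# ------------------------------------------------------------------ slides


@dataclass
class SlideSpec:
    """One synthetic stained-slide image."""

    height: int = 512
    width: int = 512
    # fine enough that the minimum particle area spans many pixels, as in
    # real slide scans; isolated noise pixels then never survive the filter
    pixel_size_mm: float = 0.005
    tissue_center: tuple[int, int] | None = None  # defaults to image center
    tissue_axes: tuple[int, int] = (200, 150)  # ellipse semi-axes, px
    particles: list[tuple[int, int, int]] = field(default_factory=list)  # (row, col, radius px)
    background_intensity: int = 10
    tissue_intensity: int = 120
    calcified_intensity: int = 230
    noise_sd: float = 2.0


def simulate_placenta_slide(spec: SlideSpec, rng: np.random.Generator | None = None):
    """Render a slide image and return (image uint8, truth dict).

    Truth areas are the rasterized pixel counts scaled by pixel size, so
    segmentation accuracy can be judged against exactly what was drawn.
    Raises if any particle is not fully inside the tissue ellipse or has a
    negative radius.
    """
    rng = rng or np.random.default_rng(0)
    h, w = spec.height, spec.width
    cy, cx = spec.tissue_center or (h // 2, w // 2)
    ay, ax = spec.tissue_axes
    yy, xx = np.mgrid[0:h, 0:w]
    tissue = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    img = np.full((h, w), float(spec.background_intensity))
    img[tissue] = spec.tissue_intensity
    px2 = spec.pixel_size_mm**2
    cal_mask = np.zeros((h, w), dtype=bool)
    for r, c, rad in spec.particles:
        if rad < 0:
            raise ValueError("particle radius must be >= 0")
        disk = (yy - r) ** 2 + (xx - c) ** 2 <= rad**2
        if not (disk <= tissue).all():
            raise ValueError(f"particle at ({r}, {c}) extends outside the tissue region")
        cal_mask |= disk
    img[cal_mask] = spec.calcified_intensity
    if spec.noise_sd > 0:
        img = img + rng.normal(0, spec.noise_sd, size=img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = {
        "tissue_area_mm2": float(tissue.sum() * px2),
        "calcified_area_mm2": float(cal_mask.sum() * px2),
        "n_particles": len(spec.particles),
    }
    return image, truth


# --------------------------------------------------------------- gestation


def simulate_gestation(
    n_per_group: dict[str, int],
    hazard_spec: dict[str, tuple],
    seed: int,
    censor_at: float | None = None,
) -> pd.DataFrame:
    """Abortion-day table (subject, group, day, event).

    ``hazard_spec`` maps group to one of ("point", day),
    ("exponential", scale) or ("weibull", shape, scale); scales must be
    positive.  With ``censor_at``, events past that day are censored there
    (fetuses alive at term), otherwise every record is an event.
    """
    rng = stage_rng(seed, "gestation")
    rows = []
    sid = 0
    for group in sorted(n_per_group):
        n = n_per_group[group]
        spec = hazard_spec[group]
        kind = spec[0]
        if kind == "point":
            days = np.full(n, float(spec[1]))
        elif kind == "exponential":
            if spec[1] <= 0:
                raise ValueError("exponential scale must be positive")
            days = rng.exponential(spec[1], size=n)
        elif kind == "weibull":
            shape, scale = spec[1], spec[2]
            if shape <= 0 or scale <= 0:
                raise ValueError("weibull parameters must be positive")
            days = scale * rng.weibull(shape, size=n)
        else:
            raise ValueError(f"unknown hazard kind {kind!r}")
        event = np.ones(n, dtype=bool)
        if censor_at is not None:
            event = days < censor_at
            days = np.minimum(days, censor_at)
        for d, e in zip(days, event):
            rows.append((f"subj{sid}", group, float(d), bool(e)))
            sid += 1
    return pd.DataFrame(rows, columns=["subject", "group", "day", "event"])
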