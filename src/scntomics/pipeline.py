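"""End-to-end demo pipeline over a fully synthetic experiment.

``run_pipeline`` wires every stage together: genome simulation, informative
SNP selection and masking, bisulfite read simulation for control (ICSI) and
test (SCNT) conditions, allele splitting, methylation calling, DMR
segmentation and annotation, RNA counts with the imprinting cascade and LOI
calls, slide morphometry, and gestation survival statistics.  Every output
is a plain-text table or image, and a manifest records the configuration
hash, seed, and a checksum per output so a re-run can be verified
byte-for-byte (all randomness flows from ``RunConfig.seed``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import allelesplit, dmr, expression, io, methylome, morphometry, repro_stats, synthdata
from .synthdata import CONTROL, TEST, DmrSpec, GeneExpressionSpec, SimulationConfig, SlideSpec


@dataclass
class RunConfig:
    """All pipeline parameters; unknown keys in a config file are rejected."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    log_level: str = "INFO"
    sim: SimulationConfig = field(default_factory=lambda: _default_sim(0))
    dmr_params: dmr.DMRCallParams = field(default_factory=dmr.DMRCallParams)
    cascade_params: expression.CascadeParams = field(default_factory=expression.CascadeParams)
    allelic_bands: expression.AllelicBands = field(default_factory=expression.AllelicBands)
    n_replicates: int = 3
    pixel_size_mm: float = 0.005  # matches the slide generator default

    @staticmethod
    def from_yaml(path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(RunConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim_raw = raw.pop("sim", None)
        cfg = RunConfig(**{k: v for k, v in raw.items() if k not in ("dmr_params",)})
        if sim_raw is not None:
            specs = [DmrSpec(**s) for s in sim_raw.pop("dmr_specs", [])]
            cfg.sim = SimulationConfig(dmr_specs=specs, **sim_raw)
        if "dmr_params" in raw:
            cfg.dmr_params = dmr.DMRCallParams(**raw["dmr_params"])
        cfg.sim.rng_seed = cfg.seed
        return cfg

    def config_hash(self) -> str:
        plain = _as_plain(self)
        plain.pop("out_dir", None)  # analysis identity, not output location
        plain.pop("log_level", None)
        blob = json.dumps(plain, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(x) for x in obj]
    return obj


def _default_sim(seed: int) -> SimulationConfig:
    return SimulationConfig(
        genome_length=150_000,
        n_chromosomes=1,
        snp_rate=2e-3,
        background_meth=0.5,
        dmr_specs=[
            # ~40 CpGs each at the depleted background density (~1 per 80 bp)
            DmrSpec("maternal_imprint", 3200, 0.9, 0.1),
            DmrSpec("somatic_hypo", 3200, 0.8, 0.2),
            DmrSpec("somatic_hyper", 3200, 0.8, 0.2),
        ],
        depth=30.0,
        read_length=100,
        conversion_efficiency=0.99,
        lambda_fraction=0.01,
        rng_seed=seed,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    out = config.out_dir
    io.ensure_dir(out)
    sim = config.sim
    outputs: list[str] = []

    def save_tsv(name: str, df: pd.DataFrame) -> str:
        path = os.path.join(out, name)
        io.write_tsv_table(path, df)
        outputs.append(path)
        return path

    # 1. genomes + truth
    maternal, paternal, truth = synthdata.gen_hybrid_genomes(sim)
    io.write_fasta(os.path.join(out, "maternal.fa"), maternal)
    io.write_fasta(os.path.join(out, "paternal.fa"), paternal)
    outputs += [os.path.join(out, "maternal.fa"), os.path.join(out, "paternal.fa")]
    save_tsv("truth_snps.tsv", truth.snps)
    save_tsv("truth_dmrs.tsv", truth.dmrs)

    # 2. informative SNPs + masked reference
    from .variants import InformativeSnp, mask_genome

    snps = [
        InformativeSnp(r.chrom, int(r.pos), r.maternal_allele, r.paternal_allele)
        for r in truth.snps.itertuples()
    ]
    reference = synthdata.reference_genome(maternal)
    masked, bed = mask_genome(reference, snps)
    io.write_fasta(os.path.join(out, "reference_masked.fa"), masked)
    outputs.append(os.path.join(out, "reference_masked.fa"))
    io.write_bed(os.path.join(out, "informative_snps.bed"), bed)
    outputs.append(os.path.join(out, "informative_snps.bed"))

    # 3-5. bisulfite reads, allele split, methylation
    cpg_tables: dict[str, pd.DataFrame] = {}
    allele_tables: dict[tuple[str, str], pd.DataFrame] = {}
    conv = {}
    for cond in (CONTROL, TEST):
        reads = synthdata.simulate_bisulfite_reads(maternal, paternal, truth, sim, cond)
        split = allelesplit.split_dataset(reads, snps, mode="bisulfite")
        save_tsv(f"split_summary_{cond}.tsv", split.summary())
        cpg = methylome.call_cpg_methylation(reads, reference)
        cpg_tables[cond] = cpg
        io.write_bedgraph(os.path.join(out, f"cpg_{cond}.bedGraph"), cpg)
        outputs.append(os.path.join(out, f"cpg_{cond}.bedGraph"))
        for verdict, label in (
            (allelesplit.Verdict.MATERNAL, "maternal"),
            (allelesplit.Verdict.PATERNAL, "paternal"),
        ):
            part = split.partitions[verdict]
            allele_tables[(cond, label)] = (
                methylome.call_cpg_methylation(part, reference) if len(part) else pd.DataFrame(columns=methylome.CPG_COLUMNS)
            )
        conv[cond] = methylome.conversion_efficiency(reads, reference)
    save_tsv(
        "conversion_efficiency.tsv",
        pd.DataFrame(
            [
                (cond, est.efficiency, est.n_converted, est.n_total, est.status)
                for cond, est in conv.items()
            ],
            columns=["condition", "efficiency", "n_converted", "n_total", "status"],
        ),
    )
    win = {
        cond: methylome.window_levels(cpg_tables[cond], chrom_lengths=truth.chrom_lengths)
        for cond in (CONTROL, TEST)
    }
    comparison = methylome.compare_window_sets(win[CONTROL]["mean_level"], win[TEST]["mean_level"])
    save_tsv("window_comparison.tsv", pd.DataFrame([comparison]))

    # 6. DMRs
    dmrs = dmr.segment_dmrs(cpg_tables[CONTROL], cpg_tables[TEST], config.dmr_params)
    gene_models = _demo_gene_models(truth, sim)
    categories = dmr.annotate_dmrs(dmrs, gene_models)
    dmr_bed = dmr.dmrs_to_bed(dmrs)
    dmr_bed["name"] = [f"{d.direction}:{cat}" for d, cat in zip(dmrs, categories)]
    io.write_bed(os.path.join(out, "dmrs.bed"), dmr_bed)
    outputs.append(os.path.join(out, "dmrs.bed"))
    save_tsv("dmr_summary.tsv", dmr.dmr_summary(dmrs))

    # 7. expression + imprinting cascade
    specs, imprint_list = _demo_expression_specs(gene_models)
    counts, allelic = synthdata.simulate_rnaseq(
        gene_models, specs, sim, truth, maternal, paternal, n_replicates=config.n_replicates
    )
    lengths = io.gene_exonic_lengths(gene_models)
    fpkm = {cond: expression.compute_fpkm(counts[cond], lengths).mean(axis=1) for cond in counts}
    de = expression.deg_flags(
        expression.differential_expression(counts[CONTROL], counts[TEST])
    )
    save_tsv("de_results.tsv", de.reset_index(names="gene_id"))
    cascade = expression.candidate_cascade(
        imprint_list, fpkm[CONTROL], fpkm[TEST], dmrs, gene_models, de, config.cascade_params
    )
    frac = {
        cond: allelesplit.allelic_fraction(
            rs, allelesplit.split_dataset(rs, snps, mode="rna").verdicts, gene_models
        )
        for cond, rs in allelic.items()
    }
    if CONTROL in frac and TEST in frac:
        expression.annotate_loi(cascade, frac[CONTROL], frac[TEST], config.allelic_bands)
    save_tsv("imprint_calls.tsv", expression.calls_to_table(cascade))

    # 8. morphometry
    metrics_rows = []
    rng = synthdata.stage_rng(config.seed, "slides")
    for group, n_particles in (("ICSI", 2), ("SCNT", 12)):
        slides = []
        for _ in range(3):
            spec = _demo_slide(rng, n_particles)
            img, _truth = synthdata.simulate_placenta_slide(spec, rng)
            slides.append(img)
        m = morphometry.compute_metrics(
            slides, morphometry.MorphometryParams(pixel_size_mm=config.pixel_size_mm)
        )
        metrics_rows.append(
            {
                "group": group,
                "cci_pct": m.cci_pct,
                "ccn": m.ccn,
                "n_dots": m.n_dots,
                "total_area_mm2": m.total_area_mm2,
                "thickness_mm": m.thickness_mm,
            }
        )
    save_tsv("morphometry.tsv", pd.DataFrame(metrics_rows))

    # 9. gestation statistics
    gest = synthdata.simulate_gestation(
        {"ICSI": 40, "SCNT": 40},
        {"ICSI": ("weibull", 4.0, 150.0), "SCNT": ("weibull", 2.0, 70.0)},
        seed=config.seed,
    )
    save_tsv("gestation.tsv", gest)
    ev = repro_stats.events_only(gest)
    a = ev[ev["group"] == "ICSI"]
    b = ev[ev["group"] == "SCNT"]
    lr = repro_stats.logrank_test(a["day"], a["event"], b["day"], b["event"])
    km_a = repro_stats.km_estimate(a["day"], a["event"], label="ICSI")
    km_b = repro_stats.km_estimate(b["day"], b["event"], label="SCNT")
    save_tsv(
        "survival.tsv",
        pd.DataFrame(
            [
                ("ICSI", km_a.median),
                ("SCNT", km_b.median),
                ("logrank_chi2", lr.statistic),
                ("logrank_p", lr.p_value),
            ],
            columns=["quantity", "value"],
        ),
    )

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_dmrs": len(dmrs),
        "outputs": {os.path.relpath(p, out): io.sha256_file(p) for p in sorted(outputs)},
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _demo_gene_models(truth: synthdata.TruthSet, sim: SimulationConfig) -> pd.DataFrame:
    """Genes overlapping each planted DMR plus evenly spaced background genes."""
    rows = []
    for i, d in enumerate(truth.dmrs.itertuples()):
        rows.append(
            {
                "gene_id": f"{d.kind}_gene{i + 1}",
                "chrom": d.chrom,
                "start": d.start,
                "end": d.end + 1000,
                "strand": "+",
                "exon_starts": str(d.start),
                "exon_ends": str(d.end + 1000),
            }
        )
    n_bg = 6
    spacing = sim.genome_length // (n_bg + 1)
    for j in range(n_bg):
        start = j * spacing + spacing // 4
        rows.append(
            {
                "gene_id": f"bg_gene{j + 1}",
                "chrom": truth.chrom_names[0],
                "start": start,
                "end": start + 1000,
                "strand": "-",
                "exon_starts": str(start),
                "exon_ends": str(start + 1000),
            }
        )
    return pd.DataFrame(rows)


def _demo_expression_specs(gene_models: pd.DataFrame):
    specs = []
    imprint_list = []
    for g in gene_models["gene_id"]:
        if g.startswith("maternal_imprint"):
            specs.append(
                GeneExpressionSpec(
                    g,
                    mean_control=100,
                    mean_test=320,
                    maternal_fraction_control=0.05,
                    maternal_fraction_test=0.5,
                    n_allelic_reads=200,
                )
            )
            imprint_list.append(g)
        else:
            specs.append(GeneExpressionSpec(g, mean_control=80, mean_test=80))
    return specs, imprint_list


def _demo_slide(rng: np.random.Generator, n_particles: int) -> SlideSpec:
    particles = []
    for _ in range(n_particles):
        ang = rng.uniform(0, 2 * np.pi)
        rad_frac = rng.uniform(0, 0.6)
        r = int(256 + 150 * rad_frac * np.sin(ang))
        c = int(256 + 200 * rad_frac * np.cos(ang))
        particles.append((r, c, int(rng.integers(3, 8))))
    return SlideSpec(particles=particles)
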