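"""Shared fixtures: one modest synthetic experiment reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from scntomics import allelesplit, methylome
from scntomics.synthdata import (
    CONTROL,
    TEST,
    DmrSpec,
    SimulationConfig,
    gen_hybrid_genomes,
    reference_genome,
    simulate_bisulfite_reads,
)
from scntomics.variants import InformativeSnp


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(
        genome_length=120_000,
        n_chromosomes=1,
        snp_rate=5e-3,
        background_meth=0.5,
        dmr_specs=[
            DmrSpec("maternal_imprint", 3200, 0.9, 0.1),
            DmrSpec("somatic_hypo", 3200, 0.8, 0.2),
        ],
        depth=30.0,
        read_length=100,
        conversion_efficiency=0.99,
        lambda_fraction=0.02,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def genomes(small_cfg):
    return gen_hybrid_genomes(small_cfg)


@pytest.fixture(scope="session")
def reference(genomes):
    maternal, _, _ = genomes
    return reference_genome(maternal)


@pytest.fixture(scope="session")
def snp_list(genomes) -> list[InformativeSnp]:
    _, _, truth = genomes
    return [
        InformativeSnp(r.chrom, int(r.pos), r.maternal_allele, r.paternal_allele)
        for r in truth.snps.itertuples()
    ]


@pytest.fixture(scope="session")
def bis_reads(genomes, small_cfg):
    maternal, paternal, truth = genomes
    return {
        cond: simulate_bisulfite_reads(maternal, paternal, truth, small_cfg, cond)
        for cond in (CONTROL, TEST)
    }


@pytest.fixture(scope="session")
def cpg_tables(bis_reads, reference):
    return {
        cond: methylome.call_cpg_methylation(reads, reference)
        for cond, reads in bis_reads.items()
    }


@pytest.fixture(scope="session")
def split_results(bis_reads, snp_list):
    return {
        cond: allelesplit.split_dataset(reads, snp_list, mode="bisulfite")
        for cond, reads in bis_reads.items()
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
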