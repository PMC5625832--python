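"""Shared fixtures: small synthetic inputs and one full default-scale run.

The ``default_run`` fixture executes the whole pipeline (simulate ->
call -> profile -> dmr -> enrich) once per session on the default 1 Mb
configuration; recovery and end-to-end tests all read from it.
"""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import wgbskit as wk


@pytest.fixture(scope="session")
def small_genome():
    """A tiny deterministic genome for unit tests."""
    cfg = wk.SimulationConfig(seed=11, chrom_length=20_000, n_genes=4,
                              gene_length_range=(1500, 3000),
                              n_dmrs=2, dmr_length=500, coverage_mean=12)
    genome, genes = wk.simulate_genome(cfg)
    return SimpleNamespace(config=cfg, genome=genome, genes=genes)


@pytest.fixture(scope="session")
def small_run(small_genome):
    cfg = small_genome.config
    samples, spikeins, truth = wk.simulate_counts(small_genome.genome, cfg)
    return SimpleNamespace(
        config=cfg,
        genome=small_genome.genome,
        genes=small_genome.genes,
        samples=samples,
        spikeins=spikeins,
        truth=truth,
    )


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default study conditions (1 Mb, 3 vs 3, 15x,
    20 planted CG DMRs of effect 0.5), fixed seed."""
    cfg = wk.SimulationConfig(seed=0)
    genome, genes = wk.simulate_genome(cfg)
    samples, spikeins, truth = wk.simulate_counts(genome, cfg)
    ids = cfg.sample_ids()
    g1_name, g2_name = cfg.groups[0][0], cfg.groups[1][0]
    g1 = [samples[s] for s, g in ids if g == g1_name]
    g2 = [samples[s] for s, g in ids if g == g2_name]
    first_sample = ids[0][0]
    conversion = wk.estimate_conversion(spikeins[first_sample])
    calls = wk.call_sites(samples[first_sample], conversion)
    diff = wk.differential_sites(g1, g2)
    dmrs = wk.call_dmrs(diff)
    mapped = wk.map_dmrs_to_genes(dmrs, genes)

    # gene sets over the simulated genes for enrichment
    gene_ids = sorted(g.gene_id for g in genes)
    half = gene_ids[: len(gene_ids) // 2]
    collection = wk.GeneSetCollection(
        sets={
            "SET:A": ("first half of genes", frozenset(half)),
            "SET:B": ("all genes", frozenset(gene_ids)),
        },
        universe=frozenset(gene_ids),
    )
    dmgs = wk.dmg_ids(mapped)
    enrichment = wk.enrich(dmgs, collection)
    composition = wk.composition_table(mapped)

    return SimpleNamespace(
        config=cfg,
        genome=genome,
        genes=genes,
        samples=samples,
        spikeins=spikeins,
        truth=truth,
        conversion=conversion,
        calls=calls,
        diff=diff,
        dmrs=dmrs,
        mapped=mapped,
        enrichment=enrichment,
        composition=composition,
        group_frames=(g1, g2),
    )


def make_report(rows):
    """Build a cytosine report frame from (chrom,pos,strand,m,u,ctx,tri)."""
    return pd.DataFrame(
        rows, columns=list(wk.io_formats.REPORT_COLUMNS)
    ).sort_values(["chrom", "pos"]).reset_index(drop=True)
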