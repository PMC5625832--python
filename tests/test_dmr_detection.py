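"""Fisher's exact test, differential sites, DMR calling and annotation."""

import math

import numpy as np
import pandas as pd
import pytest

import wgbskit as wk
from wgbskit.dmr_detection import (
    Dmr,
    UndefinedTestError,
    _gene_feature_intervals,
    verify_dmr_criteria,
)

from conftest import make_report


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by integer hypergeometric enumeration.

    All support tables with probability at most (1 + 1e-7) times the
    observed table's are summed; probabilities are exact rationals
    (integer numerators over a common denominator) until the final
    division.
    """
    m1, m2, c1 = a + b, c + d, a + c
    n = m1 + m2
    k_lo, k_hi = max(0, c1 - m2), min(m1, c1)
    nums = [math.comb(m1, k) * math.comb(m2, c1 - k)
            for k in range(k_lo, k_hi + 1)]
    obs = math.comb(m1, a) * math.comb(m2, c)
    total = sum(num for num in nums if num * 10**7 <= obs * (10**7 + 1))
    return total / math.comb(n, c1)


# --- scalar test ------------------------------------------------------------

def test_fisher_extreme_table():
    p = wk.fisher_exact_2x2(10, 0, 0, 10)
    assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)


def test_fisher_balanced_table_is_one():
    assert wk.fisher_exact_2x2(5, 5, 5, 5) == pytest.approx(1.0)


def test_fisher_all_zero_undefined():
    with pytest.raises(UndefinedTestError):
        wk.fisher_exact_2x2(0, 0, 0, 0)


def test_fisher_matches_enumeration_random_tables():
    rng = np.random.default_rng(8)
    for _ in range(300):
        a, b, c, d = rng.integers(0, 40, size=4)
        if a + b + c + d == 0:
            continue
        got = wk.fisher_exact_2x2(int(a), int(b), int(c), int(d))
        assert got == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)


def test_fisher_many_agrees_with_scalar():
    rng = np.random.default_rng(9)
    a, b, c, d = (rng.integers(0, 60, size=500) for _ in range(4))
    bulk = wk.fisher_exact_many(a, b, c, d)
    for i in range(500):
        if a[i] + b[i] + c[i] + d[i] == 0:
            assert np.isnan(bulk[i])
        else:
            scalar = wk.fisher_exact_2x2(int(a[i]), int(b[i]), int(c[i]),
                                         int(d[i]))
            assert bulk[i] == pytest.approx(scalar, abs=1e-10)


# --- differential sites -----------------------------------------------------

def _sample(rows):
    return make_report(rows)


def test_differential_sites_pools_and_tests():
    g1 = [
        _sample([("chr1", 10, "+", 6, 0, "CG", "CGA")]),
        _sample([("chr1", 10, "+", 6, 0, "CG", "CGA")]),
    ]
    g2 = [
        _sample([("chr1", 10, "+", 0, 6, "CG", "CGA")]),
        _sample([("chr1", 10, "+", 0, 6, "CG", "CGA")]),
    ]
    diff = wk.differential_sites(g1, g2)
    assert len(diff) == 1
    row = diff.iloc[0]
    assert (row["meth1"], row["unmeth1"]) == (12, 0)
    assert row["delta"] == pytest.approx(1.0)
    assert row["p_value"] == pytest.approx(2 / math.comb(24, 12), rel=1e-9)


def test_differential_sites_identical_groups():
    g = [_sample([("chr1", 10, "+", 6, 6, "CG", "CGA")])] * 2
    diff = wk.differential_sites(g, g)
    assert diff.iloc[0]["delta"] == 0.0
    assert diff.iloc[0]["p_value"] == pytest.approx(1.0)


def test_coverage_must_exceed_ten_strictly():
    g1 = [_sample([("chr1", 10, "+", 5, 5, "CG", "CGA")])]  # pooled 10
    g2 = [_sample([("chr1", 10, "+", 6, 6, "CG", "CGA")])]
    assert wk.differential_sites(g1, g2).empty
    g1b = [_sample([("chr1", 10, "+", 6, 5, "CG", "CGA")])]  # pooled 11
    assert len(wk.differential_sites(g1b, g2)) == 1


def test_site_in_one_group_only_dropped():
    g1 = [_sample([("chr1", 10, "+", 8, 8, "CG", "CGA"),
                   ("chr1", 20, "+", 8, 8, "CG", "CGA")])]
    g2 = [_sample([("chr1", 10, "+", 8, 8, "CG", "CGA")])]
    diff = wk.differential_sites(g1, g2)
    assert diff["pos"].tolist() == [10]


def test_group_swap_negates_deltas(small_run):
    ids = small_run.config.sample_ids()
    g1 = [small_run.samples[s] for s, g in ids if g == "HP"]
    g2 = [small_run.samples[s] for s, g in ids if g == "LP"]
    fwd = wk.differential_sites(g1, g2)
    rev = wk.differential_sites(g2, g1)
    assert np.allclose(fwd["delta"], -rev["delta"], atol=1e-12)
    assert np.allclose(fwd["p_value"], rev["p_value"], atol=1e-10)


# --- DMR calling ------------------------------------------------------------

def _diff_frame(rows):
    """rows: (chrom,pos,strand,context,meth1,unmeth1,meth2,unmeth2)."""
    df = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "strand", "context", "meth1", "unmeth1",
                 "meth2", "unmeth2"],
    )
    df["level1"] = df["meth1"] / (df["meth1"] + df["unmeth1"])
    df["level2"] = df["meth2"] / (df["meth2"] + df["unmeth2"])
    df["delta"] = df["level1"] - df["level2"]
    df["p_value"] = wk.fisher_exact_many(
        df["meth1"], df["unmeth1"], df["meth2"], df["unmeth2"])
    return df


def test_three_site_dmr_called():
    rows = [("chr1", pos, "+", "CG", 10, 0, 0, 10) for pos in (100, 120, 140)]
    (dmr,) = wk.call_dmrs(_diff_frame(rows))
    assert (dmr.start, dmr.end) == (100, 140)
    assert dmr.n_diff_sites == 3
    assert dmr.meth_diff == pytest.approx(1.0)
    # region-pooled table (30,0,0,30)
    assert dmr.p_value == pytest.approx(2 / math.comb(60, 30), rel=1e-9)
    assert dmr.width == 41


def test_two_sites_insufficient():
    rows = [("chr1", pos, "+", "CG", 10, 0, 0, 10) for pos in (100, 120)]
    assert wk.call_dmrs(_diff_frame(rows)) == []


def test_alternating_signs_not_one_region():
    rows = [
        ("chr1", 100, "+", "CG", 10, 0, 5, 15),   # +0.5... sign +
        ("chr1", 120, "+", "CG", 5, 15, 10, 0),   # sign -
        ("chr1", 140, "+", "CG", 10, 0, 5, 15),   # sign +
    ]
    dmrs = wk.call_dmrs(_diff_frame(rows))
    assert dmrs == []  # each same-sign run has < 3 sites


def test_gap_limit_splits_runs():
    rows = [("chr1", pos, "+", "CG", 10, 0, 0, 10)
            for pos in (100, 150, 300, 350, 400)]
    dmrs = wk.call_dmrs(_diff_frame(rows), max_gap=100)
    assert [(d.start, d.end) for d in dmrs] == [(300, 400)]


def test_region_screen_uses_context_threshold():
    # per-site deltas 0.25: qualify for CHH (0.2) but not CG (0.3)
    rows_chh = [("chr1", pos, "+", "CHH", 25, 75, 0, 100)
                for pos in (100, 110, 120)]
    rows_cg = [("chr2", pos, "+", "CG", 25, 75, 0, 100)
               for pos in (100, 110, 120)]
    dmrs = wk.call_dmrs(_diff_frame(rows_chh + rows_cg))
    assert [d.context for d in dmrs] == ["CHH"]


def test_called_dmrs_satisfy_printed_criteria(small_run):
    ids = small_run.config.sample_ids()
    g1 = [small_run.samples[s] for s, g in ids if g == "HP"]
    g2 = [small_run.samples[s] for s, g in ids if g == "LP"]
    diff = wk.differential_sites(g1, g2)
    dmrs = wk.call_dmrs(diff)
    assert dmrs, "expected at least one DMR on the planted data"
    for d in dmrs:
        assert verify_dmr_criteria(d, diff)


# --- gene annotation --------------------------------------------------------

def _gene(gene_id, tss, tts, exons, strand="+", chrom="chr1", **kw):
    return wk.GeneModel(gene_id, chrom, strand, tss, tts, exons, **kw)


def _dmr_at(start, end, chrom="chr1"):
    return Dmr(chrom=chrom, start=start, end=end, context="CG",
               n_diff_sites=3, level1=0.9, level2=0.1, meth_diff=0.8,
               p_value=1e-8)


def test_promoter_beats_intron_across_genes():
    gene_a = _gene("geneA", 1000, 5000, [(1000, 1500), (3000, 5000)])
    # DMR in geneA's first intron, and 1.5 kb upstream of geneB's TSS
    gene_b = _gene("geneB", 4000, 8000, [(4000, 8000)])
    (annotated,) = wk.map_dmrs_to_genes([_dmr_at(2400, 2600)],
                                        [gene_a, gene_b])
    assert annotated.annotation == "promoter_1_2kb"
    assert annotated.gene_id == "geneB"


def test_distal_intergenic_with_nearest_gene():
    gene = _gene("geneA", 1000, 2000, [(1000, 2000)])
    (annotated,) = wk.map_dmrs_to_genes([_dmr_at(12_000, 12_100)], [gene])
    assert annotated.annotation == "distal_intergenic"
    assert annotated.gene_id == "geneA"


def test_utr_outranks_exon():
    gene = _gene("geneA", 1000, 5000, [(1000, 2000), (3000, 5000)],
                 utr5=[(1000, 1200)])
    (annotated,) = wk.map_dmrs_to_genes([_dmr_at(1100, 1150)], [gene])
    assert annotated.annotation == "utr5"


def test_annotation_matches_brute_force(small_genome):
    """Random intervals annotate identically to an exhaustive scan over
    every gene's feature intervals in priority order."""
    rng = np.random.default_rng(5)
    genes = small_genome.genes
    flank = 3000
    prio = list(wk.dmr_detection.ANNOTATION_PRIORITY)
    for _ in range(100):
        start = int(rng.integers(1, 19_000))
        end = start + int(rng.integers(1, 400))
        (annotated,) = wk.map_dmrs_to_genes([_dmr_at(start, end)], genes,
                                            flank=flank)
        # brute force
        best = None
        for gene in genes:
            tss_dist = (0 if start <= gene.tss <= end
                        else min(abs(start - gene.tss), abs(end - gene.tss)))
            for cat, lo, hi in _gene_feature_intervals(gene, flank):
                if start <= hi and end >= lo:
                    key = (prio.index(cat), tss_dist, gene.gene_id)
                    if best is None or key < best:
                        best = key
        if best is None:
            assert annotated.annotation == "distal_intergenic"
        else:
            assert annotated.annotation == prio[best[0]]
            assert annotated.gene_id == best[2]
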