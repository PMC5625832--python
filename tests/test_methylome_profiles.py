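"""Levels, context proportions, element assignment, 9-mer motifs, CGIs."""

import numpy as np
import pandas as pd
import pytest

import wgbskit as wk
from wgbskit.methylome_profiles import (
    UndefinedLevelError,
    _element_intervals,
    assign_elements,
    cgi_classify_all,
    detect_cgi,
    is_hypermethylated,
)

from conftest import make_report


# --- site and region levels -------------------------------------------------

@pytest.mark.parametrize(
    "m, u, expected", [(3, 1, 0.75), (0, 7, 0.0), (5, 0, 1.0)]
)
def test_site_level_examples(m, u, expected):
    assert wk.site_level(m, u) == pytest.approx(expected, abs=1e-15)


def test_site_level_zero_coverage_undefined():
    with pytest.raises(UndefinedLevelError):
        wk.site_level(0, 0)


def test_region_level_is_unweighted_mean():
    rl = wk.region_level([(2, 2), (1, 3), (4, 0)])
    assert rl.n == 3
    assert rl.level == pytest.approx((0.5 + 0.25 + 1.0) / 3, abs=1e-15)
    assert wk.region_level([(1, 0)]).level == 1.0


def test_region_level_matches_loop_oracle():
    rng = np.random.default_rng(1)
    sites = [(int(m), int(u)) for m, u in
             zip(rng.integers(0, 30, 50), rng.integers(1, 30, 50))]
    total = 0.0
    for m, u in sites:
        total += m / (m + u)
    assert wk.region_level(sites).level == pytest.approx(total / 50,
                                                         abs=1e-12)


def test_region_level_concatenation_identity():
    """Level of a union = n-weighted mean of the parts' levels."""
    rng = np.random.default_rng(2)
    a = [(int(m), 1 + int(u)) for m, u in
         zip(rng.integers(0, 9, 7), rng.integers(0, 9, 7))]
    b = [(int(m), 1 + int(u)) for m, u in
         zip(rng.integers(0, 9, 13), rng.integers(0, 9, 13))]
    la, lb = wk.region_level(a), wk.region_level(b)
    lab = wk.region_level(a + b)
    weighted = (la.n * la.level + lb.n * lb.level) / (la.n + lb.n)
    assert lab.level == pytest.approx(weighted, abs=1e-12)


def test_region_level_empty_undefined():
    with pytest.raises(UndefinedLevelError):
        wk.region_level([])


# --- context proportions ----------------------------------------------------

def _calls_with_contexts(n_cg, n_chg, n_chh):
    rows = []
    pos = 1
    for ctx, tri, n in (("CG", "CGA", n_cg), ("CHG", "CAG", n_chg),
                        ("CHH", "CTT", n_chh)):
        for _ in range(n):
            rows.append(("chr1", pos, "+", 10, 0, ctx, tri))
            pos += 3
    df = make_report(rows)
    df["coverage"] = 10
    df["p_value"] = 1e-9
    df["q_value"] = 1e-9
    df["is_methylated"] = True
    return df


def test_context_proportions_shares():
    shares = wk.context_proportions(_calls_with_contexts(90, 2, 8))
    assert shares["CG"] == pytest.approx(0.9)
    assert shares["CHG"] == pytest.approx(0.02)
    assert shares["CHH"] == pytest.approx(0.08)
    assert shares.sum() == pytest.approx(1.0)


def test_context_proportions_all_cg():
    shares = wk.context_proportions(_calls_with_contexts(10, 0, 0))
    assert shares.tolist() == [1.0, 0.0, 0.0]


def test_context_proportions_no_methylated_undefined():
    df = _calls_with_contexts(3, 0, 0)
    df["is_methylated"] = False
    with pytest.raises(UndefinedLevelError):
        wk.context_proportions(df)


# --- functional elements ----------------------------------------------------

def _three_exon_gene(strand="+"):
    exons = [(100, 200), (300, 400), (500, 600)]
    if strand == "+":
        return wk.GeneModel("g", "chr1", "+", 100, 600, exons)
    return wk.GeneModel("g", "chr1", "-", 600, 100, exons[::-1])


@pytest.mark.parametrize(
    "pos, expected",
    [(150, "first_exon"), (250, "first_intron"), (350, "inner_exon"),
     (550, "last_exon"), (50, "upstream"), (650, "downstream"),
     (450, "inner_intron")],
)
def test_element_assignment_plus(pos, expected):
    gene = _three_exon_gene("+")
    assert assign_elements(gene, np.array([pos]))[0] == expected


def test_element_assignment_minus_mirrors():
    gene = _three_exon_gene("-")
    assert assign_elements(gene, np.array([550]))[0] == "first_exon"
    assert assign_elements(gene, np.array([150]))[0] == "last_exon"
    assert assign_elements(gene, np.array([650]))[0] == "upstream"
    assert assign_elements(gene, np.array([450]))[0] == "first_intron"


def test_element_partition_and_oracle(small_genome):
    """Every position in gene +/- flank maps to exactly one category, and
    the assignment equals a brute-force per-base interval lookup."""
    flank = 300
    for gene in small_genome.genes:
        positions = np.arange(gene.start - flank, gene.end + flank + 1)
        got = assign_elements(gene, positions, flank=flank)
        assert (got != "").all()
        # brute force: per-base scan of the category intervals
        intervals = _element_intervals(gene, flank)
        for pos, cat in zip(positions[::7], got[::7]):
            hits = [c for c, lo, hi in intervals if lo <= pos <= hi]
            assert hits == [cat]


def test_single_and_two_exon_gene_categories():
    g1 = wk.GeneModel("s", "chr1", "+", 100, 200, [(100, 200)])
    assert assign_elements(g1, np.array([150]))[0] == "first_exon"
    g2 = wk.GeneModel("d", "chr1", "+", 100, 400, [(100, 200), (300, 400)])
    cats = assign_elements(g2, np.array([150, 250, 350]))
    assert cats.tolist() == ["first_exon", "first_intron", "last_exon"]


def test_element_profiles_levels():
    gene = _three_exon_gene("+")
    rows = [
        ("chr1", 150, "+", 3, 1, "CG", "CGA"),   # first_exon, level .75
        ("chr1", 160, "+", 1, 3, "CG", "CGA"),   # first_exon, level .25
        ("chr1", 350, "+", 1, 0, "CHH", "CTT"),  # inner_exon
    ]
    calls = make_report(rows)
    profiles = wk.element_profiles(gene, calls, flank=50)
    assert profiles["first_exon"].levels["CG"] == pytest.approx(0.5)
    assert profiles["first_exon"].n_sites["CG"] == 2
    assert profiles["inner_exon"].levels["CHH"] == pytest.approx(1.0)
    assert np.isnan(profiles["downstream"].levels["CG"])


def test_tss_dip_shows_in_curves():
    """With promoter CG levels simulated low, the upstream/first-exon CG
    level sits below the inner-intron level."""
    cfg = wk.SimulationConfig(seed=13, chrom_length=120_000, n_genes=12,
                              gene_length_range=(3000, 5000), n_dmrs=0,
                              coverage_mean=20, promoter_level=0.1)
    genome, genes = wk.simulate_genome(cfg)
    samples, spikeins, _ = wk.simulate_counts(genome, cfg)
    conv = wk.estimate_conversion(spikeins["HP_1"])
    calls = wk.call_sites(samples["HP_1"], conv)
    profiles = wk.element_profiles(genes, calls, flank=1000)
    assert (profiles["first_exon"].levels["CG"]
            < profiles["inner_intron"].levels["CG"] - 0.1)


# --- motif matrices ---------------------------------------------------------

def test_motif_cg_forces_g_at_position_5():
    genome = wk.GenomeSequence({"chr1": "AAACGTTTTT"})
    calls = make_report([("chr1", 4, "+", 9, 1, "CG", "CGT")])
    calls["is_methylated"] = True
    m = wk.motif_matrix(calls, genome)["CG"]
    assert m.total == 1
    assert m.freq[3, 1] == 1.0  # position 4 pure C
    assert m.freq[4, 2] == 1.0  # position 5 pure G
    assert np.allclose(m.freq.sum(axis=1), 1.0)


def test_motif_planted_cag_modal():
    seq = "TTT" + "CAGTT" * 4 + "TTTTT"
    genome = wk.GenomeSequence({"chr1": seq})
    rows = []
    for i, base in enumerate(seq):
        if base == "C":
            rows.append(("chr1", i + 1, "+", 5, 0, "CHG", "CAG"))
    calls = make_report(rows)
    calls["is_methylated"] = True
    m = wk.motif_matrix(calls, genome)["CHG"]
    assert m.modal_dinucleotide == "AG"
    assert m.freq[4, 0] == 1.0 and m.freq[5, 2] == 1.0  # A then G


def test_motif_matches_substring_tally(small_run):
    conv = wk.estimate_conversion(small_run.spikeins["HP_1"])
    calls = wk.call_sites(small_run.samples["HP_1"], conv)
    matrices = wk.motif_matrix(calls, small_run.genome)
    seq = small_run.genome["chr1"]
    # independent tally: slice substrings around each methylated site
    meth = calls[calls["is_methylated"]]
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    counts = {ctx: np.zeros((9, 4)) for ctx in wk.CONTEXTS}
    totals = {ctx: 0 for ctx in wk.CONTEXTS}
    for r in meth.itertuples():
        i = r.pos - 1
        if r.strand == "+":
            if i - 3 < 0 or i + 6 > len(seq):
                continue
            kmer = seq[i - 3 : i + 6]
        else:
            if i - 5 < 0 or i + 4 > len(seq):
                continue
            kmer = "".join(comp[b] for b in reversed(seq[i - 5 : i + 4]))
        if "N" in kmer:
            continue
        for j, b in enumerate(kmer):
            counts[r.context][j, "ACGT".index(b)] += 1
        totals[r.context] += 1
    for ctx in wk.CONTEXTS:
        if totals[ctx]:
            assert np.allclose(matrices[ctx].freq,
                               counts[ctx] / totals[ctx], atol=1e-12)
            assert matrices[ctx].total == totals[ctx]
            assert np.allclose(matrices[ctx].freq.sum(axis=1), 1.0,
                               atol=1e-9)
            assert matrices[ctx].freq[3, 1] == 1.0


# --- CpG islands ------------------------------------------------------------

def test_cgi_toy_cg_repeat():
    """200 bp of CG repeats: GC 1.0, obs/exp = 100 * 200 / (100*100) = 2."""
    genome = wk.GenomeSequence({"chr1": "AT" * 150 + "CG" * 100 + "AT" * 150})
    islands = detect_cgi(genome)
    assert len(islands) == 1
    isl = islands[0]
    assert isl.gc_fraction == pytest.approx(1.0)
    assert isl.obs_exp_cpg == pytest.approx(2.0)
    assert isl.end - isl.start + 1 >= 200


def test_cgi_random_sequence_has_no_islands():
    rng = np.random.default_rng(0)
    seq = "".join(rng.choice(list("ACGT"), p=[0.31, 0.19, 0.19, 0.31],
                             size=5000))
    assert detect_cgi(wk.GenomeSequence({"chr1": seq})) == []


@pytest.mark.parametrize(
    "level, frac, expected",
    [(0.8, 0.5, True), (0.9, 0.05, False), (0.6, 0.9, False),
     (0.71, 0.1, True), (None, 0.5, False)],
)
def test_hypermethylation_rule(level, frac, expected):
    assert is_hypermethylated(level, frac) is expected


def test_classify_cgi_from_counts():
    genome = wk.GenomeSequence({"chr1": "AT" * 150 + "CG" * 100 + "AT" * 150})
    (island,) = detect_cgi(genome)
    rows = []
    # cover half of the island's 200 CG cytosine positions at depth 10,
    # heavily methylated
    positions = range(island.start, island.start + 100)
    for pos in positions:
        base = genome["chr1"][pos - 1]
        strand = "+" if base == "C" else "-"
        tri = "CGA" if strand == "+" else "CGC"
        rows.append(("chr1", pos, strand, 9, 1, "CG", tri))
    calls = make_report(rows)
    out = wk.classify_cgi(island, calls, genome=genome)
    assert out.level == pytest.approx(0.9)
    assert out.high_conf_fraction == pytest.approx(100 / 200)
    assert out.hypermethylated


def test_classify_cgi_insufficient_confidence():
    genome = wk.GenomeSequence({"chr1": "AT" * 150 + "CG" * 100 + "AT" * 150})
    (island,) = detect_cgi(genome)
    # only 4 positions covered (2% < 10%), highly methylated
    rows = [("chr1", island.start + i * 2, "+", 10, 0, "CG", "CGC")
            for i in range(4)]
    out = wk.classify_cgi(island, make_report(rows), genome=genome)
    assert out.level == pytest.approx(1.0)
    assert out.high_conf_fraction < 0.1
    assert not out.hypermethylated
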