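"""Synthetic WGBS inputs with planted ground truth.

The generator emulates the data regime of a two-group (3 vs 3 replicate)
sheep-ovary-style WGBS experiment: a random genome with CpG-island-like
GC-rich patches and non-overlapping multi-exon genes, per-cytosine
methylation levels drawn from context-specific Beta distributions (high
CG, near-zero CHG/CHH), Poisson read depth, incomplete bisulfite
conversion (an unmethylated C reads as C with probability
1 - conversion_rate, creating false methylation signal), a fully
unmethylated lambda-like spike-in, and planted DMRs of known location
and effect size. Truth (per-site levels per group, DMR intervals, the
conversion rate) is retained for recovery testing.

The per-site biological level is a property of the site: both groups
share it everywhere except inside planted DMRs, where one group's mean
is shifted by the planted delta. Replicates within a group share the
site's level and differ only in sampling (depth and read draws).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .io_formats import GeneModel, GenomeSequence, REPORT_COLUMNS
from .site_calling import classify_all_cytosines

logger = logging.getLogger(__name__)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic methylome.

    Defaults mirror the emulated experiment: two groups of three
    replicates, conversion rate 0.994, CG sites highly methylated
    (mean 0.7) and non-CG sites nearly unmethylated (mean 0.01),
    planted CG DMRs of effect size 0.5 on a 1 Mb genome at 15x depth.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    gc_fraction: float = 0.42
    n_cgi_patches: int = 5
    cgi_patch_length: int = 600
    n_genes: int = 40
    gene_length_range: tuple[int, int] = (2000, 6000)
    exon_range: tuple[int, int] = (3, 8)
    groups: tuple[tuple[str, int], tuple[str, int]] = (("HP", 3), ("LP", 3))
    coverage_mean: float = 15.0
    conversion_rate: float = 0.994
    context_level_means: dict = field(
        default_factory=lambda: {"CG": 0.7, "CHG": 0.01, "CHH": 0.01}
    )
    beta_concentration: float = 10.0
    n_dmrs: int = 20
    dmr_length: int = 1000
    dmr_delta: float = 0.5
    dmr_context: str = "CG"
    lambda_length: int = 48502
    promoter_level: Optional[float] = None  # CG mean near TSSs when set
    promoter_window: tuple[int, int] = (1000, 500)  # bp before / after TSS

    def validate(self) -> None:
        probs = {
            "gc_fraction": self.gc_fraction,
            "conversion_rate": self.conversion_rate,
            **{f"level[{k}]": v for k, v in self.context_level_means.items()},
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_dmrs > 0:
            if self.dmr_context not in self.context_level_means:
                raise ConfigurationError(
                    f"dmr_context {self.dmr_context!r} has no configured level"
                )
            base = self.context_level_means[self.dmr_context]
            if self.dmr_delta < 0 or base - self.dmr_delta < 0.0:
                raise ConfigurationError(
                    "dmr_delta must be in [0, mean level of the DMR context] "
                    "so the lowered group's mean stays in [0, 1]"
                )
        for name, count in self.groups:
            if count < 1:
                raise ConfigurationError(f"group {name!r} needs >= 1 replicate")
        if self.coverage_mean <= 0:
            raise ConfigurationError("coverage_mean must be positive")
        if self.beta_concentration <= 0:
            raise ConfigurationError("beta_concentration must be positive")

    def sample_ids(self) -> list[tuple[str, str]]:
        """(sample_id, group) pairs, e.g. HP_1 ... LP_3."""
        out = []
        for name, count in self.groups:
            for i in range(1, count + 1):
                out.append((f"{name}_{i}", name))
        return out


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery testing."""

    sites: pd.DataFrame  # chrom,pos,strand,context,level_<g1>,level_<g2>
    dmrs: pd.DataFrame  # chrom,start,end,context,delta (group1 - group2)
    conversion_rate: float
    group_names: tuple[str, str]

    def save(self, outdir: str | os.PathLike) -> None:
        outdir = str(outdir)
        os.makedirs(outdir, exist_ok=True)
        self.sites.to_csv(
            os.path.join(outdir, "truth_sites.tsv"), sep="\t", index=False
        )
        self.dmrs.to_csv(
            os.path.join(outdir, "truth_dmrs.tsv"), sep="\t", index=False
        )
        with open(os.path.join(outdir, "truth_meta.json"), "w") as fh:
            json.dump(
                {
                    "conversion_rate": self.conversion_rate,
                    "group_names": list(self.group_names),
                },
                fh,
                indent=2,
            )

    @classmethod
    def load(cls, outdir: str | os.PathLike) -> "SyntheticTruth":
        outdir = str(outdir)
        sites = pd.read_csv(os.path.join(outdir, "truth_sites.tsv"), sep="\t")
        dmrs = pd.read_csv(os.path.join(outdir, "truth_dmrs.tsv"), sep="\t")
        with open(os.path.join(outdir, "truth_meta.json")) as fh:
            meta = json.load(fh)
        return cls(sites, dmrs, meta["conversion_rate"],
                   tuple(meta["group_names"]))


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int,
                     gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=p)


def _cgi_patch(rng: np.random.Generator, length: int) -> np.ndarray:
    """GC-rich sequence with elevated CpG dinucleotide frequency."""
    out = []
    while len(out) < length:
        if rng.random() < 0.3:
            out.extend([b"C", b"G"])
        else:
            out.append(rng.choice(np.frombuffer(b"ACGT", dtype="S1"),
                                  p=[0.15, 0.35, 0.35, 0.15]))
    return np.array(out[:length], dtype="S1")


def simulate_genome(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneModel]]:
    """Random genome plus non-overlapping gene models; deterministic in
    config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    seqs: dict[str, str] = {}
    genes: list[GeneModel] = []
    min_len, max_len = config.gene_length_range
    # genes distributed across chromosomes proportionally
    genes_per_chrom = [
        config.n_genes // config.n_chroms
        + (1 if i < config.n_genes % config.n_chroms else 0)
        for i in range(config.n_chroms)
    ]
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        arr = _random_sequence(rng, config.chrom_length, config.gc_fraction)
        for _ in range(config.n_cgi_patches):
            if config.chrom_length <= config.cgi_patch_length:
                break
            start = int(
                rng.integers(0, config.chrom_length - config.cgi_patch_length)
            )
            arr[start : start + config.cgi_patch_length] = _cgi_patch(
                rng, config.cgi_patch_length
            )
        seqs[chrom] = arr.tobytes().decode("ascii")

        n_here = genes_per_chrom[ci]
        # slot the chromosome into equal compartments, one gene per slot,
        # so genes never overlap
        if n_here:
            slot = config.chrom_length // n_here
            if slot < max_len + 2:
                raise ConfigurationError(
                    f"chromosome of {config.chrom_length} bp cannot hold "
                    f"{n_here} genes of up to {max_len} bp"
                )
            for gi in range(n_here):
                glen = int(rng.integers(min_len, max_len + 1))
                lo = gi * slot + 1
                hi = (gi + 1) * slot - glen
                start = int(rng.integers(lo, max(lo + 1, hi)))
                end = start + glen - 1
                strand = "+" if rng.random() < 0.5 else "-"
                n_exons = int(rng.integers(*config.exon_range))
                exons = _random_exons(rng, start, end, n_exons)
                if strand == "-":
                    exons = exons[::-1]
                    tss, tts = end, start
                else:
                    tss, tts = start, end
                genes.append(
                    GeneModel(
                        gene_id=f"gene{len(genes) + 1:04d}",
                        chrom=chrom,
                        strand=strand,
                        tss=tss,
                        tts=tts,
                        exons=exons,
                    )
                )
    return GenomeSequence(seqs), genes


def _random_exons(
    rng: np.random.Generator, start: int, end: int, n_exons: int
) -> list[tuple[int, int]]:
    """n_exons non-overlapping intervals covering start and end, in
    genomic order (first exon starts at start, last ends at end)."""
    length = end - start + 1
    n_exons = min(n_exons, max(1, length // 100))
    if n_exons == 1:
        return [(start, end)]
    # pick 2*(n_exons-1) interior breakpoints: exon/intron boundaries
    cuts = np.sort(rng.choice(
        np.arange(1, length), size=2 * (n_exons - 1), replace=False
    ))
    bounds = [0, *cuts.tolist(), length]
    exons = []
    for i in range(0, len(bounds) - 1, 2):
        exons.append((start + bounds[i], start + bounds[i + 1] - 1))
    return exons


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------

def _beta_params(mean: float, conc: float) -> tuple[float, float]:
    mean = min(max(mean, 1e-6), 1 - 1e-6)
    return mean * conc, (1 - mean) * conc


def _plant_dmrs(
    rng: np.random.Generator,
    config: SimulationConfig,
    sites: pd.DataFrame,
) -> pd.DataFrame:
    """Choose non-overlapping planted DMR intervals, each holding at least
    3 cytosines of the DMR context; alternating effect direction."""
    if config.n_dmrs == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "context",
                                     "delta"])
    chroms = sorted(sites["chrom"].unique())
    per_chrom = [
        config.n_dmrs // len(chroms)
        + (1 if i < config.n_dmrs % len(chroms) else 0)
        for i in range(len(chroms))
    ]
    base = config.context_level_means[config.dmr_context]
    rows = []
    k = 0
    for chrom, n_here in zip(chroms, per_chrom):
        if n_here == 0:
            continue
        chrom_sites = sites[
            (sites["chrom"] == chrom) & (sites["context"] == config.dmr_context)
        ]
        positions = chrom_sites["pos"].to_numpy()
        slot = config.chrom_length // n_here
        if slot <= config.dmr_length:
            raise ConfigurationError(
                "chromosome too short for the requested planted DMRs"
            )
        for gi in range(n_here):
            lo_bound = gi * slot + 1
            hi_bound = (gi + 1) * slot - config.dmr_length
            for _ in range(100):  # retry until >= 3 context sites inside
                start = int(rng.integers(lo_bound, hi_bound))
                end = start + config.dmr_length - 1
                inside = np.count_nonzero(
                    (positions >= start) & (positions <= end)
                )
                if inside >= 3:
                    break
            else:
                raise ConfigurationError(
                    "could not place a planted DMR with >= 3 context sites"
                )
            # signed delta = level(group1) - level(group2); the effect is
            # applied by lowering one group, so direction can alternate
            # freely (clipping guards Beta-draw tails)
            direction = 1 if k % 2 == 0 else -1
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "context": config.dmr_context,
                    "delta": direction * config.dmr_delta,
                }
            )
            k += 1
    return pd.DataFrame(rows)


def simulate_counts(
    genome: GenomeSequence,
    config: SimulationConfig,
) -> tuple[dict[str, pd.DataFrame], dict[str, pd.DataFrame], SyntheticTruth]:
    """Per-sample cytosine reports, lambda spike-in reports and the truth.

    Every cytosine of the genome appears in every sample's report (zero
    rows included, Bismark CX style). Observed methylation probability at
    a site with biological level m is m + (1 - m) * (1 - conversion_rate).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sites = classify_all_cytosines(genome)
    n = len(sites)
    g1, g2 = config.groups[0][0], config.groups[1][0]

    # per-site biological level, shared by both groups outside DMRs
    conc = config.beta_concentration
    m_base = np.empty(n)
    ctx_arr = sites["context"].to_numpy()
    for ctx, mean in config.context_level_means.items():
        mask = ctx_arr == ctx
        if mean <= 0.0 or mean >= 1.0:  # degenerate: no biological spread
            m_base[mask] = mean
        else:
            a, b = _beta_params(mean, conc)
            m_base[mask] = rng.beta(a, b, size=int(mask.sum()))

    if config.promoter_level is not None:
        # CG sites near a TSS get a distinct (typically low) mean; the
        # gene placement is re-derived deterministically from the config
        _, genes = simulate_genome(config)
        before, after = config.promoter_window
        a, b = _beta_params(config.promoter_level, conc)
        for gene in genes:
            if gene.strand == "+":
                lo, hi = gene.tss - before, gene.tss + after
            else:
                lo, hi = gene.tss - after, gene.tss + before
            mask = (
                (sites["chrom"] == gene.chrom).to_numpy()
                & (sites["pos"].to_numpy() >= lo)
                & (sites["pos"].to_numpy() <= hi)
                & (ctx_arr == "CG")
            )
            m_base[mask] = rng.beta(a, b, size=int(mask.sum()))

    dmrs = _plant_dmrs(rng, config, sites)
    m1 = m_base.copy()
    m2 = m_base.copy()
    pos_arr = sites["pos"].to_numpy()
    chrom_arr = sites["chrom"].to_numpy()
    for row in dmrs.itertuples(index=False):
        mask = (
            (chrom_arr == row.chrom)
            & (pos_arr >= row.start)
            & (pos_arr <= row.end)
            & (ctx_arr == row.context)
        )
        if row.delta >= 0:
            m2[mask] = np.clip(m_base[mask] - row.delta, 0.0, 1.0)
        else:
            m1[mask] = np.clip(m_base[mask] + row.delta, 0.0, 1.0)

    fail = 1.0 - config.conversion_rate
    samples: dict[str, pd.DataFrame] = {}
    spikeins: dict[str, pd.DataFrame] = {}
    lam_genome, lam_sites = _lambda_sites(config)
    for sample_id, group in config.sample_ids():
        m = m1 if group == g1 else m2
        p_obs = m + (1.0 - m) * fail
        depth = rng.poisson(config.coverage_mean, size=n)
        meth = rng.binomial(depth, p_obs)
        report = sites.copy()
        report["meth_count"] = meth
        report["unmeth_count"] = depth - meth
        samples[sample_id] = report[list(REPORT_COLUMNS)]

        lam_depth = rng.poisson(config.coverage_mean, size=len(lam_sites))
        lam_meth = rng.binomial(lam_depth, fail)  # truly unmethylated
        lam = lam_sites.copy()
        lam["meth_count"] = lam_meth
        lam["unmeth_count"] = lam_depth - lam_meth
        spikeins[sample_id] = lam[list(REPORT_COLUMNS)]

    truth_sites = sites[["chrom", "pos", "strand", "context"]].copy()
    truth_sites[f"level_{g1}"] = m1
    truth_sites[f"level_{g2}"] = m2
    truth = SyntheticTruth(
        sites=truth_sites,
        dmrs=dmrs,
        conversion_rate=config.conversion_rate,
        group_names=(g1, g2),
    )
    return samples, spikeins, truth


def _lambda_sites(
    config: SimulationConfig,
) -> tuple[GenomeSequence, pd.DataFrame]:
    """Deterministic lambda-like spike-in genome and its cytosine table."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    arr = _random_sequence(rng, config.lambda_length, 0.50)
    genome = GenomeSequence({"lambda": arr.tobytes().decode("ascii")})
    sites = classify_all_cytosines(genome)
    return genome, sites


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

def simulate_qpcr(
    fold_changes: dict[str, float],
    reference_gene: str = "GAPDH",
    groups: tuple[str, str] = ("HP", "LP"),
    calibrator_group: str = "LP",
    n_biological: int = 3,
    n_technical: int = 3,
    baseline_ct: float = 25.0,
    reference_ct: float = 18.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table for target genes with the given fold changes.

    A gene with fold change f in the non-calibrator group gets a target
    Ct lowered by log2(f) there (one fewer cycle per doubling), plus
    Gaussian noise of sd *noise_sd* on every well. Replicate structure is
    *n_biological* x *n_technical* per group.
    """
    if reference_gene in fold_changes:
        raise ConfigurationError("reference gene cannot have a fold change")
    if calibrator_group not in groups:
        raise ConfigurationError(
            f"calibrator group {calibrator_group!r} not among {groups}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for group in groups:
        for b in range(1, n_biological + 1):
            sample = f"{group}_{b}"
            for gene, fold in list(fold_changes.items()) + [
                (reference_gene, 1.0)
            ]:
                if gene == reference_gene:
                    base = reference_ct
                else:
                    base = baseline_ct
                    if group != calibrator_group:
                        base = base - np.log2(fold)
                for t in range(1, n_technical + 1):
                    ct = base + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
                    rows.append(
                        {
                            "sample": sample,
                            "group": group,
                            "gene": gene,
                            "replicate": t,
                            "ct": ct,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_simulation(
    outdir: str | os.PathLike,
    genome: GenomeSequence,
    genes: list[GeneModel],
    samples: dict[str, pd.DataFrame],
    spikeins: dict[str, pd.DataFrame],
    truth: SyntheticTruth,
) -> None:
    """Write a complete simulated data set: genome FASTA, genes BED12,
    per-sample cytosine and lambda reports, truth sidecar."""
    from .io_formats import write_cytosine_report, write_gene_models_bed12

    outdir = str(outdir)
    os.makedirs(outdir, exist_ok=True)
    genome.to_fasta(os.path.join(outdir, "genome.fa"))
    write_gene_models_bed12(genes, os.path.join(outdir, "genes.bed"))
    for sample_id, df in samples.items():
        write_cytosine_report(
            df, os.path.join(outdir, f"{sample_id}.cx_report.tsv")
        )
    for sample_id, df in spikeins.items():
        write_cytosine_report(
            df, os.path.join(outdir, f"{sample_id}.lambda.tsv")
        )
    truth.save(outdir)
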