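"""Methylation levels, context proportions, gene-element profiles,
9-mer sequence preferences and CpG-island classification.

The level of a single cytosine is the fraction of reads supporting
methylation, C_i / (C_i + T_i). The level of a region is the unweighted
mean of per-site levels over the n covered cytosines in it,
(1/n) * sum_i C_i / (C_i + T_i) — deliberately not the pooled-count
ratio, so deeply covered sites do not dominate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import CONTEXTS, GeneModel, GenomeSequence
from .site_calling import reverse_complement

logger = logging.getLogger(__name__)

#: the seven gene functional-element categories, 5'->3'
ELEMENT_CATEGORIES = (
    "upstream",
    "first_exon",
    "first_intron",
    "inner_exon",
    "inner_intron",
    "last_exon",
    "downstream",
)

BASES = ("A", "C", "G", "T")


class UndefinedLevelError(ValueError):
    """A methylation level was requested over zero covered sites."""


def site_level(meth_count: int, unmeth_count: int) -> float:
    """Methylation level of one cytosine: C_i / (C_i + T_i)."""
    cov = meth_count + unmeth_count
    if cov < 1:
        raise UndefinedLevelError("site has zero coverage")
    return meth_count / cov


@dataclass(frozen=True)
class RegionLevel:
    """Mean per-site methylation level over a region."""

    n: int
    level: float


def region_level(sites: Iterable[tuple[int, int]]) -> RegionLevel:
    """Unweighted mean of per-site levels over (meth, unmeth) pairs."""
    levels = [site_level(m, u) for m, u in sites]
    if not levels:
        raise UndefinedLevelError("region has no covered sites")
    return RegionLevel(n=len(levels), level=float(np.mean(levels)))


def context_proportions(calls: pd.DataFrame) -> pd.Series:
    """Share of each context among methylated cytosines.

    Input is a calls frame from :func:`wgbskit.site_calling.call_sites`.
    Returns a Series indexed by CG/CHG/CHH summing to 1.
    """
    if calls.empty:
        raise UndefinedLevelError("no calls supplied")
    meth = calls[calls["is_methylated"]]
    total = len(meth)
    if total == 0:
        raise UndefinedLevelError("no methylated sites; proportions undefined")
    counts = meth["context"].value_counts()
    return pd.Series(
        {ctx: counts.get(ctx, 0) / total for ctx in CONTEXTS}, name="share"
    )


# ---------------------------------------------------------------------------
# functional-element profiles
# ---------------------------------------------------------------------------

def _element_intervals(
    gene: GeneModel, flank: int
) -> list[tuple[str, int, int]]:
    """(category, lo, hi) genomic 1-based inclusive intervals for one gene.

    The intervals partition [span_start - flank, span_end + flank] minus
    nothing: flanks are strand-oriented (upstream is 5' of the TSS).
    Single-exon genes populate first_exon only; two-exon genes have a
    first and a last exon but no inner exon.
    """
    n = len(gene.exons)
    out: list[tuple[str, int, int]] = []
    if gene.strand == "+":
        out.append(("upstream", gene.tss - flank, gene.tss - 1))
        out.append(("downstream", gene.tts + 1, gene.tts + flank))
    else:
        out.append(("upstream", gene.tss + 1, gene.tss + flank))
        out.append(("downstream", gene.tts - flank, gene.tts - 1))
    for i, (a, b) in enumerate(gene.exons):
        if n == 1:
            cat = "first_exon"
        elif i == 0:
            cat = "first_exon"
        elif i == n - 1:
            cat = "last_exon"
        else:
            cat = "inner_exon"
        out.append((cat, min(a, b), max(a, b)))
    introns = gene.introns()  # transcription order
    for i, (a, b) in enumerate(introns):
        cat = "first_intron" if i == 0 else "inner_intron"
        out.append((cat, a, b))
    return [(c, lo, hi) for c, lo, hi in out if lo <= hi]


def assign_elements(
    gene: GeneModel, positions: np.ndarray, flank: int = 3000
) -> np.ndarray:
    """Category of each genomic position relative to *gene*.

    Positions outside gene span +/- flank get the empty string; every
    position inside maps to exactly one of :data:`ELEMENT_CATEGORIES`.
    """
    positions = np.asarray(positions)
    out = np.full(positions.shape, "", dtype=object)
    for cat, lo, hi in _element_intervals(gene, flank):
        mask = (positions >= lo) & (positions <= hi)
        out[mask] = cat
    return out


@dataclass
class FunctionalElementProfile:
    """Per-context levels and binned positional curves for one category."""

    category: str
    levels: dict[str, float]  # context -> mean level (NaN when no sites)
    n_sites: dict[str, int]
    curve: dict[str, np.ndarray] = field(default_factory=dict)  # context -> bins


def _binned_curve(
    rel_pos: np.ndarray, levels: np.ndarray, n_bins: int
) -> np.ndarray:
    """Mean level in n_bins equal-width bins of relative position [0, 1]."""
    out = np.full(n_bins, np.nan)
    if len(rel_pos) == 0:
        return out
    idx = np.minimum((rel_pos * n_bins).astype(int), n_bins - 1)
    for b in range(n_bins):
        vals = levels[idx == b]
        if len(vals):
            out[b] = float(np.mean(vals))
    return out


def element_profiles(
    genes: Sequence[GeneModel] | GeneModel,
    calls: pd.DataFrame,
    flank: int = 3000,
    n_bins: int = 20,
) -> dict[str, FunctionalElementProfile]:
    """Per-category methylation levels and positional curves.

    Every covered cytosine within a gene's span +/- *flank* is assigned to
    exactly one of the seven categories (strand-aware). Levels are the
    unweighted mean of per-site levels; curves average per-gene binned
    curves across genes (elements shorter than *n_bins* bases fall back
    to a single bin).
    """
    if isinstance(genes, GeneModel):
        genes = [genes]
    covered = calls[(calls["meth_count"] + calls["unmeth_count"]) >= 1]
    lv = covered["meth_count"] / (covered["meth_count"] + covered["unmeth_count"])
    covered = covered.assign(level=lv)

    per_cat_levels: dict[str, dict[str, list[np.ndarray]]] = {
        c: {ctx: [] for ctx in CONTEXTS} for c in ELEMENT_CATEGORIES
    }
    per_cat_curves: dict[str, dict[str, list[np.ndarray]]] = {
        c: {ctx: [] for ctx in CONTEXTS} for c in ELEMENT_CATEGORIES
    }

    by_chrom = dict(tuple(covered.groupby("chrom")))
    for gene in genes:
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        lo, hi = gene.start - flank, gene.end + flank
        win = sub[(sub["pos"] >= lo) & (sub["pos"] <= hi)]
        if win.empty:
            continue
        pos = win["pos"].to_numpy()
        for cat, a, b in _element_intervals(gene, flank):
            m = (pos >= a) & (pos <= b)
            if not m.any():
                continue
            chunk = win[m]
            width = b - a + 1
            bins = n_bins if width >= n_bins else 1
            # orient positions 5'->3' along the transcript
            if gene.strand == "+":
                rel = (chunk["pos"].to_numpy() - a) / width
            else:
                rel = (b - chunk["pos"].to_numpy()) / width
            for ctx in CONTEXTS:
                cm = chunk["context"] == ctx
                if not cm.any():
                    continue
                lvl = chunk.loc[cm, "level"].to_numpy()
                per_cat_levels[cat][ctx].append(lvl)
                curve = _binned_curve(rel[cm.to_numpy()], lvl, bins)
                if bins == 1:
                    curve = np.repeat(curve, n_bins)
                per_cat_curves[cat][ctx].append(curve)

    profiles: dict[str, FunctionalElementProfile] = {}
    for cat in ELEMENT_CATEGORIES:
        levels = {}
        n_sites = {}
        curves = {}
        for ctx in CONTEXTS:
            chunks = per_cat_levels[cat][ctx]
            if chunks:
                allv = np.concatenate(chunks)
                levels[ctx] = float(np.mean(allv))
                n_sites[ctx] = int(len(allv))
            else:
                levels[ctx] = float("nan")
                n_sites[ctx] = 0
            ccs = per_cat_curves[cat][ctx]
            if ccs:
                stack = np.vstack(ccs)
                counts = (~np.isnan(stack)).sum(axis=0)
                sums = np.nansum(stack, axis=0)
                curves[ctx] = np.where(counts > 0, sums / np.maximum(counts, 1),
                                       np.nan)
            else:
                curves[ctx] = np.full(n_bins, np.nan)
        profiles[cat] = FunctionalElementProfile(cat, levels, n_sites, curves)
    return profiles


def profiles_to_frame(
    profiles: dict[str, FunctionalElementProfile]
) -> pd.DataFrame:
    rows = []
    for cat in ELEMENT_CATEGORIES:
        p = profiles[cat]
        for ctx in CONTEXTS:
            rows.append(
                {
                    "category": cat,
                    "context": ctx,
                    "n_sites": p.n_sites[ctx],
                    "level": p.levels[ctx],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# 9-mer sequence preferences
# ---------------------------------------------------------------------------

@dataclass
class MotifMatrix:
    """Position-wise base frequencies of 9-mers around methylcytosines.

    The methylcytosine sits at position 4 (1-based): 3 bases upstream and
    5 downstream, read on the cytosine's own strand. ``freq`` is 9x4 over
    A/C/G/T; each row sums to 1 and row 4 is pure C.
    """

    context: str
    freq: np.ndarray  # (9, 4)
    total: int
    modal_dinucleotide: Optional[str]  # positions 5-6


def motif_matrix(
    calls: pd.DataFrame, genome: GenomeSequence, k: int = 9, c_offset: int = 3
) -> dict[str, MotifMatrix]:
    """Tally strand-oriented 9-mers around every methylated cytosine.

    Sites whose 9-mer would run off the chromosome are skipped. Returns
    one MotifMatrix per context, plus the modal dinucleotide at positions
    5-6 (the two bases directly 3' of the mC).
    """
    meth = calls[calls["is_methylated"]]
    counts = {ctx: np.zeros((k, 4), dtype=np.int64) for ctx in CONTEXTS}
    dinuc: dict[str, dict[str, int]] = {ctx: {} for ctx in CONTEXTS}
    totals = {ctx: 0 for ctx in CONTEXTS}
    base_idx = {b: i for i, b in enumerate(BASES)}
    down = k - c_offset - 1  # bases 3' of the mC
    for chrom, pos, strand, ctx in zip(
        meth["chrom"], meth["pos"], meth["strand"], meth["context"]
    ):
        seq = genome[chrom]
        i = int(pos) - 1
        if strand == "+":
            lo, hi = i - c_offset, i + down + 1
            if lo < 0 or hi > len(seq):
                continue
            kmer = seq[lo:hi]
        else:
            lo, hi = i - down, i + c_offset + 1
            if lo < 0 or hi > len(seq):
                continue
            kmer = reverse_complement(seq[lo:hi])
        if "N" in kmer:
            continue
        for j, b in enumerate(kmer):
            counts[ctx][j, base_idx[b]] += 1
        dn = kmer[c_offset + 1 : c_offset + 3]
        dinuc[ctx][dn] = dinuc[ctx].get(dn, 0) + 1
        totals[ctx] += 1

    out: dict[str, MotifMatrix] = {}
    for ctx in CONTEXTS:
        total = totals[ctx]
        if total:
            freq = counts[ctx] / total
            modal = max(sorted(dinuc[ctx]), key=lambda d: dinuc[ctx][d])
        else:
            freq = np.full((k, 4), np.nan)
            modal = None
        out[ctx] = MotifMatrix(ctx, freq, total, modal)
    return out


# ---------------------------------------------------------------------------
# CpG islands
# ---------------------------------------------------------------------------

@dataclass
class CpGIsland:
    """A CG-dense segment with its hypermethylation classification.

    ``hypermethylated`` follows the rule: region CG level > 0.7, except
    when fewer than 10% of the island's CG positions carry high-confidence
    (coverage-qualified) calls.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int
    gc_fraction: float
    obs_exp_cpg: float
    level: Optional[float] = None
    n_sites: int = 0
    high_conf_fraction: float = 0.0
    hypermethylated: bool = False


def is_hypermethylated(
    level: Optional[float],
    high_conf_fraction: float,
    level_threshold: float = 0.7,
    min_high_conf: float = 0.1,
) -> bool:
    """The hypermethylated-CGI rule as a pure predicate."""
    if level is None or np.isnan(level):
        return False
    return level > level_threshold and high_conf_fraction >= min_high_conf


def _island_stats(seq: str) -> tuple[float, float]:
    n = len(seq)
    c = seq.count("C")
    g = seq.count("G")
    cpg = seq.count("CG")
    gc = (c + g) / n if n else 0.0
    if c and g:
        obs_exp = cpg * n / (c * g)
    else:
        obs_exp = 0.0
    return gc, obs_exp


def detect_cgi(
    genome: GenomeSequence,
    min_length: int = 200,
    min_gc: float = 0.5,
    min_obs_exp: float = 0.6,
    window: int = 200,
) -> list[CpGIsland]:
    """CpG islands by the Gardiner-Garden & Frommer criteria.

    Slides a *window*-bp window one base at a time; windows with
    GC >= *min_gc* and observed/expected CpG >= *min_obs_exp* are merged
    when they overlap. Each merged segment is trimmed to its outermost
    CpG dinucleotides and kept only if the trimmed interval itself still
    meets all three criteria (length >= *min_length*, GC, obs/exp),
    which stops window margins from dragging flanking AT-rich sequence
    into the reported island.
    """
    islands: list[CpGIsland] = []
    for chrom in sorted(genome.seqs):
        seq = genome[chrom]
        L = len(seq)
        if L < window:
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        is_c = (arr == ord("C")).astype(np.int64)
        is_g = (arr == ord("G")).astype(np.int64)
        cpg = ((arr[:-1] == ord("C")) & (arr[1:] == ord("G"))).astype(np.int64)
        csum_c = np.concatenate([[0], np.cumsum(is_c)])
        csum_g = np.concatenate([[0], np.cumsum(is_g)])
        csum_cpg = np.concatenate([[0], np.cumsum(cpg)])
        starts = np.arange(0, L - window + 1)
        nc = csum_c[starts + window] - csum_c[starts]
        ng = csum_g[starts + window] - csum_g[starts]
        # CpG dinucleotides fully inside the window
        ncpg = csum_cpg[np.minimum(starts + window - 1, L - 1)] - csum_cpg[starts]
        gc = (nc + ng) / window
        with np.errstate(divide="ignore", invalid="ignore"):
            obs_exp = np.where(nc * ng > 0, ncpg * window / (nc * ng), 0.0)
        ok = (gc >= min_gc) & (obs_exp >= min_obs_exp)
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            continue
        # merge overlapping qualifying windows [i, i+window)
        breaks = np.flatnonzero(np.diff(idx) >= window)
        seg_starts = np.concatenate([[0], breaks + 1])
        seg_ends = np.concatenate([breaks, [idx.size - 1]])
        for a, b in zip(seg_starts, seg_ends):
            lo = int(idx[a])
            hi = int(idx[b]) + window  # exclusive
            sub = seq[lo:hi]
            first = sub.find("CG")
            if first < 0:
                continue
            lo2 = lo + first
            hi2 = lo + sub.rfind("CG") + 2
            if hi2 - lo2 < min_length:
                continue
            gc_f, oe = _island_stats(seq[lo2:hi2])
            if gc_f < min_gc or oe < min_obs_exp:
                continue
            islands.append(
                CpGIsland(
                    chrom=chrom,
                    start=lo2 + 1,
                    end=hi2,
                    gc_fraction=gc_f,
                    obs_exp_cpg=oe,
                )
            )
    return islands


def classify_cgi(
    island: CpGIsland,
    calls: pd.DataFrame,
    genome: Optional[GenomeSequence] = None,
    level_threshold: float = 0.7,
    min_high_conf: float = 0.1,
    min_cov: int = 4,
) -> CpGIsland:
    """Fill in methylation level and hypermethylation status of an island.

    The level is the region level over covered CG-context sites inside
    the island. ``high_conf_fraction`` is the share of the island's CG
    cytosine positions (from the genome when given, else from the calls
    frame) whose coverage reaches *min_cov*.
    """
    sub = calls[
        (calls["chrom"] == island.chrom)
        & (calls["pos"] >= island.start)
        & (calls["pos"] <= island.end)
        & (calls["context"] == "CG")
    ]
    cov = sub["meth_count"] + sub["unmeth_count"]
    covered = sub[cov >= 1]
    if genome is not None:
        seq = genome[island.chrom][island.start - 1 : island.end]
        # CG cytosines on both strands = C of a CG on + plus G of a CG on -
        n_positions = 2 * seq.count("CG")
    else:
        n_positions = len(sub)
    n_high = int((cov >= min_cov).sum())
    if len(covered):
        lv = region_level(
            list(zip(covered["meth_count"], covered["unmeth_count"]))
        )
        island.level = lv.level
        island.n_sites = lv.n
    else:
        island.level = None
        island.n_sites = 0
    island.high_conf_fraction = n_high / n_positions if n_positions else 0.0
    island.hypermethylated = is_hypermethylated(
        island.level, island.high_conf_fraction, level_threshold, min_high_conf
    )
    return island


def cgi_classify_all(
    genome: GenomeSequence,
    calls: pd.DataFrame,
    **detect_kwargs,
) -> list[CpGIsland]:
    """Detect all CpG islands and classify each for hypermethylation."""
    islands = detect_cgi(genome, **detect_kwargs)
    return [classify_cgi(i, calls, genome=genome) for i in islands]


def cgi_to_frame(islands: Sequence[CpGIsland]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": i.chrom,
                "start": i.start,
                "end": i.end,
                "gc_fraction": i.gc_fraction,
                "obs_exp_cpg": i.obs_exp_cpg,
                "level": i.level if i.level is not None else float("nan"),
                "n_sites": i.n_sites,
                "high_conf_fraction": i.high_conf_fraction,
                "hypermethylated": i.hypermethylated,
            }
            for i in islands
        ]
    )
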