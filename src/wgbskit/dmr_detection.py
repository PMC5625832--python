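"""Differentially methylated region (DMR) calling between two groups.

Replicate counts are pooled within each group. Sites with pooled coverage
strictly greater than ``min_pooled_cov`` (default 10) in both groups are
compared: the per-site difference of methylation levels and Fisher's exact
test on the pooled 2x2 (methylated/unmethylated x group) table.

A DMR is a run of same-context, same-sign differential sites (per-site
|difference| past the context threshold, consecutive qualifying sites no
more than ``max_gap`` bp apart) that, taken as a region, satisfies the
three criteria: at least ``min_sites`` (3) differential sites, region
level difference beyond 0.3 (CG) or 0.2 (CHG/CHH) in absolute value, and
Fisher's exact p below ``alpha`` (0.05) on the region-pooled counts.
Region levels are the unweighted mean of per-site levels (per group) over
all coverage-qualified sites of the region's context inside its bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneModel

logger = logging.getLogger(__name__)

#: annotation categories in priority order (highest first); a DMR gets the
#: first category it overlaps across all genes within reach
ANNOTATION_PRIORITY = (
    "promoter_1kb",
    "promoter_1_2kb",
    "promoter_2_3kb",
    "utr5",
    "utr3",
    "first_exon",
    "other_exon",
    "first_intron",
    "other_intron",
)
DISTAL = "distal_intergenic"


class UndefinedTestError(ValueError):
    """Fisher's exact test on an all-zero table is undefined."""


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities no greater than the observed
    table's; exact for all inputs.
    """
    if a + b + c + d == 0:
        raise UndefinedTestError("all-zero 2x2 table")
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def fisher_exact_many(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, d: np.ndarray,
    chunk: int = 20000,
) -> np.ndarray:
    """Vectorized two-sided Fisher's exact test over parallel count arrays.

    Same tie convention as :func:`fisher_exact_2x2` (a support table is
    counted when its probability is within a factor 1 + 1e-7 of the
    observed one). Processes in chunks to bound memory.
    """
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    c = np.asarray(c, dtype=np.int64)
    d = np.asarray(d, dtype=np.int64)
    n_tables = len(a)
    out = np.empty(n_tables, dtype=float)
    for lo in range(0, n_tables, chunk):
        hi = min(lo + chunk, n_tables)
        aa, bb, cc, dd = a[lo:hi], b[lo:hi], c[lo:hi], d[lo:hi]
        m1 = aa + bb  # row margins
        m2 = cc + dd
        n = m1 + m2
        c1 = aa + cc  # first column margin
        k_lo = np.maximum(0, c1 - m2)
        k_hi = np.minimum(m1, c1)
        width = int((k_hi - k_lo).max()) + 1 if hi > lo else 1
        k = k_lo[:, None] + np.arange(width)[None, :]
        valid = k <= k_hi[:, None]
        k_safe = np.where(valid, k, k_lo[:, None])
        pmf = stats.hypergeom.pmf(k_safe, n[:, None], m1[:, None], c1[:, None])
        pmf = np.where(valid, pmf, 0.0)
        p_obs = stats.hypergeom.pmf(aa, n, m1, c1)
        take = pmf <= p_obs[:, None] * (1 + 1e-7)
        out[lo:hi] = np.minimum((pmf * take).sum(axis=1), 1.0)
        zero = n == 0
        if zero.any():
            out[lo:hi][zero] = np.nan
    return out


# ---------------------------------------------------------------------------
# differential sites
# ---------------------------------------------------------------------------

_KEY = ["chrom", "pos", "strand", "context"]


def _pool_group(samples: Sequence[pd.DataFrame]) -> pd.DataFrame:
    if not samples:
        raise ValueError("group has no samples")
    cat = pd.concat(
        [s[_KEY + ["meth_count", "unmeth_count"]] for s in samples],
        ignore_index=True,
    )
    return cat.groupby(_KEY, as_index=False, sort=False).sum()


def differential_sites(
    group1: Sequence[pd.DataFrame],
    group2: Sequence[pd.DataFrame],
    min_pooled_cov: int = 10,
    compute_pvalues: bool = True,
) -> pd.DataFrame:
    """Per-site group comparison on within-group pooled counts.

    Sites must exceed *min_pooled_cov* coverage (strictly) in both groups;
    sites present in only one group are dropped with a logged tally.
    Returns a frame sorted by (chrom, pos) with pooled counts, per-group
    levels, ``delta`` = level1 - level2 and (optionally) the per-site
    Fisher p-value.
    """
    p1 = _pool_group(group1).rename(
        columns={"meth_count": "meth1", "unmeth_count": "unmeth1"}
    )
    p2 = _pool_group(group2).rename(
        columns={"meth_count": "meth2", "unmeth_count": "unmeth2"}
    )
    merged = p1.merge(p2, on=_KEY, how="outer", indicator=True)
    one_sided = int((merged["_merge"] != "both").sum())
    if one_sided:
        logger.info("%d site(s) present in one group only; dropped", one_sided)
    merged = merged[merged["_merge"] == "both"].drop(columns="_merge")
    for col in ("meth1", "unmeth1", "meth2", "unmeth2"):
        merged[col] = merged[col].astype(np.int64)
    cov1 = merged["meth1"] + merged["unmeth1"]
    cov2 = merged["meth2"] + merged["unmeth2"]
    keep = (cov1 > min_pooled_cov) & (cov2 > min_pooled_cov)
    merged = merged[keep].copy()
    cov1, cov2 = cov1[keep], cov2[keep]
    merged["level1"] = merged["meth1"] / cov1
    merged["level2"] = merged["meth2"] / cov2
    merged["delta"] = merged["level1"] - merged["level2"]
    if compute_pvalues:
        merged["p_value"] = fisher_exact_many(
            merged["meth1"].to_numpy(),
            merged["unmeth1"].to_numpy(),
            merged["meth2"].to_numpy(),
            merged["unmeth2"].to_numpy(),
        )
    merged = merged.sort_values(["chrom", "pos"], kind="mergesort")
    return merged.reset_index(drop=True)


# ---------------------------------------------------------------------------
# DMR calling
# ---------------------------------------------------------------------------

@dataclass
class Dmr:
    """A called differentially methylated region (1-based inclusive)."""

    chrom: str
    start: int
    end: int
    context: str
    n_diff_sites: int
    level1: float
    level2: float
    meth_diff: float  # level1 - level2
    p_value: float
    annotation: Optional[str] = None
    gene_strand: Optional[str] = None
    gene_id: Optional[str] = None

    @property
    def width(self) -> int:
        return self.end - self.start + 1


def _context_threshold(context: str, delta_cg: float, delta_non_cg: float) -> float:
    return delta_cg if context == "CG" else delta_non_cg


def call_dmrs(
    diff_sites: pd.DataFrame,
    max_gap: int = 100,
    min_sites: int = 3,
    delta_cg: float = 0.3,
    delta_non_cg: float = 0.2,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[Dmr]:
    """Call DMRs from a differential-site table (see module docstring).

    With *bh_correct* the candidate regions' Fisher p-values are
    Benjamini-Hochberg adjusted before the *alpha* screen (off by
    default: the screen is on raw p).
    """
    candidates: list[tuple[str, str, pd.DataFrame, int]] = []
    for (chrom, context), sub in diff_sites.groupby(["chrom", "context"],
                                                    sort=True):
        thr = _context_threshold(context, delta_cg, delta_non_cg)
        sub = sub.sort_values("pos", kind="mergesort")
        qual = sub[np.abs(sub["delta"]) >= thr]
        if qual.empty:
            continue
        pos = qual["pos"].to_numpy()
        sign = np.sign(qual["delta"].to_numpy())
        new_run = np.ones(len(qual), dtype=bool)
        new_run[1:] = (np.diff(pos) > max_gap) | (sign[1:] != sign[:-1])
        run_id = np.cumsum(new_run)
        for rid in np.unique(run_id):
            members = qual[run_id == rid]
            if len(members) < min_sites:
                continue
            start = int(members["pos"].min())
            end = int(members["pos"].max())
            region = sub[(sub["pos"] >= start) & (sub["pos"] <= end)]
            candidates.append((chrom, context, region, len(members)))

    if not candidates:
        return []

    stats_rows = []
    for chrom, context, region, n_qual in candidates:
        level1 = float(region["level1"].mean())  # region level, per group
        level2 = float(region["level2"].mean())
        table = (
            int(region["meth1"].sum()),
            int(region["unmeth1"].sum()),
            int(region["meth2"].sum()),
            int(region["unmeth2"].sum()),
        )
        stats_rows.append((level1, level2, table))
    pvals = fisher_exact_many(
        np.array([t[2][0] for t in stats_rows]),
        np.array([t[2][1] for t in stats_rows]),
        np.array([t[2][2] for t in stats_rows]),
        np.array([t[2][3] for t in stats_rows]),
    )
    screen_p = pvals
    if bh_correct:
        _, screen_p, _, _ = multipletests(pvals, method="fdr_bh")

    dmrs: list[Dmr] = []
    for (chrom, context, region, n_qual), (l1, l2, _), p, sp in zip(
        candidates, stats_rows, pvals, screen_p
    ):
        thr = _context_threshold(context, delta_cg, delta_non_cg)
        meth_diff = l1 - l2
        if n_qual < min_sites:
            continue
        if abs(meth_diff) <= thr:
            continue
        if not sp < alpha:
            continue
        dmrs.append(
            Dmr(
                chrom=chrom,
                start=int(region["pos"].min()),
                end=int(region["pos"].max()),
                context=context,
                n_diff_sites=n_qual,
                level1=l1,
                level2=l2,
                meth_diff=meth_diff,
                p_value=float(p),
            )
        )
    dmrs.sort(key=lambda d: (d.chrom, d.start, d.context))
    logger.info("called %d DMR(s) from %d candidate region(s)",
                len(dmrs), len(candidates))
    return dmrs


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def _gene_feature_intervals(
    gene: GeneModel, flank: int
) -> list[tuple[str, int, int]]:
    """(category, lo, hi) 1-based inclusive annotation intervals."""
    out: list[tuple[str, int, int]] = []
    tss = gene.tss
    if gene.strand == "+":
        bands = [
            ("promoter_1kb", tss - 1000, tss - 1),
            ("promoter_1_2kb", tss - 2000, tss - 1001),
            ("promoter_2_3kb", tss - flank, tss - 2001),
        ]
    else:
        bands = [
            ("promoter_1kb", tss + 1, tss + 1000),
            ("promoter_1_2kb", tss + 1001, tss + 2000),
            ("promoter_2_3kb", tss + 2001, tss + flank),
        ]
    out.extend(bands)
    for name, ivs in (("utr5", gene.utr5), ("utr3", gene.utr3)):
        for a, b in ivs:
            out.append((name, min(a, b), max(a, b)))
    for i, (a, b) in enumerate(gene.exons):
        cat = "first_exon" if i == 0 else "other_exon"
        out.append((cat, min(a, b), max(a, b)))
    for i, (a, b) in enumerate(gene.introns()):
        cat = "first_intron" if i == 0 else "other_intron"
        out.append((cat, a, b))
    return [(c, lo, hi) for c, lo, hi in out if lo <= hi]


def map_dmrs_to_genes(
    dmrs: Sequence[Dmr], genes: Sequence[GeneModel], flank: int = 3000
) -> list[Dmr]:
    """Annotate each DMR with its highest-priority overlapping category.

    Priority: promoter bands (nearest first), then 5'/3' UTR, first/other
    exon, first/other intron. A DMR overlapping none of these for any
    gene (including one only inside a downstream flank) is
    ``distal_intergenic`` and carries the nearest gene (smallest distance
    to the TSS, ties by gene_id). Category ties across genes break by
    TSS distance, then gene_id.
    """
    prio = {cat: i for i, cat in enumerate(ANNOTATION_PRIORITY)}
    trees: dict[str, IntervalTree] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for gene in genes:
        by_chrom.setdefault(gene.chrom, []).append(gene)
        tree = trees.setdefault(gene.chrom, IntervalTree())
        lo = gene.start - flank
        hi = gene.end + flank
        tree[lo : hi + 1] = gene

    out: list[Dmr] = []
    for dmr in dmrs:
        hits = trees.get(dmr.chrom, IntervalTree())[dmr.start : dmr.end + 1]
        best: Optional[tuple[int, int, str, GeneModel]] = None
        for hit in hits:
            gene: GeneModel = hit.data
            tss_dist = _interval_tss_distance(dmr, gene)
            for cat, lo, hi in _gene_feature_intervals(gene, flank):
                if dmr.start <= hi and dmr.end >= lo:
                    key = (prio[cat], tss_dist, gene.gene_id, gene)
                    if best is None or key[:3] < best[:3]:
                        best = key
        if best is not None:
            _, _, _, gene = best
            cat = ANNOTATION_PRIORITY[best[0]]
            out.append(
                replace(dmr, annotation=cat, gene_strand=gene.strand,
                        gene_id=gene.gene_id)
            )
        else:
            nearest = _nearest_gene(dmr, by_chrom.get(dmr.chrom, []))
            out.append(
                replace(
                    dmr,
                    annotation=DISTAL,
                    gene_strand=nearest.strand if nearest else None,
                    gene_id=nearest.gene_id if nearest else None,
                )
            )
    return out


def _interval_tss_distance(dmr: Dmr, gene: GeneModel) -> int:
    if dmr.start <= gene.tss <= dmr.end:
        return 0
    return min(abs(dmr.start - gene.tss), abs(dmr.end - gene.tss))


def _nearest_gene(
    dmr: Dmr, genes: Sequence[GeneModel]
) -> Optional[GeneModel]:
    best = None
    for gene in sorted(genes, key=lambda g: g.gene_id):
        dist = _interval_tss_distance(dmr, gene)
        if best is None or dist < best[0]:
            best = (dist, gene)
    return best[1] if best else None


def verify_dmr_criteria(
    dmr: Dmr,
    diff_sites: pd.DataFrame,
    min_sites: int = 3,
    delta_cg: float = 0.3,
    delta_non_cg: float = 0.2,
    alpha: float = 0.05,
) -> bool:
    """Re-derive the three DMR criteria for one called region from the
    differential-site table (independent post-hoc check)."""
    thr = _context_threshold(dmr.context, delta_cg, delta_non_cg)
    region = diff_sites[
        (diff_sites["chrom"] == dmr.chrom)
        & (diff_sites["context"] == dmr.context)
        & (diff_sites["pos"] >= dmr.start)
        & (diff_sites["pos"] <= dmr.end)
    ]
    n_qual = int((np.abs(region["delta"]) >= thr).sum())
    meth_diff = float(region["level1"].mean() - region["level2"].mean())
    p = fisher_exact_2x2(
        int(region["meth1"].sum()),
        int(region["unmeth1"].sum()),
        int(region["meth2"].sum()),
        int(region["unmeth2"].sum()),
    )
    return n_qual >= min_sites and abs(meth_diff) > thr and p < alpha
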