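"""Conversion-rate estimation, cytosine context typing and methylation calls.

Bisulfite treatment converts unmethylated cytosines to uracil (sequenced
as T) while methylated cytosines stay C. A fully unmethylated spike-in
(lambda phage) therefore estimates the conversion rate, and a truly
unmethylated genomic cytosine yields a C read only on conversion failure.
Each covered cytosine is tested against that failure rate with an exact
one-sided binomial test; Benjamini-Hochberg controls the FDR across all
tested sites, and a site is called methylated when its coverage is at
least ``min_cov`` (default 4) and its q-value is below ``fdr``
(default 0.05).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomeSequence

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: columns appended to a cytosine report by :func:`call_sites`
CALL_COLUMNS = ("coverage", "p_value", "q_value", "is_methylated")


class EstimationError(ValueError):
    """Conversion rate cannot be estimated from the given spike-in."""


class ClassificationError(ValueError):
    """The queried position does not hold a cytosine on the given strand."""


@dataclass(frozen=True)
class ConversionEstimate:
    """Bisulfite conversion rate from an unmethylated spike-in genome."""

    converted: int  # spike-in cytosine observations read as T
    total: int  # all spike-in cytosine observations

    @property
    def rate(self) -> float:
        return self.converted / self.total


def estimate_conversion(spikein: pd.DataFrame) -> ConversionEstimate:
    """Estimate the conversion rate from spike-in cytosine counts.

    The spike-in genome is unmethylated by construction, so every read
    still showing C is a conversion failure:
    rate = sum(unmeth) / sum(meth + unmeth).
    """
    converted = int(spikein["unmeth_count"].sum())
    failed = int(spikein["meth_count"].sum())
    total = converted + failed
    if total <= 0:
        raise EstimationError("spike-in has zero cytosine observations")
    return ConversionEstimate(converted=converted, total=total)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def classify_context(
    genome: GenomeSequence, chrom: str, pos: int, strand: str
) -> tuple[str, str]:
    """Type the cytosine at (chrom, pos, strand) as CG / CHG / CHH.

    The context is read from the two bases 3' of the cytosine on its own
    strand (H = A, C or T). Positions whose downstream bases run off the
    chromosome end are N-padded and fall through to CHH.
    Returns (context, trinucleotide).
    """
    seq = genome[chrom]
    i = pos - 1
    if strand == "+":
        if i < 0 or i >= len(seq) or seq[i] != "C":
            raise ClassificationError(
                f"{chrom}:{pos}:+ is {'out of range' if i < 0 or i >= len(seq) else seq[i]!r}, not C"
            )
        tri = seq[i : i + 3]
        tri = tri + "N" * (3 - len(tri))
    elif strand == "-":
        if i < 0 or i >= len(seq) or seq[i] != "G":
            raise ClassificationError(
                f"{chrom}:{pos}:- is {'out of range' if i < 0 or i >= len(seq) else seq[i]!r} on +, not C on -"
            )
        chunk = seq[max(i - 2, 0) : i + 1]
        chunk = "N" * (3 - len(chunk)) + chunk
        tri = reverse_complement(chunk)
    else:
        raise ValueError(f"bad strand {strand!r}")
    if tri[1] == "G":
        context = "CG"
    elif tri[2] == "G" and tri[1] in "ACT":
        context = "CHG"
    else:
        context = "CHH"  # includes N-padded ends
    return context, tri


def classify_all_cytosines(genome: GenomeSequence) -> pd.DataFrame:
    """Vectorized scan of every cytosine on both strands.

    Returns a DataFrame (chrom, pos, strand, context, trinucleotide)
    sorted by (chrom, pos).
    """
    comp_lut = np.full(256, ord("N"), dtype=np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp_lut[a] = b

    frames = []
    for chrom in sorted(genome.seqs):
        seq = genome[chrom]
        if not seq:
            continue
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
        n_pad = np.uint8(ord("N"))

        def shifted(a: np.ndarray, k: int) -> np.ndarray:
            """a shifted so out[i] = a[i+k], N-padded at the ends."""
            out = np.full_like(a, n_pad)
            if k >= 0:
                if k < len(a):
                    out[: len(a) - k] = a[k:]
            else:
                out[-k:] = a[:k]
            return out

        for strand in "+-":
            if strand == "+":
                mask = arr == ord("C")
                b1, b2 = shifted(arr, 1), shifted(arr, 2)
            else:
                # a C on the minus strand is a G on plus; its 3' neighbours
                # are plus positions i-1 and i-2, complemented
                mask = arr == ord("G")
                b1, b2 = comp_lut[shifted(arr, -1)], comp_lut[shifted(arr, -2)]
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            first, second = b1[idx], b2[idx]
            is_h = (first == ord("A")) | (first == ord("C")) | (first == ord("T"))
            context = np.where(
                first == ord("G"),
                "CG",
                np.where((second == ord("G")) & is_h, "CHG", "CHH"),
            )
            tri_bytes = np.empty((idx.size, 3), dtype=np.uint8)
            tri_bytes[:, 0] = ord("C")
            tri_bytes[:, 1] = first
            tri_bytes[:, 2] = second
            tri = tri_bytes.view("S3").ravel().astype("U3")
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "pos": idx + 1,
                        "strand": strand,
                        "context": context,
                        "trinucleotide": tri,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=["chrom", "pos", "strand", "context", "trinucleotide"]
        )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
        drop=True
    )


def call_sites(
    records: pd.DataFrame,
    conversion: ConversionEstimate,
    min_cov: int = 4,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Binomial methylation calls with BH FDR control.

    For each site with coverage >= *min_cov*, the p-value is the exact
    upper binomial tail P(X >= meth_count | n=coverage, p0=1-rate): under
    the null of no methylation, a methylated read arises only from a
    conversion failure. q-values are Benjamini-Hochberg over all tested
    sites; ``is_methylated`` requires q < *fdr*. Sites below *min_cov*
    are returned untested (p/q = NaN, not methylated).
    """
    rate = conversion.rate
    if not 0.0 < rate <= 1.0:
        raise ValueError(
            f"conversion rate must be in (0, 1], got {rate!r}; a rate of 0 "
            "makes the null probability 1 and the test degenerate"
        )
    p0 = 1.0 - rate
    out = records.copy()
    cov = out["meth_count"].to_numpy() + out["unmeth_count"].to_numpy()
    out["coverage"] = cov
    tested = cov >= min_cov
    p = np.full(len(out), np.nan)
    if tested.any():
        k = out["meth_count"].to_numpy()[tested]
        n = cov[tested]
        # P(X >= k) = sf(k-1); k = 0 gives exactly 1
        p[tested] = stats.binom.sf(k - 1, n, p0)
    q = np.full(len(out), np.nan)
    if tested.any():
        _, q_adj, _, _ = multipletests(p[tested], method="fdr_bh")
        q[tested] = q_adj
    out["p_value"] = p
    out["q_value"] = q
    out["is_methylated"] = tested & (q < fdr)
    n_called = int(out["is_methylated"].sum())
    logger.info(
        "called %d/%d tested sites methylated (min_cov=%d, fdr=%g)",
        n_called, int(tested.sum()), min_cov, fdr,
    )
    return out
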