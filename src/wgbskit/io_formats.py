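"""Readers and writers for the external formats the pipeline touches.

Internal coordinate convention: 1-based, fully-closed intervals everywhere
(the dialect of Bismark cytosine reports and of printed genomic intervals
like ``chr12:74369711-74369728``). BED input/output converts to and from
0-based half-open at the boundary, and nowhere else.

The canonical in-memory container for per-cytosine counts is a pandas
DataFrame with the columns of :data:`REPORT_COLUMNS`, sorted by
(chrom, pos); :class:`CytosineRecord` is the row-level view of the same
data for record-at-a-time APIs.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

CONTEXTS = ("CG", "CHG", "CHH")

#: Bismark CX-report-style columns, tab separated, in file order.
REPORT_COLUMNS = (
    "chrom",
    "pos",
    "strand",
    "meth_count",
    "unmeth_count",
    "context",
    "trinucleotide",
)

DMR_TABLE_COLUMNS = (
    "methChr",
    "start",
    "end",
    "width",
    "methDiff",
    "pvalue",
    "methType",
    "Annotation",
    "geneStrand",
    "geneId",
)


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class CytosineRecord(NamedTuple):
    """One cytosine position with its methylated/unmethylated read counts."""

    chrom: str
    pos: int  # 1-based
    strand: str  # '+' or '-'
    meth_count: int
    unmeth_count: int
    context: str  # CG / CHG / CHH
    trinucleotide: str


def context_from_trinucleotide(tri: str) -> Optional[str]:
    """Context implied by a 3-mer starting at the cytosine (5'->3' on its
    own strand). Returns None when an N makes the context ambiguous."""
    if len(tri) != 3 or tri[0] != "C":
        return None
    if "N" in tri[1:]:
        return None
    if tri[1] == "G":
        return "CG"
    if tri[2] == "G":
        return "CHG"
    return "CHH"


@dataclass
class GenomeSequence:
    """Uppercase reference sequences keyed by chromosome name."""

    seqs: dict[str, str]

    def __post_init__(self) -> None:
        cleaned: dict[str, str] = {}
        for name, seq in self.seqs.items():
            seq = seq.upper()
            if set(seq) - set("ACGTN"):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValidationError(
                    f"chromosome {name!r} contains non-ACGTN symbols: {bad}"
                )
            cleaned[name] = seq
        self.seqs = cleaned

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.seqs.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.seqs

    def __getitem__(self, name: str) -> str:
        return self.seqs[name]

    @classmethod
    def from_fasta(cls, path: str | os.PathLike) -> "GenomeSequence":
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValidationError(f"duplicate chromosome name {rec.id!r}")
            seqs[rec.id] = str(rec.seq)
        return cls(seqs)

    def to_fasta(self, path: str | os.PathLike, width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.seqs.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)


@dataclass
class GeneModel:
    """A gene with its exon structure, in transcription order.

    ``tss``/``tts`` are the transcription start/termination sites (1-based);
    for minus-strand genes tss > tts. ``exons`` are 1-based inclusive
    intervals listed 5'->3' in transcription order.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: list[tuple[int, int]]
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene_id}: bad strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"{self.gene_id}: gene has no exons")
        genomic = sorted((min(a, b), max(a, b)) for a, b in self.exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise ValidationError(f"{self.gene_id}: overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.exons) != expected:
            raise ValidationError(
                f"{self.gene_id}: exons not in transcription order"
            )
        if self.strand == "+" and self.tss > self.tts:
            raise ValidationError(f"{self.gene_id}: tss after tts on + strand")
        if self.strand == "-" and self.tss < self.tts:
            raise ValidationError(f"{self.gene_id}: tss before tts on - strand")

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate of the gene span."""
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate of the gene span."""
        return max(self.tss, self.tts)

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals in transcription order (may be empty)."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append((e1 + 1, s2 - 1))
            else:
                out.append((e2 + 1, s1 - 1))
        # normalise to (low, high) genomic intervals
        return [(min(a, b), max(a, b)) for a, b in out]


# ---------------------------------------------------------------------------
# cytosine reports
# ---------------------------------------------------------------------------

def _empty_report() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype="int64"),
            "strand": pd.Series(dtype=str),
            "meth_count": pd.Series(dtype="int64"),
            "unmeth_count": pd.Series(dtype="int64"),
            "context": pd.Series(dtype=str),
            "trinucleotide": pd.Series(dtype=str),
        }
    )


def read_cytosine_report(
    path: str | os.PathLike, genome: Optional[GenomeSequence] = None
) -> pd.DataFrame:
    """Read a Bismark-style 7-column cytosine report.

    Returns a DataFrame with :data:`REPORT_COLUMNS`, sorted by (chrom, pos).
    When *genome* is given, context and trinucleotide are re-derived from
    the sequence; the genome wins and discrepancies are logged.
    """
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            header=None,
            names=list(REPORT_COLUMNS),
            dtype={
                "chrom": str,
                "strand": str,
                "context": str,
                "trinucleotide": str,
            },
            comment=None,
        )
    except pd.errors.EmptyDataError:
        return _empty_report()
    except (ValueError, pd.errors.ParserError) as exc:
        raise ParseError(f"{path}: malformed cytosine report: {exc}") from exc

    for col in ("pos", "meth_count", "unmeth_count"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            line = int(bad.idxmax()) + 1
            raise ParseError(
                f"{path}: line {line}: non-integer value in column {col!r}"
            )
        df[col] = numeric.astype("int64")

    _validate_report(df, str(path))

    if genome is not None:
        from .site_calling import classify_context  # local to avoid cycle

        mismatches = 0
        contexts = []
        tris = []
        for chrom, pos, strand, ctx, tri in zip(
            df["chrom"], df["pos"], df["strand"], df["context"],
            df["trinucleotide"],
        ):
            g_ctx, g_tri = classify_context(genome, chrom, int(pos), strand)
            if g_ctx != ctx or g_tri != tri:
                mismatches += 1
            contexts.append(g_ctx)
            tris.append(g_tri)
        if mismatches:
            logger.warning(
                "%s: %d record(s) disagreed with genome-derived context; "
                "genome-derived values used", path, mismatches,
            )
        df["context"] = contexts
        df["trinucleotide"] = tris

    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def _validate_report(df: pd.DataFrame, source: str) -> None:
    if (df["meth_count"] < 0).any() or (df["unmeth_count"] < 0).any():
        bad = ((df["meth_count"] < 0) | (df["unmeth_count"] < 0)).idxmax()
        raise ValidationError(f"{source}: line {int(bad) + 1}: negative count")
    if (df["pos"] < 1).any():
        bad = (df["pos"] < 1).idxmax()
        raise ValidationError(f"{source}: line {int(bad) + 1}: pos < 1")
    bad_strand = ~df["strand"].isin(["+", "-"])
    if bad_strand.any():
        raise ValidationError(
            f"{source}: line {int(bad_strand.idxmax()) + 1}: bad strand token"
        )
    bad_ctx = ~df["context"].isin(CONTEXTS)
    if bad_ctx.any():
        line = int(bad_ctx.idxmax()) + 1
        tok = df["context"].iloc[line - 1]
        raise ValidationError(
            f"{source}: line {line}: unknown context token {tok!r}"
        )
    # context must be consistent with the trinucleotide when unambiguous
    implied = df["trinucleotide"].map(context_from_trinucleotide)
    inconsistent = implied.notna() & (implied != df["context"])
    if inconsistent.any():
        line = int(inconsistent.idxmax()) + 1
        raise ValidationError(
            f"{source}: line {line}: context "
            f"{df['context'].iloc[line - 1]!r} inconsistent with "
            f"trinucleotide {df['trinucleotide'].iloc[line - 1]!r}"
        )


def write_cytosine_report(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a cytosine report DataFrame back to 7-column TSV."""
    df.to_csv(path, sep="\t", header=False, index=False,
              columns=list(REPORT_COLUMNS))


def iter_records(df: pd.DataFrame) -> Iterator[CytosineRecord]:
    """Yield rows of a cytosine report frame as CytosineRecord tuples."""
    for row in df.itertuples(index=False):
        yield CytosineRecord(*row)


def records_to_frame(records: Iterable[CytosineRecord]) -> pd.DataFrame:
    records = list(records)
    if not records:
        return _empty_report()
    df = pd.DataFrame(records, columns=list(REPORT_COLUMNS))
    return df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | os.PathLike, dialect: str) -> list[GeneModel]:
    """Read gene models from BED12 or GFF3.

    BED12 half-open 0-based coordinates are converted to the internal
    1-based inclusive convention; minus-strand exon lists are reversed to
    transcription order.
    """
    dialect = dialect.upper()
    if dialect == "BED12":
        return _read_bed12(path)
    if dialect == "GFF3":
        return _read_gff3(path)
    raise ValueError(f"unknown gene-model dialect {dialect!r}")


def _read_bed12(path: str | os.PathLike) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}: line {lineno}: BED12 needs 12 columns, "
                    f"got {len(fields)}"
                )
            try:
                chrom = fields[0]
                chrom_start = int(fields[1])
                chrom_end = int(fields[2])
                name = fields[3]
                strand = fields[5]
                thick_start = int(fields[6])
                thick_end = int(fields[7])
                block_count = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if len(sizes) != block_count or len(starts) != block_count:
                raise ParseError(
                    f"{path}: line {lineno}: blockSizes/blockStarts "
                    f"inconsistent with blockCount"
                )
            exons_genomic = []
            for size, rel in zip(sizes, starts):
                s0 = chrom_start + rel  # 0-based half-open
                e0 = s0 + size
                if e0 > chrom_end or s0 < chrom_start:
                    raise ParseError(
                        f"{path}: line {lineno}: block outside gene span"
                    )
                exons_genomic.append((s0 + 1, e0))  # 1-based inclusive
            if strand == "+":
                tss, tts = chrom_start + 1, chrom_end
                exons = exons_genomic
            elif strand == "-":
                tss, tts = chrom_end, chrom_start + 1
                exons = exons_genomic[::-1]
            else:
                raise ParseError(f"{path}: line {lineno}: bad strand {strand!r}")
            utr5, utr3 = _utrs_from_thick(
                exons_genomic, thick_start, thick_end, strand
            )
            try:
                genes.append(
                    GeneModel(name, chrom, strand, tss, tts, exons, utr5, utr3)
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}: line {lineno}: {exc}") from exc
    return genes


def _utrs_from_thick(
    exons_genomic: Sequence[tuple[int, int]],
    thick_start: int,
    thick_end: int,
    strand: str,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Derive UTR intervals (1-based inclusive) from the BED thick (CDS)
    region: exonic sequence outside [thickStart, thickEnd)."""
    if thick_start >= thick_end:  # non-coding: no UTRs
        return [], []
    cds_lo, cds_hi = thick_start + 1, thick_end  # 1-based inclusive
    left: list[tuple[int, int]] = []
    right: list[tuple[int, int]] = []
    for s, e in exons_genomic:
        if s < cds_lo:
            left.append((s, min(e, cds_lo - 1)))
        if e > cds_hi:
            right.append((max(s, cds_hi + 1), e))
    if strand == "+":
        return left, right
    return right[::-1], left[::-1]


def _read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        exons_genomic = sorted(
            (f.start, f.end) for f in db.children(gene, featuretype="exon")
        )
        if not exons_genomic:
            exons_genomic = [(gene.start, gene.end)]
        utr5 = sorted(
            (f.start, f.end)
            for f in db.children(gene, featuretype="five_prime_UTR")
        )
        utr3 = sorted(
            (f.start, f.end)
            for f in db.children(gene, featuretype="three_prime_UTR")
        )
        if gene.strand == "+":
            tss, tts = gene.start, gene.end
            exons = exons_genomic
        elif gene.strand == "-":
            tss, tts = gene.end, gene.start
            exons = exons_genomic[::-1]
            utr5 = utr5[::-1]
            utr3 = utr3[::-1]
        else:
            raise ParseError(f"{path}: gene {gene.id}: bad strand")
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        genes.append(
            GeneModel(gene_id, gene.seqid, gene.strand, tss, tts, exons,
                      utr5, utr3)
        )
    return genes


def write_gene_models_bed12(
    genes: Sequence[GeneModel], path: str | os.PathLike
) -> None:
    """Write gene models as BED12 (0-based half-open at the boundary)."""
    with open(path, "w") as fh:
        for g in genes:
            genomic = sorted((min(a, b), max(a, b)) for a, b in g.exons)
            chrom_start = g.start - 1
            chrom_end = g.end
            sizes = ",".join(str(e - s + 1) for s, e in genomic)
            starts = ",".join(str(s - 1 - chrom_start) for s, _ in genomic)
            # thick region: CDS = exonic minus UTRs; if no UTRs, whole span
            utr = sorted((min(a, b), max(a, b)) for a, b in g.utr5 + g.utr3)
            if utr:
                utr_pos = set()
                for s, e in utr:
                    utr_pos.update((s, e))
                cds_lo = g.start
                cds_hi = g.end
                for s, e in utr:
                    if s == cds_lo:
                        cds_lo = e + 1
                for s, e in reversed(utr):
                    if e == cds_hi:
                        cds_hi = s - 1
                thick_start, thick_end = cds_lo - 1, cds_hi
            else:
                thick_start, thick_end = chrom_start, chrom_end
            fh.write(
                "\t".join(
                    [
                        g.chrom,
                        str(chrom_start),
                        str(chrom_end),
                        g.gene_id,
                        "0",
                        g.strand,
                        str(thick_start),
                        str(thick_end),
                        "0,0,0",
                        str(len(genomic)),
                        sizes + ",",
                        starts + ",",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# DMR tables
# ---------------------------------------------------------------------------

def write_dmr_table(dmrs, path: str | os.PathLike) -> None:
    """Write called DMRs as a TSV (1-based inclusive) plus a BED6 companion.

    *dmrs* is a sequence of objects with the Dmr attributes (see
    :mod:`wgbskit.dmr_detection`), sorted by (chrom, start); the BED6 file
    is written next to *path* with a ``.bed`` extension.
    """
    dmrs = list(dmrs)
    keys = [(d.chrom, d.start) for d in dmrs]
    if keys != sorted(keys):
        raise ValidationError("DMRs must be sorted by (chrom, start)")
    rows = []
    for d in dmrs:
        rows.append(
            {
                "methChr": d.chrom,
                "start": d.start,
                "end": d.end,
                "width": d.end - d.start + 1,
                "methDiff": d.meth_diff,
                "pvalue": d.p_value,
                "methType": d.context,
                "Annotation": d.annotation if d.annotation is not None else ".",
                "geneStrand": d.gene_strand if d.gene_strand is not None else ".",
                "geneId": d.gene_id if d.gene_id is not None else ".",
            }
        )
    table = pd.DataFrame(rows, columns=list(DMR_TABLE_COLUMNS))
    table.to_csv(path, sep="\t", index=False)

    bed_path = os.path.splitext(str(path))[0] + ".bed"
    with open(bed_path, "w") as fh:
        for d in dmrs:
            name = f"{d.context}|{d.gene_id or '.'}"
            strand = d.gene_strand or "."
            fh.write(
                f"{d.chrom}\t{d.start - 1}\t{d.end}\t{name}\t0\t{strand}\n"
            )
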