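"""Domain types and strand-aware interval algebra.

All coordinates are 0-based, half-open, on the forward strand. GTF/GFF
(1-based, inclusive) coordinates are converted at the I/O boundary only.
Adjacent half-open intervals overlap by 0 bases and have gap distance 0;
"within X nt" tests elsewhere in the package use ``gap_distance < X`` with
overlapping features counted as distance 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

STRANDS = ("+", "-", ".")
BIOTYPES = ("protein_coding", "housekeeping_rna", "mirna_precursor", "unknown")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC codes pass through)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A located, stranded span: ``[start, end)`` on ``chrom``.

    ``strand`` is ``'+'``, ``'-'`` or ``'.'`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by ``a`` and ``b`` (0 if on different chromosomes).

    Strand is ignored at this level; callers impose strand requirements.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Bases strictly between two spans on one chromosome; 0 when they touch.

    Overlapping *and* immediately adjacent half-open intervals both return 0.
    Raises ``ValueError`` for intervals on different chromosomes (the distance
    is undefined, never 0).
    """
    if a.chrom != b.chrom:
        raise ValueError(
            f"gap_distance undefined across chromosomes ({a.chrom} vs {b.chrom})"
        )
    return max(0, max(a.start, b.start) - min(a.end, b.end))


@dataclass(frozen=True)
class TranscriptModel:
    """A multi-exon, stranded transcript with an optional CDS/UTR partition.

    Exons must be sorted, non-overlapping, and share one chromosome and
    strand. ``cds``/``utr5``/``utr3`` are optional sub-feature interval lists
    (used for the AU-content partition of coding transcripts).
    """

    transcript_id: str
    gene_id: str
    exons: tuple[GenomicInterval, ...]
    biotype: str = "unknown"
    cds: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValueError("transcript_id must be non-empty")
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript needs >= 1 exon")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.transcript_id}: unknown biotype {self.biotype!r}")
        chrom = self.exons[0].chrom
        strand = self.exons[0].strand
        prev_end = -1
        for ex in self.exons:
            if ex.chrom != chrom or ex.strand != strand:
                raise ValueError(
                    f"{self.transcript_id}: exons span multiple chrom/strand"
                )
            if ex.start < prev_end:
                raise ValueError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = ex.end
        span = self.span
        for part in (self.cds, self.utr5, self.utr3):
            for iv in part:
                if iv.chrom != chrom or not (
                    span.start <= iv.start and iv.end <= span.end
                ):
                    raise ValueError(
                        f"{self.transcript_id}: sub-feature outside transcript span"
                    )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def spliced_length(self) -> int:
        return sum(len(ex) for ex in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class Gene:
    """An annotated gene locus (span-level) used for overlap/adjacency tests."""

    gene_id: str
    span: GenomicInterval
    biotype: str = "protein_coding"


@dataclass(frozen=True)
class TranscriptAttributes:
    """Per-transcript decision inputs for the filtration cascade.

    ``cpc_score`` is the coding-potential score; ``fpkm_wt``/``fpkm_sa`` are
    normalized expression under control and salt conditions.
    """

    cpc_score: float
    has_swissprot_hit: bool
    fpkm_wt: float
    fpkm_sa: float

    def __post_init__(self) -> None:
        for name in ("fpkm_wt", "fpkm_sa"):
            v = getattr(self, name)
            if not (v >= 0.0 and v == v and v != float("inf")):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


CONTEXTS = ("CpG", "CHG", "CHH")


@dataclass(frozen=True)
class CytosineSite:
    """One strand-specific cytosine with context and read counts.

    ``pos`` is the 0-based offset of the cytosine itself (the G on the
    forward strand for a minus-strand site). Context is read on the strand
    carrying the cytosine: CpG, CHG or CHH with H in {A, T, C}.
    """

    chrom: str
    pos: int
    strand: str
    context: str
    meth_reads: int = 0
    unmeth_reads: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"cytosine strand must be +/-, got {self.strand!r}")
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.meth_reads < 0 or self.unmeth_reads < 0:
            raise ValueError("read counts must be nonnegative")

    @property
    def coverage(self) -> int:
        return self.meth_reads + self.unmeth_reads


def spliced_sequence(t: TranscriptModel, genome: Mapping[str, str]) -> str:
    """Concatenated exonic sequence of ``t``, 5'->3' (revcomp on minus strand).

    Returned uppercase; ambiguity codes pass through unchanged.
    Raises ``KeyError``/``ValueError`` naming the transcript when the
    chromosome is missing or an exon is out of bounds.
    """
    if t.chrom not in genome:
        raise KeyError(f"{t.transcript_id}: chromosome {t.chrom!r} not in genome")
    seq = genome[t.chrom]
    n = len(seq)
    parts = []
    for ex in t.exons:
        if ex.end > n:
            raise ValueError(
                f"{t.transcript_id}: exon [{ex.start},{ex.end}) beyond end of "
                f"{t.chrom} (length {n})"
            )
        parts.append(seq[ex.start:ex.end])
    out = "".join(parts).upper()
    if t.strand == "-":
        out = reverse_complement(out)
    return out


def au_fraction(seq: str) -> float:
    """(A+T)/(A+C+G+T) of a sequence; NaN when no unambiguous base present.

    Ambiguity codes (N etc.) are excluded from both numerator and denominator.
    """
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (s.count("A") + s.count("T")) / acgt
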