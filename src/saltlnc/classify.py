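"""The lncRNA filtration cascade.

Assembled transcripts are passed through an ordered series of removal
stages — sense overlap with annotated genes, housekeeping-RNA and miRNA
precursor blacklists, coding potential, protein-database homology, minimum
length, minimum expression, and same-strand adjacency — and the survivors
are classified as lincRNAs (intergenic) or lncNATs (antisense overlap with
an annotated gene). Each transcript is removed at the first stage it fails,
and the audit object records one disposition per transcript, so the
accounting identity

    input = sum(per-stage removals) + lincRNAs + lncNATs

holds for every input.

Boundary conventions: coding-potential score strictly > 0.5 removed; spliced
length < 200 nt removed (200 kept); FPKM < 2 under both conditions removed
(2.0 in either kept); same-strand gap < 200 nt removed (exactly 200 kept).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core import (
    Gene,
    GenomicInterval,
    TranscriptAttributes,
    TranscriptModel,
    gap_distance,
    overlap_length,
)

STAGE_ORDER = (
    "sense_overlap",
    "housekeeping",
    "mirna",
    "coding_potential",
    "homology",
    "length",
    "expression",
    "adjacency",
)


@dataclass
class CascadeParams:
    """Thresholds of the cascade; defaults are the study's values."""

    cpc_max: float = 0.5
    min_len: int = 200
    min_fpkm: float = 2.0
    adjacency_nt: int = 200
    evalue_max: float = 1e-5
    exon_level: bool = False  # span-level overlap by default


@dataclass
class CascadeAudit:
    """Ordered per-stage removal counts plus final class labels.

    ``disposition`` maps every input transcript_id to either the stage that
    removed it or its final class (``lincRNA``/``lncNAT``).
    """

    input_count: int
    removals: list[tuple[str, int]]
    final_lincRNA: int
    final_lncNAT: int
    disposition: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        removed = sum(n for _, n in self.removals)
        retained = self.final_lincRNA + self.final_lncNAT
        if self.input_count != removed + retained:
            raise ValueError(
                f"cascade accounting violated: {self.input_count} != "
                f"{removed} removed + {retained} retained"
            )

    @property
    def final_retained(self) -> int:
        return self.final_lincRNA + self.final_lncNAT

    def to_dict(self) -> dict:
        return {
            "input_count": self.input_count,
            "removals": {stage: n for stage, n in self.removals},
            "final_lincRNA": self.final_lincRNA,
            "final_lncNAT": self.final_lncNAT,
            "disposition": dict(sorted(self.disposition.items())),
        }


def audit_from_counts(
    input_count: int, removal_counts: Sequence[int], final_lncnat: int = 0
) -> CascadeAudit:
    """Build an audit from printed per-stage removal counts alone.

    The retained total is implied by the conservation identity; useful for
    checking published flowchart accounting without transcript-level data.
    """
    if len(removal_counts) != len(STAGE_ORDER):
        raise ValueError(
            f"expected {len(STAGE_ORDER)} stage counts, got {len(removal_counts)}"
        )
    retained = input_count - sum(removal_counts)
    if retained < 0:
        raise ValueError("removal counts exceed input count")
    return CascadeAudit(
        input_count=input_count,
        removals=list(zip(STAGE_ORDER, removal_counts)),
        final_lincRNA=retained - final_lncnat,
        final_lncNAT=final_lncnat,
    )


# ---------------------------------------------------------------------------
# interval index helpers

class _GeneIndex:
    """Per-chromosome lists of gene spans for overlap and gap queries."""

    def __init__(self, genes: Iterable[Gene]):
        self.by_chrom: dict[str, list[Gene]] = defaultdict(list)
        for g in genes:
            self.by_chrom[g.span.chrom].append(g)

    def overlapping(
        self, iv: GenomicInterval, strand: Optional[str] = None
    ) -> list[Gene]:
        """Genes with >= 1 bp span overlap; ``strand`` '+'/'-' restricts to
        that strand, ``'opposite'``/``'same'`` are relative to ``iv``."""
        out = []
        for g in self.by_chrom.get(iv.chrom, ()):
            if overlap_length(iv, g.span) == 0:
                continue
            if strand == "same" and g.span.strand != iv.strand:
                continue
            if strand == "opposite" and (
                g.span.strand == iv.strand or g.span.strand == "."
            ):
                continue
            out.append(g)
        return out

    def min_gap(
        self,
        iv: GenomicInterval,
        strand: Optional[str] = None,
        biotype: Optional[str] = None,
    ) -> Optional[tuple[Gene, int]]:
        """Nearest gene by gap distance (overlap counts as 0); None if no
        candidate gene shares the chromosome."""
        best: Optional[tuple[Gene, int]] = None
        for g in self.by_chrom.get(iv.chrom, ()):
            if strand == "same" and g.span.strand != iv.strand:
                continue
            if strand == "opposite" and g.span.strand == iv.strand:
                continue
            if biotype is not None and g.biotype != biotype:
                continue
            d = gap_distance(iv, g.span)
            if best is None or d < best[1] or (
                d == best[1] and g.gene_id < best[0].gene_id
            ):
                best = (g, d)
        return best


def _query_span(t: TranscriptModel, exon_level: bool) -> list[GenomicInterval]:
    return list(t.exons) if exon_level else [t.span]


def _overlaps_any(
    t: TranscriptModel, index: _GeneIndex, strand: str, exon_level: bool
) -> bool:
    return any(
        index.overlapping(iv, strand=strand) for iv in _query_span(t, exon_level)
    )


# ---------------------------------------------------------------------------
# stages

def stage_sense_overlap(
    transcripts: Sequence[TranscriptModel],
    annotation: Sequence[Gene],
    exon_level: bool = False,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Remove transcripts overlapping an annotated gene on the same strand.

    The removed set are the study's mRNAs; they are returned first and kept
    for the characterization stage. Unstranded transcripts are an error —
    the cascade is strand-specific throughout.
    """
    removed, kept = [], []
    index = _GeneIndex(annotation)
    for t in transcripts:
        if t.strand == ".":
            raise ValueError(
                f"{t.transcript_id}: unstranded transcript; cascade requires strand"
            )
        if _overlaps_any(t, index, "same", exon_level):
            removed.append(t)
        else:
            kept.append(t)
    return removed, kept


def stage_blacklist(
    transcripts: Sequence[TranscriptModel],
    housekeeping_loci: Sequence[tuple[GenomicInterval, str]] = (),
    mirna_loci: Sequence[tuple[GenomicInterval, str]] = (),
    housekeeping_ids: Iterable[str] = (),
    mirna_ids: Iterable[str] = (),
) -> tuple[list[TranscriptModel], list[TranscriptModel], list[TranscriptModel]]:
    """Remove housekeeping-RNA and miRNA-precursor matches, in that order.

    A transcript overlapping a blacklist locus on either strand, or whose id
    is listed, is removed; a transcript matching both lists counts as a
    housekeeping removal (first stage wins).
    """
    hk_ids = set(housekeeping_ids)
    mi_ids = set(mirna_ids)

    def hits(t: TranscriptModel, loci) -> bool:
        return any(overlap_length(t.span, iv) > 0 for iv, _ in loci)

    removed_hk, removed_mi, kept = [], [], []
    for t in transcripts:
        if t.transcript_id in hk_ids or hits(t, housekeeping_loci):
            removed_hk.append(t)
        elif t.transcript_id in mi_ids or hits(t, mirna_loci):
            removed_mi.append(t)
        else:
            kept.append(t)
    return removed_hk, removed_mi, kept


def _require_attrs(
    t: TranscriptModel, attrs: Mapping[str, TranscriptAttributes]
) -> TranscriptAttributes:
    a = attrs.get(t.transcript_id)
    if a is None:
        raise KeyError(f"{t.transcript_id}: no attribute row for transcript")
    return a


def stage_coding_potential(
    transcripts: Sequence[TranscriptModel],
    attrs: Mapping[str, TranscriptAttributes],
    cpc_max: float = 0.5,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Remove transcripts with coding-potential score strictly above the cut."""
    removed, kept = [], []
    for t in transcripts:
        if _require_attrs(t, attrs).cpc_score > cpc_max:
            removed.append(t)
        else:
            kept.append(t)
    return removed, kept


def stage_homology(
    transcripts: Sequence[TranscriptModel],
    hits: Sequence[tuple[str, str, float]],
    evalue_max: float = 1e-5,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Remove transcripts with >= 1 protein-database hit at e-value <= cutoff."""
    hit_ids = {q for q, _s, e in hits if e <= evalue_max}
    removed = [t for t in transcripts if t.transcript_id in hit_ids]
    kept = [t for t in transcripts if t.transcript_id not in hit_ids]
    return removed, kept


def stage_length(
    transcripts: Sequence[TranscriptModel], min_len: int = 200
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Remove transcripts with spliced length below the minimum (200 kept)."""
    removed = [t for t in transcripts if t.spliced_length < min_len]
    kept = [t for t in transcripts if t.spliced_length >= min_len]
    return removed, kept


def stage_expression(
    transcripts: Sequence[TranscriptModel],
    attrs: Mapping[str, TranscriptAttributes],
    min_fpkm: float = 2.0,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Remove transcripts below the FPKM floor under *both* conditions."""
    removed, kept = [], []
    for t in transcripts:
        a = _require_attrs(t, attrs)
        if a.fpkm_wt < min_fpkm and a.fpkm_sa < min_fpkm:
            removed.append(t)
        else:
            kept.append(t)
    return removed, kept


def stage_adjacency(
    transcripts: Sequence[TranscriptModel],
    coding_genes: Sequence[Gene],
    max_gap: int = 200,
    exon_level: bool = False,
    both_strands: bool = False,
    all_genes: Optional[Sequence[Gene]] = None,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Remove intergenic transcripts within ``max_gap`` nt of a same-strand
    protein-coding gene (gap of exactly ``max_gap`` kept).

    Transcripts with an antisense gene overlap (against ``all_genes`` when
    given, else ``coding_genes``) bypass this stage — they are on the lncNAT
    path and adjacency does not apply. With ``both_strands`` the proximity
    test also counts opposite-strand neighbours.
    """
    index = _GeneIndex([g for g in coding_genes if g.biotype == "protein_coding"])
    nat_index = index if all_genes is None else _GeneIndex(all_genes)
    removed, kept = [], []
    for t in transcripts:
        if _overlaps_any(t, nat_index, "opposite", exon_level):
            kept.append(t)
            continue
        nearest = index.min_gap(t.span, strand=None if both_strands else "same")
        if nearest is not None and nearest[1] < max_gap:
            removed.append(t)
        else:
            kept.append(t)
    return removed, kept


def classify_final(
    kept: Sequence[TranscriptModel],
    annotation: Sequence[Gene],
    exon_level: bool = False,
) -> tuple[list[TranscriptModel], list[TranscriptModel]]:
    """Split cascade survivors into lincRNAs and lncNATs.

    A transcript with >= 1 bp span overlap with any annotated gene on the
    opposite strand is a lncNAT; everything else is a lincRNA.
    """
    index = _GeneIndex(annotation)
    lincs, nats = [], []
    for t in kept:
        if _overlaps_any(t, index, "opposite", exon_level):
            nats.append(t)
        else:
            lincs.append(t)
    return lincs, nats


@dataclass
class CascadeResult:
    """Audit plus the transcript sets the downstream modules consume."""

    audit: CascadeAudit
    mRNAs: list[TranscriptModel]
    lincRNAs: list[TranscriptModel]
    lncNATs: list[TranscriptModel]
    removed: dict[str, list[TranscriptModel]]

    @property
    def class_labels(self) -> dict[str, str]:
        labels = {t.transcript_id: "lincRNA" for t in self.lincRNAs}
        labels.update({t.transcript_id: "lncNAT" for t in self.lncNATs})
        return labels

    def gene_counts(self) -> dict[str, int]:
        """Distinct gene_ids behind the final transcript classes."""
        return {
            "lincRNA_genes": len({t.gene_id for t in self.lincRNAs}),
            "lncNAT_genes": len({t.gene_id for t in self.lncNATs}),
        }


def run_cascade(
    transcripts: Sequence[TranscriptModel],
    annotation: Sequence[Gene],
    attrs: Mapping[str, TranscriptAttributes],
    housekeeping_loci: Sequence[tuple[GenomicInterval, str]] = (),
    mirna_loci: Sequence[tuple[GenomicInterval, str]] = (),
    hits: Sequence[tuple[str, str, float]] = (),
    params: Optional[CascadeParams] = None,
) -> CascadeResult:
    """Apply all stages in fixed order and return audit + classified sets."""
    p = params or CascadeParams()
    disposition: dict[str, str] = {}
    removed: dict[str, list[TranscriptModel]] = {}

    def note(stage: str, batch: Sequence[TranscriptModel]) -> None:
        removed[stage] = list(batch)
        for t in batch:
            disposition[t.transcript_id] = stage

    mrnas, pool = stage_sense_overlap(transcripts, annotation, p.exon_level)
    note("sense_overlap", mrnas)
    hk, mi, pool = stage_blacklist(pool, housekeeping_loci, mirna_loci)
    note("housekeeping", hk)
    note("mirna", mi)
    cp, pool = stage_coding_potential(pool, attrs, p.cpc_max)
    note("coding_potential", cp)
    hom, pool = stage_homology(pool, hits, p.evalue_max)
    note("homology", hom)
    short, pool = stage_length(pool, p.min_len)
    note("length", short)
    low, pool = stage_expression(pool, attrs, p.min_fpkm)
    note("expression", low)
    coding = [g for g in annotation if g.biotype == "protein_coding"]
    adj, pool = stage_adjacency(
        pool, coding, p.adjacency_nt, p.exon_level, all_genes=annotation
    )
    note("adjacency", adj)
    lincs, nats = classify_final(pool, annotation, p.exon_level)
    for t in lincs:
        disposition[t.transcript_id] = "lincRNA"
    for t in nats:
        disposition[t.transcript_id] = "lncNAT"

    audit = CascadeAudit(
        input_count=len(transcripts),
        removals=[(stage, len(removed[stage])) for stage in STAGE_ORDER],
        final_lincRNA=len(lincs),
        final_lncNAT=len(nats),
        disposition=disposition,
    )
    return CascadeResult(
        audit=audit, mRNAs=mrnas, lincRNAs=lincs, lncNATs=nats, removed=removed
    )
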