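"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions: GTF/GFF3 files are 1-based inclusive and are
converted to the internal 0-based half-open convention here and only here.
BED is already 0-based half-open. Bismark CX reports give the 1-based
position of each cytosine. Plain-gzip inputs (``.gz``) are transparent.
"""

from __future__ import annotations

import gzip
import json
import re
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    CytosineSite,
    Gene,
    GenomicInterval,
    TranscriptAttributes,
    TranscriptModel,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gtf",
    "write_gtf",
    "read_annotation_genes",
    "read_cx_report",
    "write_cx_report",
    "read_bed_track",
    "write_bed_track",
    "read_blast_tab",
    "read_attribute_table",
    "write_attribute_table",
    "write_results",
]


def _open(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict[str, str]:
    """Genome as an ordered ``{chrom: uppercase sequence}`` map."""
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: Mapping[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    with _open(path, "wt") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# GTF / GFF3

_ATTR_GTF = re.compile(r'(\w+)\s+"([^"]*)"')
_ATTR_GFF = re.compile(r"(\w+)=([^;]*)")

_FEATURE_KEYS = {
    "exon": "exons",
    "cds": "cds",
    "five_prime_utr": "utr5",
    "5utr": "utr5",
    "three_prime_utr": "utr3",
    "3utr": "utr3",
}


def _parse_attributes(text: str) -> dict[str, str]:
    """Parse both ``key "value";`` (GTF) and ``key=value`` (GFF3) dialects."""
    attrs = dict(_ATTR_GTF.findall(text))
    if not attrs:
        attrs = {k: v.strip() for k, v in _ATTR_GFF.findall(text)}
    return attrs


def read_gtf(path) -> list[TranscriptModel]:
    """Read transcript models from a GTF/GFF file.

    Exon features are grouped by ``transcript_id`` (GFF3 ``Parent``/``ID``
    accepted); CDS and UTR features are attached when present; all other
    feature types are ignored. Raises ``ValueError`` with the line number on
    a missing transcript_id or an ``end < start`` coordinate.
    """
    per_tx: dict[str, dict] = {}
    order: list[str] = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 8 tab-separated fields"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame = (
                fields[:8]
            )
            key = _FEATURE_KEYS.get(feature.lower())
            if key is None:
                continue
            start, end = int(start_s), int(end_s)
            if end < start:
                raise ValueError(f"{path}:{lineno}: end {end} < start {start}")
            attrs = _parse_attributes(fields[8] if len(fields) > 8 else "")
            tid = attrs.get("transcript_id") or attrs.get("Parent")
            if not tid:
                raise ValueError(f"{path}:{lineno}: missing transcript_id attribute")
            entry = per_tx.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", tid),
                    "biotype": attrs.get(
                        "biotype", attrs.get("gene_biotype", "unknown")
                    ),
                    "exons": [],
                    "cds": [],
                    "utr5": [],
                    "utr3": [],
                },
            )
            if tid not in order:
                order.append(tid)
            # GTF 1-based inclusive -> internal 0-based half-open
            entry[key].append(GenomicInterval(chrom, start - 1, end, strand))
    models = []
    for tid in order:
        e = per_tx[tid]
        biotype = e["biotype"] if e["biotype"] in (
            "protein_coding",
            "housekeeping_rna",
            "mirna_precursor",
        ) else "unknown"
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=e["gene_id"],
                exons=tuple(sorted(e["exons"], key=lambda iv: iv.start)),
                biotype=biotype,
                cds=tuple(sorted(e["cds"], key=lambda iv: iv.start)),
                utr5=tuple(sorted(e["utr5"], key=lambda iv: iv.start)),
                utr3=tuple(sorted(e["utr3"], key=lambda iv: iv.start)),
            )
        )
    return models


_GTF_FEATURES = (("exons", "exon"), ("utr5", "5UTR"), ("cds", "CDS"), ("utr3", "3UTR"))


def write_gtf(
    transcripts: Sequence[TranscriptModel],
    path,
    class_labels: Optional[Mapping[str, str]] = None,
    source: str = "saltlnc",
) -> None:
    """Write transcript models as GTF (1-based inclusive, Cufflinks dialect).

    Rows are ordered deterministically by (chrom, start, transcript_id).
    ``class_labels`` adds a ``transcript_class`` attribute per transcript.
    """
    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with _open(path, "wt") as fh:
        for t in ordered:
            for attr_name, feature in _GTF_FEATURES:
                for iv in getattr(t, attr_name):
                    attrs = (
                        f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                    )
                    if t.biotype != "unknown":
                        attrs += f' biotype "{t.biotype}";'
                    if class_labels and t.transcript_id in class_labels:
                        attrs += (
                            f' transcript_class "{class_labels[t.transcript_id]}";'
                        )
                    fh.write(
                        "\t".join(
                            (
                                iv.chrom,
                                source,
                                feature,
                                str(iv.start + 1),
                                str(iv.end),
                                ".",
                                iv.strand,
                                ".",
                                attrs,
                            )
                        )
                        + "\n"
                    )


def read_annotation_genes(path) -> list[Gene]:
    """Read gene loci (span-level) from a GFF3/GTF annotation.

    ``gene`` features are used directly when present; otherwise gene spans
    are the union span of each gene's transcript features.
    """
    genes: dict[str, Gene] = {}
    found_gene_feature = False
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 8 tab-separated fields"
                )
            if fields[2].lower() != "gene":
                continue
            found_gene_feature = True
            attrs = _parse_attributes(fields[8] if len(fields) > 8 else "")
            gid = attrs.get("gene_id") or attrs.get("ID")
            if not gid:
                raise ValueError(f"{path}:{lineno}: gene feature without gene_id/ID")
            span = GenomicInterval(
                fields[0], int(fields[3]) - 1, int(fields[4]), fields[6]
            )
            biotype = attrs.get("biotype", attrs.get("gene_biotype", "protein_coding"))
            genes[gid] = Gene(gid, span, biotype)
    if found_gene_feature:
        return list(genes.values())
    # fall back to transcript-level grouping
    out: dict[str, Gene] = {}
    for t in read_gtf(path):
        g = out.get(t.gene_id)
        if g is None:
            out[t.gene_id] = Gene(t.gene_id, t.span, "protein_coding")
        else:
            span = GenomicInterval(
                g.span.chrom,
                min(g.span.start, t.start),
                max(g.span.end, t.end),
                g.span.strand,
            )
            out[t.gene_id] = Gene(t.gene_id, span, g.biotype)
    return list(out.values())


# ---------------------------------------------------------------------------
# Bismark CX report

_CONTEXT_ALIASES = {"CG": "CpG", "CPG": "CpG", "CHG": "CHG", "CHH": "CHH"}


def read_cx_report(path) -> list[CytosineSite]:
    """Read a Bismark cytosine (CX) report into CytosineSite records.

    Expected columns: chrom, 1-based position, strand, count methylated,
    count unmethylated, context, trinucleotide. Positions become 0-based;
    the context token is normalized (``CG`` -> ``CpG``). Zero-coverage rows
    are retained.
    """
    sites = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 6 columns in CX report"
                )
            chrom, pos_s, strand, meth_s, unmeth_s, context_raw = fields[:6]
            context = _CONTEXT_ALIASES.get(context_raw.upper())
            if context is None:
                raise ValueError(
                    f"{path}:{lineno}: unknown context token {context_raw!r}"
                )
            meth, unmeth = int(meth_s), int(unmeth_s)
            if meth < 0 or unmeth < 0:
                raise ValueError(f"{path}:{lineno}: negative read count")
            sites.append(
                CytosineSite(
                    chrom=chrom,
                    pos=int(pos_s) - 1,
                    strand=strand,
                    context=context,
                    meth_reads=meth,
                    unmeth_reads=unmeth,
                )
            )
    return sites


_CX_TOKEN = {"CpG": "CG", "CHG": "CHG", "CHH": "CHH"}


def write_cx_report(
    sites: Iterable[CytosineSite],
    path,
    genome: Optional[Mapping[str, str]] = None,
) -> None:
    """Write sites in Bismark CX-report layout (1-based positions).

    The trinucleotide column is filled from ``genome`` when given, else '.'.
    """
    with _open(path, "wt") as fh:
        for s in sites:
            if genome is not None:
                seq = genome[s.chrom]
                if s.strand == "+":
                    tri = seq[s.pos : s.pos + 3]
                else:
                    from .core import reverse_complement

                    tri = reverse_complement(seq[max(0, s.pos - 2) : s.pos + 1])
            else:
                tri = "."
            fh.write(
                "\t".join(
                    (
                        s.chrom,
                        str(s.pos + 1),
                        s.strand,
                        str(s.meth_reads),
                        str(s.unmeth_reads),
                        _CX_TOKEN[s.context],
                        tri,
                    )
                )
                + "\n"
            )


def cx_to_frame(sites: Sequence[CytosineSite]) -> pd.DataFrame:
    """Site list as a DataFrame (chrom, pos, strand, context, meth, unmeth)."""
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "strand": [s.strand for s in sites],
            "context": [s.context for s in sites],
            "meth": [s.meth_reads for s in sites],
            "unmeth": [s.unmeth_reads for s in sites],
        }
    )


# ---------------------------------------------------------------------------
# BED

def read_bed_track(path) -> list[tuple[GenomicInterval, str]]:
    """Read a BED3+/BED6 track as ``(interval, label)`` pairs.

    Column 4 is the label (empty when absent), column 6 the strand
    (unstranded when absent). ``track``/``browser``/comment lines skipped.
    """
    out = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if (
                not line
                or line.startswith("#")
                or line.startswith("track")
                or line.startswith("browser")
            ):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(f"{path}:{lineno}: start {start} >= end {end}")
            label = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            strand = (
                fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            )
            out.append((GenomicInterval(chrom, start, end, strand), label))
    return out


def write_bed_track(track: Iterable[tuple[GenomicInterval, str]], path) -> None:
    with _open(path, "wt") as fh:
        for iv, label in sorted(track, key=lambda x: (x[0].chrom, x[0].start)):
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label or '.'}\t.\t{iv.strand}\n"
            )


# ---------------------------------------------------------------------------
# BLAST tabular (outfmt 6)

def read_blast_tab(path) -> list[tuple[str, str, float]]:
    """Read BLAST outfmt-6 hits as ``(query_id, subject_id, evalue)`` triples.

    Only the three named fields are retained; the e-value threshold is
    applied downstream, never at parse time.
    """
    hits = []
    with _open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12-column BLAST tabular row"
                )
            try:
                evalue = float(fields[10])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric e-value {fields[10]!r}"
                ) from exc
            hits.append((fields[0], fields[1], evalue))
    return hits


# ---------------------------------------------------------------------------
# Attribute table (CPC / BLAST / Cufflinks summary per transcript)

_ATTR_COLUMNS = ["transcript_id", "cpc_score", "has_swissprot_hit", "fpkm_wt", "fpkm_sa"]


def read_attribute_table(path) -> dict[str, TranscriptAttributes]:
    """Read the per-transcript attribute TSV into an id -> attributes map."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_ATTR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["transcript_id"].duplicated().any():
        dup = df.loc[df["transcript_id"].duplicated(), "transcript_id"].iloc[0]
        raise ValueError(f"{path}: duplicate transcript_id {dup!r}")
    return {
        row.transcript_id: TranscriptAttributes(
            cpc_score=float(row.cpc_score),
            has_swissprot_hit=bool(row.has_swissprot_hit),
            fpkm_wt=float(row.fpkm_wt),
            fpkm_sa=float(row.fpkm_sa),
        )
        for row in df.itertuples()
    }


def write_attribute_table(attrs: Mapping[str, TranscriptAttributes], path) -> None:
    rows = [
        {
            "transcript_id": tid,
            "cpc_score": a.cpc_score,
            "has_swissprot_hit": int(a.has_swissprot_hit),
            "fpkm_wt": a.fpkm_wt,
            "fpkm_sa": a.fpkm_sa,
        }
        for tid, a in sorted(attrs.items())
    ]
    pd.DataFrame(rows, columns=_ATTR_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=lambda x: format(x, ".17g")
    )


# ---------------------------------------------------------------------------
# Result bundle

def write_results(
    out_dir,
    classified: Optional[Sequence[TranscriptModel]] = None,
    class_labels: Optional[Mapping[str, str]] = None,
    audit=None,
    tables: Optional[Mapping[str, pd.DataFrame]] = None,
) -> list[Path]:
    """Write the classification GTF, audit JSON and any result tables.

    Row order is deterministic: (chrom, start, id) for the GTF, stage order
    for the audit, input order for tables. Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    if classified is not None:
        p = out_dir / "classified.gtf"
        write_gtf(classified, p, class_labels=class_labels)
        written.append(p)
    if audit is not None:
        p = out_dir / "cascade_audit.json"
        with open(p, "w") as fh:
            json.dump(audit.to_dict(), fh, indent=2)
            fh.write("\n")
        written.append(p)
    for name, df in (tables or {}).items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written
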