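"""Descriptive statistics of the classified transcript sets.

Covers: per-class length and exon-number distributions, repeat/TE overlap
(by transcript number and by pooled exonic length), TE superfamily
composition, AU-content empirical distributions (with coding transcripts
split into 5'UTR/CDS/3'UTR partitions), antisense coverage of lncNATs,
chromosome-window counts, expression classes with a 2x2 chi-square of
induced fractions, nearest-gene targets of lincRNAs, and the presence/
absence conservation matrix from per-genome homology hit tables.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    Gene,
    GenomicInterval,
    TranscriptAttributes,
    TranscriptModel,
    au_fraction,
    gap_distance,
    overlap_length,
    spliced_sequence,
)

__all__ = [
    "length_exon_stats",
    "merge_intervals",
    "feature_overlap_stats",
    "te_composition",
    "au_content_ecdf",
    "ecdf",
    "nat_coverage",
    "window_distribution",
    "expression_classes",
    "induced_chi_square",
    "nearest_gene_targets",
    "conservation_matrix",
    "OverlapStats",
    "ExpressionClass",
]


# ---------------------------------------------------------------------------
# length / exon number

def length_exon_stats(
    classes: Mapping[str, Sequence[TranscriptModel]]
) -> pd.DataFrame:
    """Mean spliced length and exon-count histogram per transcript class.

    Columns: class, n, mean_length, exon histogram as ``exon_counts`` dict,
    single_exon_fraction. Empty classes get NaN means (flagged by n = 0).
    """
    rows = []
    for cls, txs in classes.items():
        lengths = [t.spliced_length for t in txs]
        exon_counts: dict[int, int] = defaultdict(int)
        for t in txs:
            exon_counts[t.n_exons] += 1
        n = len(txs)
        rows.append(
            {
                "class": cls,
                "n": n,
                "mean_length": float(np.mean(lengths)) if n else float("nan"),
                "exon_counts": dict(sorted(exon_counts.items())),
                "single_exon_fraction": (exon_counts.get(1, 0) / n)
                if n
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# feature (repeat / TE) overlap

def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[tuple[int, int]]]:
    """Strand-blind union of intervals per chromosome (sorted, disjoint)."""
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for iv in intervals:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    merged = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        out: list[tuple[int, int]] = []
        for s, e in ivs:
            if out and s <= out[-1][1]:
                out[-1] = (out[-1][0], max(out[-1][1], e))
            else:
                out.append((s, e))
        merged[chrom] = out
    return merged


def _covered_bases(
    exon: GenomicInterval, merged: Mapping[str, list[tuple[int, int]]]
) -> int:
    total = 0
    for s, e in merged.get(exon.chrom, ()):
        if s >= exon.end:
            break
        total += max(0, min(e, exon.end) - max(s, exon.start))
    return total


@dataclass(frozen=True)
class OverlapStats:
    """Repeat-overlap of a transcript class by number and by pooled length."""

    fraction_by_number: float
    fraction_by_length: float

    def __post_init__(self) -> None:
        for v in (self.fraction_by_number, self.fraction_by_length):
            if not (0.0 <= v <= 1.0 or v != v):
                raise ValueError("fractions must be in [0, 1]")


def feature_overlap_stats(
    transcripts: Sequence[TranscriptModel],
    features: Sequence[tuple[GenomicInterval, str]],
) -> OverlapStats:
    """Fraction of transcripts with >= 1 bp exonic feature overlap, and the
    pooled fraction of exonic bases covered by the merged feature set."""
    merged = merge_intervals(iv for iv, _ in features)
    n_overlapping = 0
    covered = 0
    exonic = 0
    for t in transcripts:
        t_cov = sum(_covered_bases(ex, merged) for ex in t.exons)
        covered += t_cov
        exonic += t.spliced_length
        if t_cov > 0:
            n_overlapping += 1
    n = len(transcripts)
    return OverlapStats(
        fraction_by_number=(n_overlapping / n) if n else float("nan"),
        fraction_by_length=(covered / exonic) if exonic else float("nan"),
    )


def te_composition(
    lincRNAs: Sequence[TranscriptModel],
    te_track: Sequence[tuple[GenomicInterval, str]],
    per_transcript_majority: bool = False,
) -> tuple[dict[str, float], float]:
    """TE superfamily shares within TE-overlapping lincRNAs, plus the mean
    per-transcript TE-covered fraction among them.

    Shares are computed over TE-overlapped exonic bases (label by label,
    each label's intervals merged separately); ``per_transcript_majority``
    instead assigns each overlapping transcript wholly to its majority
    label. Labels outside the canonical superfamily codes pass through.
    """
    by_label: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv, label in te_track:
        by_label[label or "unlabeled"].append(iv)
    merged_by_label = {lab: merge_intervals(ivs) for lab, ivs in by_label.items()}
    all_merged = merge_intervals(iv for iv, _ in te_track)

    label_bases: dict[str, float] = defaultdict(float)
    covered_fractions = []
    for t in lincRNAs:
        total_cov = sum(_covered_bases(ex, all_merged) for ex in t.exons)
        if total_cov == 0:
            continue
        covered_fractions.append(total_cov / t.spliced_length)
        per_label = {
            lab: sum(_covered_bases(ex, m) for ex in t.exons)
            for lab, m in merged_by_label.items()
        }
        if per_transcript_majority:
            top = max(sorted(per_label), key=lambda k: per_label[k])
            label_bases[top] += 1
        else:
            for lab, b in per_label.items():
                label_bases[lab] += b
    total = sum(label_bases.values())
    shares = (
        {lab: b / total for lab, b in sorted(label_bases.items()) if b > 0}
        if total
        else {}
    )
    mean_cov = float(np.mean(covered_fractions)) if covered_fractions else float("nan")
    return shares, mean_cov


# ---------------------------------------------------------------------------
# AU content

def ecdf(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Empirical CDF as (sorted values, cumulative fractions ending at 1)."""
    x = np.sort(np.asarray(values, dtype=float))
    y = np.arange(1, len(x) + 1) / len(x) if len(x) else np.empty(0)
    return x, y


def au_content_ecdf(
    classes: Mapping[str, Sequence[TranscriptModel]],
    genome: Mapping[str, str],
) -> dict[str, np.ndarray]:
    """Per-class AU fractions (one value per sequence), ECDF-ready.

    Non-coding classes contribute their spliced sequences; the ``mRNA``
    class is split into 5'UTR / CDS / 3'UTR partitions (transcripts with an
    annotated partition only; zero-length partitions are skipped).
    """
    out: dict[str, list[float]] = defaultdict(list)
    for cls, txs in classes.items():
        for t in txs:
            if cls == "mRNA":
                for part_name, part in (
                    ("5'UTR", t.utr5),
                    ("CDS", t.cds),
                    ("3'UTR", t.utr3),
                ):
                    if not part:
                        continue
                    sub = TranscriptModel(
                        transcript_id=f"{t.transcript_id}:{part_name}",
                        gene_id=t.gene_id,
                        exons=part,
                    )
                    au = au_fraction(spliced_sequence(sub, genome))
                    if au == au:
                        out[part_name].append(au)
            else:
                au = au_fraction(spliced_sequence(t, genome))
                if au == au:
                    out[cls].append(au)
    return {cls: np.asarray(v) for cls, v in out.items()}


# ---------------------------------------------------------------------------
# lncNAT antisense coverage

def nat_coverage(
    lncNATs: Sequence[TranscriptModel], annotation: Sequence[Gene]
) -> pd.DataFrame:
    """Per-NAT maximum single-gene antisense span coverage.

    Coverage of a NAT by a gene is overlap(NAT span, gene span) / NAT span
    length; the maximum over antisense-overlapping genes is reported, with
    ``fully_covered`` when it reaches 1. A lncNAT without any antisense
    gene contradicts its classification and raises ``ValueError``.
    """
    by_chrom: dict[str, list[Gene]] = defaultdict(list)
    for g in annotation:
        by_chrom[g.span.chrom].append(g)
    rows = []
    for t in lncNATs:
        span = t.span
        best_gene, best_cov = None, -1.0
        for g in by_chrom.get(span.chrom, ()):
            if g.span.strand in (t.strand, "."):
                continue
            ov = overlap_length(span, g.span)
            if ov == 0:
                continue
            cov = ov / len(span)
            if cov > best_cov:
                best_gene, best_cov = g, cov
        if best_gene is None:
            raise ValueError(
                f"{t.transcript_id}: lncNAT with no antisense gene overlap"
            )
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": best_gene.gene_id,
                "coverage": best_cov,
                "fully_covered": best_cov >= 1.0,
            }
        )
    return pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "coverage", "fully_covered"]
    )


# ---------------------------------------------------------------------------
# windowed genome distribution

def window_distribution(
    classes: Mapping[str, Sequence[TranscriptModel]],
    chrom_lengths: Mapping[str, int],
    window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Transcript counts per (chrom, window, class); assignment by span
    start; the last partial window is kept."""
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    counts: dict[tuple[str, int, str], int] = defaultdict(int)
    for cls, txs in classes.items():
        for t in txs:
            length = chrom_lengths.get(t.chrom)
            if length is None or t.start >= length:
                raise ValueError(
                    f"{t.transcript_id}: start {t.start} beyond {t.chrom} length"
                )
            counts[(t.chrom, t.start // window_bp, cls)] += 1
    rows = []
    for chrom, length in chrom_lengths.items():
        n_windows = max(1, -(-length // window_bp))
        for w in range(n_windows):
            for cls in classes:
                rows.append(
                    {
                        "chrom": chrom,
                        "window": w,
                        "start": w * window_bp,
                        "end": min((w + 1) * window_bp, length),
                        "class": cls,
                        "count": counts.get((chrom, w, cls), 0),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression classes

@dataclass(frozen=True)
class ExpressionClass:
    """Condition response of one transcript.

    ``activated``: zero in control, expressed under salt. ``silenced``: the
    reverse. Fold change is defined only when both FPKMs are positive.
    """

    transcript_id: str
    expr_class: str
    fold_change: float  # NaN when undefined


def classify_expression(
    attrs: TranscriptAttributes, fold_threshold: float = 2.0
) -> tuple[str, float]:
    wt, sa = attrs.fpkm_wt, attrs.fpkm_sa
    if wt == 0.0 and sa > 0.0:
        return "activated", float("nan")
    if sa == 0.0 and wt > 0.0:
        return "silenced", float("nan")
    if wt == 0.0 and sa == 0.0:
        return "unchanged", float("nan")
    fc = sa / wt
    if fc > fold_threshold:
        return "up_regulated", fc
    if 1.0 / fc > fold_threshold:
        return "down_regulated", fc
    return "unchanged", fc


def expression_classes(
    class_members: Mapping[str, Sequence[str]],
    attrs: Mapping[str, TranscriptAttributes],
    fold_threshold: float = 2.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Expression class per transcript plus per-class induced fractions.

    ``class_members`` maps transcript class (lincRNA/lncNAT/mRNA) to its
    transcript ids. Induced = activated or up-regulated more than
    ``fold_threshold``-fold. Returns (per-transcript table, fractions).
    """
    if fold_threshold <= 1.0:
        raise ValueError("fold_threshold must be > 1")
    rows = []
    induced: dict[str, float] = {}
    for cls, ids in class_members.items():
        n_induced = 0
        for tid in ids:
            a = attrs[tid]
            ec, fc = classify_expression(a, fold_threshold)
            rows.append(
                {
                    "transcript_id": tid,
                    "class": cls,
                    "expr_class": ec,
                    "fold_change": fc,
                    "fpkm_wt": a.fpkm_wt,
                    "fpkm_sa": a.fpkm_sa,
                }
            )
            if ec in ("activated", "up_regulated"):
                n_induced += 1
        induced[cls] = (n_induced / len(ids)) if ids else float("nan")
    return (
        pd.DataFrame(
            rows,
            columns=[
                "transcript_id",
                "class",
                "expr_class",
                "fold_change",
                "fpkm_wt",
                "fpkm_sa",
            ],
        ),
        induced,
    )


def induced_chi_square(
    table: Sequence[Sequence[int]], correction: bool = False
) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 induced/not-induced contingency table.

    No continuity correction by default (the study scale makes it
    negligible); returns (statistic, p-value).
    """
    stat, p, _dof, _exp = stats.chi2_contingency(
        np.asarray(table), correction=correction
    )
    return float(stat), float(p)


# ---------------------------------------------------------------------------
# nearest genes

def nearest_gene_targets(
    lincRNAs: Sequence[TranscriptModel],
    coding_genes: Sequence[Gene],
) -> pd.DataFrame:
    """Nearest protein-coding gene per lincRNA over both strands.

    Distance is the gap (overlap counts as 0). Ties break by orientation
    (sense first), then lexicographic gene_id. lincRNAs on chromosomes
    without genes are omitted.
    """
    by_chrom: dict[str, list[Gene]] = defaultdict(list)
    for g in coding_genes:
        if g.biotype == "protein_coding":
            by_chrom[g.span.chrom].append(g)
    rows = []
    for t in lincRNAs:
        span = t.span
        best: Optional[tuple[int, int, str, str]] = None  # (dist, anti, gid, orient)
        for g in by_chrom.get(span.chrom, ()):
            d = gap_distance(span, g.span)
            orient = "sense" if g.span.strand == t.strand else "antisense"
            key = (d, 0 if orient == "sense" else 1, g.gene_id)
            if best is None or key < (best[0], best[1], best[2]):
                best = (d, key[1], g.gene_id, orient)
        if best is None:
            continue
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "gene_id": best[2],
                "distance": best[0],
                "orientation": best[3],
            }
        )
    return pd.DataFrame(
        rows, columns=["transcript_id", "gene_id", "distance", "orientation"]
    )


# ---------------------------------------------------------------------------
# conservation screen

def conservation_matrix(
    lnc_ids: Mapping[str, Sequence[str]],
    hit_tables: Mapping[str, Sequence[tuple[str, str, float]]],
    evalue_max: float = 1e-5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Presence/absence of homologs per target genome.

    ``lnc_ids`` maps class -> transcript ids; ``hit_tables`` maps genome
    label -> hit triples. Presence means >= 1 hit at e-value <= cutoff.
    Returns (id x genome boolean matrix, per-genome retained fraction per
    class). Duplicate genome labels are rejected by dict construction
    upstream; an empty mapping yields empty frames.
    """
    genomes = list(hit_tables)
    if len(genomes) != len(set(genomes)):
        raise ValueError("duplicate genome labels")
    present_by_genome = {
        g: {q for q, _s, e in hits if e <= evalue_max}
        for g, hits in hit_tables.items()
    }
    all_ids = [tid for ids in lnc_ids.values() for tid in ids]
    matrix = pd.DataFrame(
        {
            g: [tid in present_by_genome[g] for tid in all_ids]
            for g in genomes
        },
        index=pd.Index(all_ids, name="transcript_id"),
    )
    rows = []
    for cls, ids in lnc_ids.items():
        for g in genomes:
            frac = (
                float(np.mean([tid in present_by_genome[g] for tid in ids]))
                if len(ids)
                else float("nan")
            )
            rows.append({"class": cls, "genome": g, "fraction_present": frac})
    return matrix, pd.DataFrame(rows, columns=["class", "genome", "fraction_present"])
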