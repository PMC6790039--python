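"""Cytosine context calling and RMC (ratio of methylated cytosines) analysis.

The RMC of a region and context is the number of methylated cytosine sites
divided by the number of called cytosine sites of that context inside the
region, both strands pooled. A site is *called* when its read coverage
reaches ``min_cov``; a called site is *methylated* when it has at least one
methylated read. Contexts are read on the strand carrying the cytosine:
CpG, CHG, CHH with H in {A, T, C}.

Aggregations provided: per arbitrary region, per gene and 1-kb promoter,
per fixed chromosome window, and as a strand-aware metagene profile
(upstream bins of fixed width plus a length-scaled gene body).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import CONTEXTS, CytosineSite, Gene, GenomicInterval

logger = logging.getLogger(__name__)

_H_PLUS = frozenset("ACT")  # H bases as read on the site's own strand
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# context calling

def _contexts_one_strand(seq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Positions and context codes of plus-strand cytosines in a byte array.

    Context codes: 0 CpG, 1 CHG, 2 CHH, -1 unresolvable (skip).
    """
    C, G = ord("C"), ord("G")
    n = len(seq)
    pos = np.flatnonzero(seq == C)
    if len(pos) == 0:
        return pos, np.empty(0, dtype=np.int8)
    pad = np.full(2, ord("N"), dtype=seq.dtype)
    ext = np.concatenate([seq, pad])
    nxt1, nxt2 = ext[pos + 1], ext[pos + 2]
    is_h1 = np.isin(nxt1, [ord(b) for b in "ACT"])
    is_h2 = np.isin(nxt2, [ord(b) for b in "ACT"])
    code = np.full(len(pos), -1, dtype=np.int8)
    code[nxt1 == G] = 0
    code[is_h1 & (nxt2 == G)] = 1
    code[is_h1 & is_h2] = 2
    # drop positions whose trinucleotide runs off the chromosome end
    code[(pos + 1 >= n) | ((nxt1 != G) & (pos + 2 >= n))] = -1
    return pos, code


def call_contexts(genome: Mapping[str, str]) -> list[CytosineSite]:
    """Enumerate every cytosine on both strands with its context, zero counts.

    A minus-strand site is a G on the forward strand read as C on the
    reverse complement. Cytosines whose strand-local trinucleotide is
    truncated by a chromosome end or contains an ambiguity code that leaves
    the context undetermined are skipped (logged at debug level).
    """
    sites: list[CytosineSite] = []
    names = list(CONTEXTS)
    for chrom, seq in genome.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        pos, code = _contexts_one_strand(arr)
        skipped = int((code == -1).sum())
        for p, c in zip(pos[code >= 0], code[code >= 0]):
            sites.append(CytosineSite(chrom, int(p), "+", names[c]))
        # minus strand: reverse-complement, call, map positions back
        rc = arr[::-1].copy()
        for a, b in ((ord("A"), ord("T")), (ord("C"), ord("G"))):
            ai, bi = rc == a, rc == b
            rc[ai], rc[bi] = b, a
        mpos, mcode = _contexts_one_strand(rc)
        skipped += int((mcode == -1).sum())
        n = len(arr)
        minus_sites = [
            CytosineSite(chrom, int(n - 1 - p), "-", names[c])
            for p, c in zip(mpos[mcode >= 0], mcode[mcode >= 0])
        ]
        minus_sites.reverse()  # ascending genomic position
        sites.extend(minus_sites)
        if skipped:
            logger.debug(
                "%s: %d cytosines with unresolvable context skipped", chrom, skipped
            )
    return sites


def call_site_state(site: CytosineSite, min_cov: int = 1) -> str:
    """'methylated', 'unmethylated' or 'no_call' (coverage below ``min_cov``).

    A called site is methylated when it has >= 1 methylated read.
    """
    if site.coverage < min_cov:
        return "no_call"
    return "methylated" if site.meth_reads >= 1 else "unmethylated"


# ---------------------------------------------------------------------------
# site frames

_FRAME_COLS = ["chrom", "pos", "strand", "context", "meth", "unmeth"]

SiteInput = Union[Sequence[CytosineSite], pd.DataFrame]


def as_site_frame(sites: SiteInput) -> pd.DataFrame:
    """Coerce a site list to the internal DataFrame layout (idempotent)."""
    if isinstance(sites, pd.DataFrame):
        return sites
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": np.asarray([s.pos for s in sites], dtype=np.int64),
            "strand": [s.strand for s in sites],
            "context": [s.context for s in sites],
            "meth": np.asarray([s.meth_reads for s in sites], dtype=np.int64),
            "unmeth": np.asarray([s.unmeth_reads for s in sites], dtype=np.int64),
        }
    )


def _called(frame: pd.DataFrame, min_cov: int) -> pd.DataFrame:
    df = frame[(frame["meth"] + frame["unmeth"]) >= min_cov].copy()
    df["methylated"] = df["meth"] >= 1
    return df


@dataclass(frozen=True)
class RegionMethylation:
    """RMC of one region and context; ``rmc`` is NaN when no site is called."""

    region_id: str
    context: str
    n_sites: int
    n_methylated: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_methylated <= self.n_sites):
            raise ValueError("need 0 <= n_methylated <= n_sites")

    @property
    def rmc(self) -> float:
        if self.n_sites == 0:
            return float("nan")
        return self.n_methylated / self.n_sites


def region_rmc(
    region: GenomicInterval,
    sites: SiteInput,
    context: str,
    min_cov: int = 1,
    region_id: str = "",
) -> RegionMethylation:
    """RMC over called sites of ``context`` inside ``[start, end)``, both
    strands pooled; no-call sites enter neither numerator nor denominator."""
    df = _called(as_site_frame(sites), min_cov)
    sel = df[
        (df["chrom"] == region.chrom)
        & (df["pos"] >= region.start)
        & (df["pos"] < region.end)
        & (df["context"] == context)
    ]
    return RegionMethylation(
        region_id=region_id or f"{region.chrom}:{region.start}-{region.end}",
        context=context,
        n_sites=len(sel),
        n_methylated=int(sel["methylated"].sum()),
    )


def promoter_interval(
    gene: Gene, promoter_bp: int = 1000, chrom_length: Optional[int] = None
) -> Optional[GenomicInterval]:
    """The fixed window immediately upstream of the strand-aware start,
    clipped at chromosome boundaries; None when fully clipped away."""
    span = gene.span
    if span.strand == "-":
        start, end = span.end, span.end + promoter_bp
        if chrom_length is not None:
            end = min(end, chrom_length)
    else:
        start, end = span.start - promoter_bp, span.start
        start = max(0, start)
    if start >= end:
        return None
    return GenomicInterval(span.chrom, start, end, span.strand)


def gene_promoter_rmc(
    genes: Sequence[Gene],
    sites: SiteInput,
    min_cov: int = 1,
    promoter_bp: int = 1000,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Per gene x {gene, promoter} x context RMC table.

    Columns: gene_id, region, context, n_sites, n_methylated, rmc. Six rows
    per gene (promoter rows absent only when the promoter is fully clipped).
    """
    df = _called(as_site_frame(sites), min_cov)
    rows = []
    grouped = {c: g for c, g in df.groupby("chrom")}
    for gene in genes:
        regions = [("gene", gene.span)]
        prom = promoter_interval(
            gene,
            promoter_bp,
            None if chrom_lengths is None else chrom_lengths.get(gene.span.chrom),
        )
        if prom is not None:
            regions.append(("promoter", prom))
        chrom_df = grouped.get(gene.span.chrom)
        for region_name, iv in regions:
            if chrom_df is None:
                sel = df.iloc[0:0]
            else:
                sel = chrom_df[
                    (chrom_df["pos"] >= iv.start) & (chrom_df["pos"] < iv.end)
                ]
            counts = sel.groupby("context")["methylated"].agg(["size", "sum"])
            for context in CONTEXTS:
                n = int(counts["size"].get(context, 0))
                m = int(counts["sum"].get(context, 0))
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "region": region_name,
                        "context": context,
                        "n_sites": n,
                        "n_methylated": m,
                        "rmc": (m / n) if n else float("nan"),
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "region", "context", "n_sites", "n_methylated", "rmc"]
    )


def never_methylated_fraction(
    gene_rmc: pd.DataFrame, class_map: Mapping[str, str]
) -> dict[str, float]:
    """Fraction of genes per class with zero methylated CpG+CHG calls over
    the gene region. Classes with no genes are omitted."""
    body = gene_rmc[
        (gene_rmc["region"] == "gene") & gene_rmc["context"].isin(["CpG", "CHG"])
    ]
    per_gene = body.groupby("gene_id")["n_methylated"].sum()
    out: dict[str, list] = {}
    counts: dict[str, list[int]] = {}
    for gene_id, n_meth in per_gene.items():
        cls = class_map.get(gene_id)
        if cls is None:
            continue
        total, never = counts.setdefault(cls, [0, 0])
        counts[cls][0] = total + 1
        counts[cls][1] = never + (1 if n_meth == 0 else 0)
    return {cls: never / total for cls, (total, never) in counts.items()}


def chrom_window_rmc(
    sites: SiteInput,
    chrom_lengths: Mapping[str, int],
    window_bp: int = 1_000_000,
    min_cov: int = 1,
) -> pd.DataFrame:
    """Pooled RMC per (chrom, window, context); empty windows have NaN RMC.

    Windows are half-open ``[k*window_bp, (k+1)*window_bp)``; the last
    partial window is kept.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    df = _called(as_site_frame(sites), min_cov)
    df = df.assign(window=df["pos"] // window_bp)
    agg = (
        df.groupby(["chrom", "window", "context"])["methylated"]
        .agg(n_sites="size", n_methylated="sum")
        .reset_index()
    )
    rows = []
    seen = {
        (r.chrom, r.window, r.context): (r.n_sites, r.n_methylated)
        for r in agg.itertuples()
    }
    for chrom, length in chrom_lengths.items():
        n_windows = max(1, -(-length // window_bp))
        for w in range(n_windows):
            for context in CONTEXTS:
                n, m = seen.get((chrom, w, context), (0, 0))
                rows.append(
                    {
                        "chrom": chrom,
                        "window": w,
                        "start": w * window_bp,
                        "end": min((w + 1) * window_bp, length),
                        "context": context,
                        "n_sites": int(n),
                        "n_methylated": int(m),
                        "rmc": (m / n) if n else float("nan"),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# metagene profile

def metagene_profile(
    genes: Sequence[Gene],
    sites: SiteInput,
    n_body_bins: int = 60,
    upstream_bp: int = 1000,
    n_up_bins: int = 20,
    min_cov: int = 1,
) -> pd.DataFrame:
    """Mean per-gene RMC along upstream + length-scaled gene-body bins.

    Bins run 5'->3': indices 0..n_up_bins-1 are fixed-width upstream bins
    (farthest upstream first), n_up_bins..n_up_bins+n_body_bins-1 the
    length-scaled body. Sites are points, so every gene — however short —
    contributes each called site to exactly one bin; the cross-gene mean in
    a bin is over genes with >= 1 called site there. Minus-strand genes have
    both upstream direction and body order reversed relative to genomic
    coordinates.

    Columns: bin, segment (upstream/body), context, n_genes, mean_rmc.
    """
    df = _called(as_site_frame(sites), min_cov)
    n_bins = n_up_bins + n_body_bins
    up_w = upstream_bp / n_up_bins if n_up_bins else 0.0
    # accumulate per (bin, context): sum of per-gene RMCs and gene count
    acc: dict[tuple[int, str], list[float]] = {}
    by_chrom = {c: g for c, g in df.groupby("chrom")}
    for gene in genes:
        span = gene.span
        chrom_df = by_chrom.get(span.chrom)
        if chrom_df is None:
            continue
        glen = len(span)
        if span.strand == "-":
            lo, hi = span.start, span.end + upstream_bp
        else:
            lo, hi = span.start - upstream_bp, span.end
        sel = chrom_df[(chrom_df["pos"] >= max(0, lo)) & (chrom_df["pos"] < hi)]
        if sel.empty:
            continue
        pos = sel["pos"].to_numpy()
        if span.strand == "-":
            # signed 5'->3' coordinate: negative upstream, [0, glen) in body
            rel = span.end - 1 - pos
        else:
            rel = pos - span.start
        in_body = rel >= 0
        bins = np.empty(len(rel), dtype=np.int64)
        body_rel = rel[in_body]
        bins[in_body] = n_up_bins + np.minimum(
            (body_rel * n_body_bins) // glen, n_body_bins - 1
        )
        if n_up_bins:
            up_rel = -rel[~in_body]  # 1..upstream_bp, 1 = closest to TSS
            b = n_up_bins - 1 - ((up_rel - 1) // up_w).astype(np.int64)
            bins[~in_body] = np.clip(b, 0, n_up_bins - 1)
        else:
            bins[~in_body] = -1
        meth = sel["methylated"].to_numpy()
        ctx = sel["context"].to_numpy()
        tmp = pd.DataFrame({"bin": bins, "context": ctx, "methylated": meth})
        tmp = tmp[tmp["bin"] >= 0]
        g = tmp.groupby(["bin", "context"])["methylated"].agg(["size", "sum"])
        for (b, context), row in g.iterrows():
            entry = acc.setdefault((int(b), context), [0.0, 0])
            entry[0] += row["sum"] / row["size"]
            entry[1] += 1
    rows = []
    for b in range(n_bins):
        segment = "upstream" if b < n_up_bins else "body"
        for context in CONTEXTS:
            total, n_genes = acc.get((b, context), (0.0, 0))
            rows.append(
                {
                    "bin": b,
                    "segment": segment,
                    "context": context,
                    "n_genes": n_genes,
                    "mean_rmc": (total / n_genes) if n_genes else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def condition_ratio(
    rmc_wt: pd.DataFrame, rmc_sa: pd.DataFrame
) -> pd.DataFrame:
    """Per gene/region/context pairing of condition RMCs with their ratio.

    Ratio is rmc_sa / rmc_wt, NaN (and flagged) when the control RMC is 0
    or either condition is undefined.
    """
    keys = ["gene_id", "region", "context"]
    merged = rmc_wt[keys + ["rmc"]].merge(
        rmc_sa[keys + ["rmc"]], on=keys, suffixes=("_wt", "_sa")
    )
    wt = merged["rmc_wt"].to_numpy(dtype=float)
    sa = merged["rmc_sa"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(wt > 0, sa / wt, np.nan)
    merged["ratio"] = ratio
    merged["flagged"] = ~np.isfinite(ratio)
    return merged


def h_base_composition(
    sites: SiteInput, genome: Mapping[str, str]
) -> pd.DataFrame:
    """Base frequencies at the H positions of CHG/CHH trinucleotides.

    For CHG the H is position 2 of the strand-local trinucleotide; for CHH
    positions 2 and 3 are pooled. Raises ``ValueError`` if a G appears at an
    H position (inconsistent context call).

    Columns: context, base, frequency.
    """
    df = as_site_frame(sites)
    counts = {("CHG", b): 0 for b in "ATC"}
    counts.update({("CHH", b): 0 for b in "ATC"})
    for chrom, sub in df[df["context"].isin(["CHG", "CHH"])].groupby("chrom"):
        seq = genome[chrom].upper()
        for pos, strand, context in zip(
            sub["pos"].to_numpy(), sub["strand"], sub["context"]
        ):
            if strand == "+":
                tri = seq[pos : pos + 3]
            else:
                raw = seq[max(0, pos - 2) : pos + 1][::-1]
                tri = "".join(_COMP.get(b, "N") for b in raw)
            h_positions = [1] if context == "CHG" else [1, 2]
            for i in h_positions:
                if i >= len(tri):
                    continue
                base = tri[i]
                if base == "G":
                    raise ValueError(
                        f"{chrom}:{pos}({strand}): G at H position of {context} site"
                    )
                if base in "ATC":
                    counts[(context, base)] += 1
    rows = []
    for context in ("CHG", "CHH"):
        total = sum(counts[(context, b)] for b in "ATC")
        for base in "ATC":
            rows.append(
                {
                    "context": context,
                    "base": base,
                    "frequency": (counts[(context, base)] / total)
                    if total
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def genome_wide_methylated_fraction(
    sites: SiteInput, min_cov: int = 1
) -> dict[str, float]:
    """Per-context fraction of called sites that are methylated."""
    df = _called(as_site_frame(sites), min_cov)
    out = {}
    for context, sub in df.groupby("context"):
        out[context] = float(sub["methylated"].mean())
    return out
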