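"""Synthetic study generator with planted ground truth.

Builds a complete toy study — multi-chromosome genome, protein-coding genes
with UTR/CDS structure, planted intergenic (lincRNA) and antisense (lncNAT)
non-coding transcripts, decoy transcripts engineered to fail exactly one
cascade stage each, repeat/TE tracks, blacklist loci, per-transcript
attribute tables, and per-cytosine methylation reports for two conditions.

Placement is sequential along each chromosome with inter-feature gaps of at
least twice the adjacency threshold, which guarantees every planted lincRNA
is >= 200 nt from all coding genes on either strand; lncNATs are planted
inside gene spans on the opposite strand; each decoy is constructed to pass
every cascade stage before its intended one and fail exactly there. All
outputs are a pure function of the configuration (seed included).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (
    CytosineSite,
    Gene,
    GenomicInterval,
    TranscriptAttributes,
    TranscriptModel,
)
from .methylome import call_contexts

TE_SUPERFAMILIES = ("RLG", "RLC", "DTM", "DTH", "DTC", "DHH")
# LTR Gypsy and Copia dominate; DNA transposons split the remainder
TE_WEIGHTS = (0.684, 0.212, 0.030, 0.028, 0.026, 0.020)

DECOY_STAGES = (
    "sense_overlap",
    "housekeeping",
    "mirna",
    "coding_potential",
    "homology",
    "length",
    "expression",
    "adjacency",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic fixture.

    Methylation rates default to the per-context methylated fractions the
    study observed under control (63.7 % CpG, 43.6 % CHG, 4 % CHH), with a
    small uniform downward shift under salt. Expression-class fractions for
    lncRNAs default to 55 % activated + 20 % up-regulated (~75 % induced);
    mRNAs to 5 % + 25 % (~30 % induced).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 250_000
    n_coding_genes: int = 40
    n_lincRNAs: int = 50
    n_lncNATs: int = 20
    n_decoys_per_stage: int = 1
    meth_rate_cpg: float = 0.637
    meth_rate_chg: float = 0.436
    meth_rate_chh: float = 0.04
    salt_meth_shift: float = -0.02
    mean_coverage: float = 10.0
    frac_activated: float = 0.55
    frac_upregulated: float = 0.20
    mrna_frac_activated: float = 0.05
    mrna_frac_upregulated: float = 0.25
    frac_te_linc: float = 0.25
    frac_nat_full_coverage: float = 0.72
    adjacency_nt: int = 200

    def __post_init__(self) -> None:
        for name in (
            "meth_rate_cpg",
            "meth_rate_chg",
            "meth_rate_chh",
            "frac_activated",
            "frac_upregulated",
            "mrna_frac_activated",
            "mrna_frac_upregulated",
            "frac_te_linc",
            "frac_nat_full_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_activated + self.frac_upregulated > 1.0:
            raise ValueError("activated + upregulated fractions exceed 1")
        for name in (
            "n_chroms",
            "chrom_length",
            "n_coding_genes",
            "n_lincRNAs",
            "n_lncNATs",
            "n_decoys_per_stage",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")

    @property
    def meth_rates(self) -> dict[str, float]:
        return {
            "CpG": self.meth_rate_cpg,
            "CHG": self.meth_rate_chg,
            "CHH": self.meth_rate_chh,
        }

    def condition_rates(self, condition: str) -> dict[str, float]:
        shift = 0.0 if condition == "wt" else self.salt_meth_shift
        return {
            ctx: float(np.clip(rate + shift, 0.0, 1.0))
            for ctx, rate in self.meth_rates.items()
        }


@dataclass
class PlantedTranscript:
    """Coordinates and truth label of one planted transcript."""

    transcript_id: str
    kind: str  # 'mRNA', 'lincRNA', 'lncNAT', or 'decoy:<stage>'
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    expr_class: str = "unchanged"

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class SimulatedStudy:
    """In-memory synthetic study: genome, annotation, planted transcripts."""

    config: SimulationConfig
    genome: dict[str, str]
    genes: list[Gene]
    gene_models: list[TranscriptModel]
    planted: list[PlantedTranscript]
    hk_loci: list[tuple[GenomicInterval, str]]
    mirna_loci: list[tuple[GenomicInterval, str]]
    te_track: list[tuple[GenomicInterval, str]]
    repeat_track: list[tuple[GenomicInterval, str]]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.genome.items()}

    def truth(self) -> dict:
        """Planted truth ledger: per-transcript labels plus summary counts."""
        per_tx = {p.transcript_id: p.kind for p in self.planted}
        counts: dict[str, int] = {}
        for kind in per_tx.values():
            counts[kind] = counts.get(kind, 0) + 1
        return {
            "transcripts": per_tx,
            "counts": counts,
            "n_lincRNA": counts.get("lincRNA", 0),
            "n_lncNAT": counts.get("lncNAT", 0),
        }


def _partition_exons(
    exons: Sequence[tuple[int, int]], strand: str, u5_len: int, u3_len: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]], list[tuple[int, int]]]:
    """Split an exon chain into 5'UTR / CDS / 3'UTR by spliced offsets."""
    total = sum(e - s for s, e in exons)
    u5_len = min(u5_len, max(0, total - 1))
    u3_len = min(u3_len, max(0, total - u5_len - 1))
    a, b = u5_len, total - u3_len  # spliced 5'->3' cut points
    ordered = list(exons) if strand == "+" else list(exons)[::-1]
    parts: dict[str, list[tuple[int, int]]] = {"utr5": [], "cds": [], "utr3": []}
    offset = 0
    for s, e in ordered:
        length = e - s
        for name, lo, hi in (("utr5", 0, a), ("cds", a, b), ("utr3", b, total)):
            seg_lo, seg_hi = max(lo, offset), min(hi, offset + length)
            if seg_lo >= seg_hi:
                continue
            if strand == "+":
                parts[name].append((s + (seg_lo - offset), s + (seg_hi - offset)))
            else:
                parts[name].append((e - (seg_hi - offset), e - (seg_lo - offset)))
        offset += length
    for v in parts.values():
        v.sort()
    return parts["utr5"], parts["cds"], parts["utr3"]


def _random_exons(
    rng: np.random.Generator, start: int, total_len: int, n_exons: int
) -> list[tuple[int, int]]:
    """Exon chain of summed length ``total_len`` with ~100 bp introns."""
    if n_exons <= 1:
        return [(start, start + total_len)]
    cuts = np.sort(
        rng.choice(np.arange(50, total_len - 50), size=n_exons - 1, replace=False)
    )
    lengths = np.diff(np.concatenate([[0], cuts, [total_len]]))
    exons = []
    pos = start
    for L in lengths:
        exons.append((pos, pos + int(L)))
        pos += int(L) + int(rng.integers(80, 150))
    return exons


class _Placer:
    """Sequential feature placement with minimum inter-unit spacing."""

    def __init__(self, cfg: SimulationConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        self.cursors = {f"chr{i + 1}": 1000 for i in range(cfg.n_chroms)}
        self.chroms = list(self.cursors)
        self._next = 0

    def take(self, footprint: int) -> tuple[str, int]:
        """Reserve ``footprint`` bases on the next chromosome with room."""
        min_gap = 2 * self.cfg.adjacency_nt
        for _ in range(len(self.chroms)):
            chrom = self.chroms[self._next % len(self.chroms)]
            self._next += 1
            start = self.cursors[chrom]
            end = start + footprint
            if end <= self.cfg.chrom_length - 1000:
                gap = int(self.rng.integers(min_gap, 2 * min_gap))
                self.cursors[chrom] = end + gap
                return chrom, start
        raise ValueError(
            "could not place all requested features; increase chrom_length "
            f"(currently {self.cfg.chrom_length})"
        )


def simulate_genome(cfg: SimulationConfig) -> SimulatedStudy:
    """Place all study features and draw the genome sequence.

    Raises ``ValueError`` suggesting a larger ``chrom_length`` when the
    requested features cannot be packed with the guaranteed spacing.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    placer = _Placer(cfg, rng)

    genes: list[Gene] = []
    gene_models: list[TranscriptModel] = []
    planted: list[PlantedTranscript] = []
    hk_loci: list[tuple[GenomicInterval, str]] = []
    mirna_loci: list[tuple[GenomicInterval, str]] = []

    n_dec = cfg.n_decoys_per_stage
    # gene units carry at most one attachment each: lncNATs first, then
    # sense-overlap decoys, then adjacency decoys
    needed_hosts = cfg.n_lncNATs + 2 * n_dec
    if cfg.n_coding_genes < needed_hosts:
        raise ValueError(
            f"need >= {needed_hosts} coding genes to host lncNATs and "
            f"gene-linked decoys, got {cfg.n_coding_genes}"
        )
    attachments = (
        ["lncNAT"] * cfg.n_lncNATs
        + ["decoy:sense_overlap"] * n_dec
        + ["decoy:adjacency"] * n_dec
        + [None] * (cfg.n_coding_genes - needed_hosts)
    )
    rng.shuffle(attachments)  # type: ignore[arg-type]

    nat_i = 0
    for gi, attach in enumerate(attachments):
        glen = int(rng.integers(1500, 3000))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        # room for downstream attachments inside the reserved footprint
        extra = 400 if attach else 0
        chrom, start = placer.take(glen + (n_exons - 1) * 150 + extra)
        exons = _random_exons(rng, start, glen, n_exons)
        span = (exons[0][0], exons[-1][1])
        gid = f"gene_{gi + 1:04d}"
        u5, cds, u3 = _partition_exons(
            exons,
            strand,
            int(rng.integers(80, 200)),
            int(rng.integers(120, 300)),
        )
        gene = Gene(gid, GenomicInterval(chrom, span[0], span[1], strand))
        genes.append(gene)
        gene_models.append(
            TranscriptModel(
                transcript_id=f"{gid}.1",
                gene_id=gid,
                exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
                biotype="protein_coding",
                cds=tuple(GenomicInterval(chrom, s, e, strand) for s, e in cds),
                utr5=tuple(GenomicInterval(chrom, s, e, strand) for s, e in u5),
                utr3=tuple(GenomicInterval(chrom, s, e, strand) for s, e in u3),
            )
        )
        planted.append(
            PlantedTranscript(
                transcript_id=f"asm_{gid}",
                kind="mRNA",
                chrom=chrom,
                strand=strand,
                exons=[(s, e) for s, e in exons],
            )
        )
        anti = "-" if strand == "+" else "+"
        if attach == "lncNAT":
            nat_i += 1
            nlen = int(rng.integers(250, min(500, span[1] - span[0] - 60)))
            if rng.random() < cfg.frac_nat_full_coverage:
                ns = span[0] + int(
                    rng.integers(20, span[1] - span[0] - nlen - 20)
                )
            else:  # extend past the gene 3' boundary
                overhang = int(rng.integers(50, 150))
                ns = span[1] - nlen + overhang
            planted.append(
                PlantedTranscript(
                    transcript_id=f"nat_{nat_i:04d}",
                    kind="lncNAT",
                    chrom=chrom,
                    strand=anti,
                    exons=[(ns, ns + nlen)],
                )
            )
        elif attach == "decoy:sense_overlap":
            dlen = int(rng.integers(250, 400))
            ds = span[1] - dlen // 2  # straddles the gene 3' end, same strand
            planted.append(
                PlantedTranscript(
                    transcript_id=f"decoy_sense_{gi}",
                    kind="decoy:sense_overlap",
                    chrom=chrom,
                    strand=strand,
                    exons=[(ds, ds + dlen)],
                )
            )
        elif attach == "decoy:adjacency":
            gap = int(rng.integers(40, cfg.adjacency_nt - 20))
            dlen = int(rng.integers(220, 350))
            ds = span[1] + gap
            planted.append(
                PlantedTranscript(
                    transcript_id=f"decoy_adjacent_{gi}",
                    kind="decoy:adjacency",
                    chrom=chrom,
                    strand=strand,
                    exons=[(ds, ds + dlen)],
                )
            )

    for li in range(cfg.n_lincRNAs):
        llen = int(rng.integers(220, 620))
        strand = "+" if rng.random() < 0.5 else "-"
        two_exon = rng.random() < 0.03
        chrom, start = placer.take(llen + (150 if two_exon else 0))
        exons = _random_exons(rng, start, llen, 2 if two_exon else 1)
        planted.append(
            PlantedTranscript(
                transcript_id=f"linc_{li + 1:04d}",
                kind="lincRNA",
                chrom=chrom,
                strand=strand,
                exons=[(s, e) for s, e in exons],
            )
        )

    # blacklist loci with one overlapping decoy transcript each
    for stage, loci in (("housekeeping", hk_loci), ("mirna", mirna_loci)):
        for k in range(n_dec):
            chrom, start = placer.take(600)
            label = "tRNA" if stage == "housekeeping" else "miRNA_precursor"
            loci.append(
                (GenomicInterval(chrom, start, start + 200, "+"), label)
            )
            planted.append(
                PlantedTranscript(
                    transcript_id=f"decoy_{stage}_{k}",
                    kind=f"decoy:{stage}",
                    chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=[(start + 100, start + 450)],
                )
            )

    # free-standing single-stage decoys
    for stage, length_range in (
        ("coding_potential", (250, 500)),
        ("homology", (250, 500)),
        ("length", (120, 199)),
        ("expression", (250, 500)),
    ):
        for k in range(n_dec):
            dlen = int(rng.integers(*length_range))
            strand = "+" if rng.random() < 0.5 else "-"
            chrom, start = placer.take(dlen)
            planted.append(
                PlantedTranscript(
                    transcript_id=f"decoy_{stage}_{k}",
                    kind=f"decoy:{stage}",
                    chrom=chrom,
                    strand=strand,
                    exons=[(start, start + dlen)],
                )
            )

    # genome sequence
    genome = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for ci in range(cfg.n_chroms):
        seq = rng.choice(bases, size=cfg.chrom_length)
        genome[f"chr{ci + 1}"] = seq.tobytes().decode()

    # TE track: cover a fraction of lincRNAs at high coverage, plus background
    te_track: list[tuple[GenomicInterval, str]] = []
    lincs = [p for p in planted if p.kind == "lincRNA"]
    n_te_lincs = int(round(cfg.frac_te_linc * len(lincs)))
    te_idx = rng.choice(len(lincs), size=n_te_lincs, replace=False) if lincs else []
    labels = list(TE_SUPERFAMILIES)
    for i in te_idx:
        p = lincs[int(i)]
        s, e = p.span
        covered = int(0.87 * (e - s))
        label = labels[
            int(rng.choice(len(labels), p=np.asarray(TE_WEIGHTS) / sum(TE_WEIGHTS)))
        ]
        off = int(rng.integers(0, (e - s) - covered + 1))
        te_track.append(
            (GenomicInterval(p.chrom, s + off, s + off + covered, "."), label)
        )
    # background TEs in unconstrained positions
    for _ in range(3 * cfg.n_chroms):
        chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
        s = int(rng.integers(0, cfg.chrom_length - 2000))
        te_track.append(
            (
                GenomicInterval(chrom, s, s + int(rng.integers(300, 1500)), "."),
                labels[int(rng.choice(len(labels)))],
            )
        )
    # repeat track = TEs plus unlabeled simple repeats
    repeat_track = list(te_track)
    for _ in range(5 * cfg.n_chroms):
        chrom = f"chr{int(rng.integers(cfg.n_chroms)) + 1}"
        s = int(rng.integers(0, cfg.chrom_length - 500))
        repeat_track.append(
            (GenomicInterval(chrom, s, s + int(rng.integers(80, 400)), "."), "simple")
        )

    return SimulatedStudy(
        config=cfg,
        genome=genome,
        genes=genes,
        gene_models=gene_models,
        planted=planted,
        hk_loci=hk_loci,
        mirna_loci=mirna_loci,
        te_track=te_track,
        repeat_track=repeat_track,
    )


def _draw_lnc_fpkm(
    rng: np.random.Generator, frac_act: float, frac_up: float
) -> tuple[str, float, float]:
    """Expression class and (fpkm_wt, fpkm_sa) for a retained transcript."""
    u = rng.random()
    if u < frac_act:
        return "activated", 0.0, float(2.0 + rng.lognormal(1.0, 0.6))
    if u < frac_act + frac_up:
        wt = float(rng.uniform(2.0, 6.0))
        return "up_regulated", wt, wt * float(rng.uniform(2.2, 5.0))
    wt = float(rng.uniform(2.0, 8.0))
    return "unchanged", wt, wt * float(rng.uniform(0.6, 1.8))


def simulate_transcript_set(
    cfg: SimulationConfig, study: SimulatedStudy
) -> tuple[
    list[TranscriptModel],
    dict[str, TranscriptAttributes],
    list[tuple[str, str, float]],
]:
    """Materialize planted transcripts, attribute rows, and homology hits.

    Planted true positives get coding-potential <= 0.5, no protein hit, and
    expression passing retention; each decoy's attributes make it fail its
    single intended stage.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    transcripts: list[TranscriptModel] = []
    attrs: dict[str, TranscriptAttributes] = {}
    hits: list[tuple[str, str, float]] = []
    for p in study.planted:
        transcripts.append(
            TranscriptModel(
                transcript_id=p.transcript_id,
                gene_id=f"XLOC_{p.transcript_id}",
                exons=tuple(
                    GenomicInterval(p.chrom, s, e, p.strand) for s, e in p.exons
                ),
            )
        )
        low_cpc = float(rng.uniform(-1.0, 0.4))
        if p.kind == "mRNA":
            cls, wt, sa = _draw_lnc_fpkm(
                rng, cfg.mrna_frac_activated, cfg.mrna_frac_upregulated
            )
            attrs[p.transcript_id] = TranscriptAttributes(
                cpc_score=float(rng.uniform(2.0, 10.0)),
                has_swissprot_hit=True,
                fpkm_wt=wt,
                fpkm_sa=sa,
            )
        elif p.kind in ("lincRNA", "lncNAT"):
            cls, wt, sa = _draw_lnc_fpkm(
                rng, cfg.frac_activated, cfg.frac_upregulated
            )
            attrs[p.transcript_id] = TranscriptAttributes(
                cpc_score=low_cpc, has_swissprot_hit=False, fpkm_wt=wt, fpkm_sa=sa
            )
            p.expr_class = cls
        elif p.kind == "decoy:coding_potential":
            attrs[p.transcript_id] = TranscriptAttributes(
                cpc_score=float(rng.uniform(0.6, 3.0)),
                has_swissprot_hit=False,
                fpkm_wt=3.0,
                fpkm_sa=3.0,
            )
        elif p.kind == "decoy:homology":
            attrs[p.transcript_id] = TranscriptAttributes(
                cpc_score=low_cpc,
                has_swissprot_hit=True,
                fpkm_wt=3.0,
                fpkm_sa=3.0,
            )
            hits.append((p.transcript_id, "sp|Q0000|SYNTH", 1e-20))
        elif p.kind == "decoy:expression":
            attrs[p.transcript_id] = TranscriptAttributes(
                cpc_score=low_cpc,
                has_swissprot_hit=False,
                fpkm_wt=float(rng.uniform(0.0, 1.9)),
                fpkm_sa=float(rng.uniform(0.0, 1.9)),
            )
        else:  # sense-overlap, blacklist, length, adjacency decoys
            attrs[p.transcript_id] = TranscriptAttributes(
                cpc_score=low_cpc,
                has_swissprot_hit=False,
                fpkm_wt=3.0,
                fpkm_sa=3.0,
            )
    return transcripts, attrs, hits


def simulate_methylome(
    cfg: SimulationConfig,
    genome: dict[str, str],
    condition: str = "wt",
) -> list[CytosineSite]:
    """Per-cytosine methylation report for one condition.

    Every cytosine on both strands is enumerated with its true context; the
    site's binary methylation state is Bernoulli(context rate) and coverage
    is Poisson(mean_coverage), with all reads agreeing with the state (a
    methylated site emits only methylated reads), so a covered site's calls
    reflect the planted truth exactly.
    """
    if condition not in ("wt", "sa"):
        raise ValueError("condition must be 'wt' or 'sa'")
    rates = cfg.condition_rates(condition)
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 3 if condition == "wt" else 4])
    )
    skeleton = call_contexts(genome)
    n = len(skeleton)
    contexts = np.array([s.context for s in skeleton])
    state = np.zeros(n, dtype=bool)
    for ctx, rate in rates.items():
        mask = contexts == ctx
        state[mask] = rng.random(int(mask.sum())) < rate
    coverage = rng.poisson(cfg.mean_coverage, size=n)
    out = []
    for site, st, cov in zip(skeleton, state, coverage):
        out.append(
            CytosineSite(
                chrom=site.chrom,
                pos=site.pos,
                strand=site.strand,
                context=site.context,
                meth_reads=int(cov) if st else 0,
                unmeth_reads=0 if st else int(cov),
            )
        )
    return out


def write_study(study: SimulatedStudy, out_dir) -> dict[str, Path]:
    """Write the study to disk: FASTA, GFF3, GTF, BEDs, TSVs, truth.json."""
    from . import io as sio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = study.config
    paths = {
        "genome": out_dir / "genome.fa",
        "annotation": out_dir / "annotation.gtf",
        "transcripts": out_dir / "transcripts.gtf",
        "attributes": out_dir / "attributes.tsv",
        "blast": out_dir / "swissprot_hits.tsv",
        "hk_bed": out_dir / "housekeeping.bed",
        "mirna_bed": out_dir / "mirna_precursors.bed",
        "te_bed": out_dir / "te_track.bed",
        "repeat_bed": out_dir / "repeat_track.bed",
        "cx_wt": out_dir / "methylome_wt.cx.txt",
        "cx_sa": out_dir / "methylome_sa.cx.txt",
        "truth": out_dir / "truth.json",
    }
    sio.write_fasta(study.genome, paths["genome"])
    sio.write_gtf(study.gene_models, paths["annotation"])
    transcripts, attrs, hits = simulate_transcript_set(cfg, study)
    sio.write_gtf(transcripts, paths["transcripts"])
    sio.write_attribute_table(attrs, paths["attributes"])
    with open(paths["blast"], "w") as fh:
        for q, s, e in hits:
            fh.write(
                f"{q}\t{s}\t98.0\t200\t2\t0\t1\t200\t1\t200\t{e:g}\t350\n"
            )
    sio.write_bed_track(study.hk_loci, paths["hk_bed"])
    sio.write_bed_track(study.mirna_loci, paths["mirna_bed"])
    sio.write_bed_track(study.te_track, paths["te_bed"])
    sio.write_bed_track(study.repeat_track, paths["repeat_bed"])
    for cond in ("wt", "sa"):
        sites = simulate_methylome(cfg, study.genome, cond)
        sio.write_cx_report(sites, paths[f"cx_{cond}"], genome=study.genome)
    truth = study.truth()
    truth["config"] = asdict(cfg)
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
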