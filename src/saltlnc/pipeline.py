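"""End-to-end orchestration: simulate -> classify -> characterize -> methylome.

``run_all`` validates the configuration up front, runs each stage behind the
library functions, and writes a machine-readable run manifest (config echo,
input checksums, per-stage row counts). Outputs are a pure function of
configuration + inputs; a rerun with the same seed and inputs is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import characterize as ch
from . import io as sio
from . import methylome as me
from .classify import CascadeParams, run_cascade
from .core import Gene
from .simulate import SimulationConfig, simulate_genome, simulate_methylome, write_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Input paths and thresholds; defaults are the study's values."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    # input file roles (filled automatically after a simulate stage)
    gtf: Optional[str] = None
    annotation: Optional[str] = None
    genome: Optional[str] = None
    attrs: Optional[str] = None
    hk_bed: Optional[str] = None
    mirna_bed: Optional[str] = None
    blast_tsv: Optional[str] = None
    te_bed: Optional[str] = None
    repeat_bed: Optional[str] = None
    cx_wt: Optional[str] = None
    cx_sa: Optional[str] = None
    # thresholds
    cpc_max: float = 0.5
    min_len: int = 200
    min_fpkm: float = 2.0
    adjacency_nt: int = 200
    evalue_max: float = 1e-5
    min_cov: int = 1
    promoter_bp: int = 1000
    window_bp: int = 1_000_000
    body_bins: int = 60
    up_bins: int = 20

    def validate(self) -> None:
        numeric = {
            "cpc_max": float,
            "min_fpkm": float,
            "evalue_max": float,
            "min_len": int,
            "adjacency_nt": int,
            "min_cov": int,
            "promoter_bp": int,
            "window_bp": int,
            "body_bins": int,
            "up_bins": int,
            "seed": int,
        }
        for name, kind in numeric.items():
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ValueError(f"config field {name!r} must be numeric, got {v!r}")
            if kind is int and int(v) != v:
                raise ValueError(f"config field {name!r} must be an integer, got {v!r}")
        for name in ("window_bp", "promoter_bp", "body_bins", "up_bins", "min_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"config field {name!r} must be positive")


def _checksum(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(
    config: PipelineConfig,
    simulate: bool = True,
    sim_config: Optional[SimulationConfig] = None,
) -> Path:
    """Run the full pipeline; returns the output directory.

    With ``simulate`` the synthetic study is generated first and its files
    feed the remaining stages; otherwise every input path must exist.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "status": "running",
    }

    def fail(stage: str, exc: Exception):
        manifest["status"] = f"failed:{stage}"
        manifest["error"] = str(exc)
        _write_manifest(out_dir, manifest)
        raise exc

    if simulate:
        scfg = sim_config or SimulationConfig(seed=config.seed)
        study = simulate_genome(scfg)
        sim_dir = out_dir / "simulated"
        paths = write_study(study, sim_dir)
        config.gtf = str(paths["transcripts"])
        config.annotation = str(paths["annotation"])
        config.genome = str(paths["genome"])
        config.attrs = str(paths["attributes"])
        config.hk_bed = str(paths["hk_bed"])
        config.mirna_bed = str(paths["mirna_bed"])
        config.blast_tsv = str(paths["blast"])
        config.te_bed = str(paths["te_bed"])
        config.repeat_bed = str(paths["repeat_bed"])
        config.cx_wt = str(paths["cx_wt"])
        config.cx_sa = str(paths["cx_sa"])
        manifest["stages"]["simulate"] = {
            "n_planted": len(study.planted),
            "truth": str(paths["truth"]),
        }
        logger.info("simulated study with %d planted transcripts", len(study.planted))

    required = {
        "gtf": config.gtf,
        "annotation": config.annotation,
        "genome": config.genome,
        "attrs": config.attrs,
    }
    missing = [k for k, v in required.items() if not v or not Path(v).exists()]
    if missing:
        raise FileNotFoundError(f"missing required inputs: {missing}")
    manifest["inputs"] = {
        k: {"path": v, "sha256": _checksum(Path(v))}
        for k, v in dataclasses.asdict(config).items()
        if k
        in (
            "gtf",
            "annotation",
            "genome",
            "attrs",
            "hk_bed",
            "mirna_bed",
            "blast_tsv",
            "te_bed",
            "repeat_bed",
            "cx_wt",
            "cx_sa",
        )
        and v
        and Path(v).exists()
    }

    # ---- classify
    transcripts = sio.read_gtf(config.gtf)
    annotation = sio.read_annotation_genes(config.annotation)
    attrs = sio.read_attribute_table(config.attrs)
    hk = sio.read_bed_track(config.hk_bed) if config.hk_bed else []
    mirna = sio.read_bed_track(config.mirna_bed) if config.mirna_bed else []
    hits = sio.read_blast_tab(config.blast_tsv) if config.blast_tsv else []
    params = CascadeParams(
        cpc_max=config.cpc_max,
        min_len=config.min_len,
        min_fpkm=config.min_fpkm,
        adjacency_nt=config.adjacency_nt,
        evalue_max=config.evalue_max,
    )
    try:
        result = run_cascade(transcripts, annotation, attrs, hk, mirna, hits, params)
    except Exception as exc:  # manifest marks the failure point
        fail("classify", exc)
    classified = result.lincRNAs + result.lncNATs
    sio.write_results(
        out_dir,
        classified=classified,
        class_labels=result.class_labels,
        audit=result.audit,
    )
    manifest["stages"]["classify"] = result.audit.to_dict() | result.gene_counts()
    del manifest["stages"]["classify"]["disposition"]

    # ---- characterize
    genome = sio.read_fasta(config.genome)
    chrom_lengths = {name: len(seq) for name, seq in genome.items()}
    classes = {
        "lincRNA": result.lincRNAs,
        "lncNAT": result.lncNATs,
        "mRNA": result.mRNAs,
    }
    tables: dict[str, pd.DataFrame] = {}
    tables["length_exon_stats"] = length_stats = ch.length_exon_stats(classes)
    length_stats["exon_counts"] = length_stats["exon_counts"].map(json.dumps)
    repeats = sio.read_bed_track(config.repeat_bed) if config.repeat_bed else []
    overlap_rows = []
    for cls, txs in classes.items():
        st = ch.feature_overlap_stats(txs, repeats)
        overlap_rows.append(
            {
                "class": cls,
                "fraction_by_number": st.fraction_by_number,
                "fraction_by_length": st.fraction_by_length,
            }
        )
    tables["repeat_overlap"] = pd.DataFrame(overlap_rows)
    te = sio.read_bed_track(config.te_bed) if config.te_bed else []
    shares, mean_cov = ch.te_composition(result.lincRNAs, te)
    tables["te_composition"] = pd.DataFrame(
        [{"superfamily": k, "share": v} for k, v in shares.items()]
        + [{"superfamily": "mean_covered_fraction", "share": mean_cov}]
    )
    au = ch.au_content_ecdf(classes, genome)
    tables["au_content"] = pd.DataFrame(
        [
            {"class": cls, "au_fraction": float(v)}
            for cls, values in au.items()
            for v in values
        ]
    )
    if result.lncNATs:
        tables["nat_coverage"] = ch.nat_coverage(result.lncNATs, annotation)
    tables["window_distribution"] = ch.window_distribution(
        classes, chrom_lengths, config.window_bp
    )
    expr_table, induced = ch.expression_classes(
        {cls: [t.transcript_id for t in txs] for cls, txs in classes.items()}, attrs
    )
    tables["expression_classes"] = expr_table
    tables["induced_fractions"] = pd.DataFrame(
        [{"class": k, "induced_fraction": v} for k, v in induced.items()]
    )
    tables["nearest_genes"] = ch.nearest_gene_targets(result.lincRNAs, annotation)
    manifest["stages"]["characterize"] = {
        "tables": sorted(tables),
        "induced_fractions": induced,
    }

    # ---- methylome
    if config.cx_wt:
        sites_wt = me.as_site_frame(sio.read_cx_report(config.cx_wt))
        lnc_genes = [Gene(t.transcript_id, t.span, "unknown") for t in classified]
        coding = [g for g in annotation if g.biotype == "protein_coding"]
        all_regions = coding + lnc_genes
        rmc_wt = me.gene_promoter_rmc(
            all_regions,
            sites_wt,
            min_cov=config.min_cov,
            promoter_bp=config.promoter_bp,
            chrom_lengths=chrom_lengths,
        )
        tables["gene_rmc_wt"] = rmc_wt
        tables["window_rmc_wt"] = me.chrom_window_rmc(
            sites_wt, chrom_lengths, config.window_bp, config.min_cov
        )
        tables["metagene_wt"] = me.metagene_profile(
            all_regions,
            sites_wt,
            n_body_bins=config.body_bins,
            upstream_bp=config.promoter_bp,
            n_up_bins=config.up_bins,
            min_cov=config.min_cov,
        )
        class_map = {t.transcript_id: cls for cls, txs in classes.items() for t in txs}
        class_map.update({g.gene_id: "mRNA" for g in coding})
        never = me.never_methylated_fraction(rmc_wt, class_map)
        manifest["stages"]["methylome"] = {
            "never_methylated_fraction": never,
            "genome_wide_methylated_fraction": me.genome_wide_methylated_fraction(
                sites_wt, config.min_cov
            ),
        }
        if config.cx_sa:
            sites_sa = me.as_site_frame(sio.read_cx_report(config.cx_sa))
            rmc_sa = me.gene_promoter_rmc(
                all_regions,
                sites_sa,
                min_cov=config.min_cov,
                promoter_bp=config.promoter_bp,
                chrom_lengths=chrom_lengths,
            )
            tables["gene_rmc_sa"] = rmc_sa
            tables["condition_ratio"] = me.condition_ratio(rmc_wt, rmc_sa)
        tables["h_base_composition"] = me.h_base_composition(sites_wt, genome)

    sio.write_results(out_dir, tables=tables)
    manifest["status"] = "ok"
    _write_manifest(out_dir, manifest)
    return out_dir


def _write_manifest(out_dir: Path, manifest: dict) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
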