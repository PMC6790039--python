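#!/usr/bin/env python
"""Methylation-ratio (RMC) analysis of the simulated two-condition
methylome: genome-wide context rates, per-gene and promoter RMCs for
mRNAs and lncRNAs, chromosome-window profiles, metagene profiles, the
between-condition RMC ratio, and H-base composition.

Reads results/study/ + results/classify/, writes results/methylome/.
"""

import argparse
import json
from pathlib import Path

from saltlnc import io as sio
from saltlnc import methylome as me
from saltlnc.core import Gene


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--classify", type=Path, default=Path("results/classify"))
    ap.add_argument("--out", type=Path, default=Path("results/methylome"))
    ap.add_argument("--min-cov", type=int, default=1)
    args = ap.parse_args()

    genome = sio.read_fasta(args.study / "genome.fa")
    chrom_lengths = {k: len(v) for k, v in genome.items()}
    annotation = sio.read_annotation_genes(args.study / "annotation.gtf")
    classified = sio.read_gtf(args.classify / "classified.gtf")
    audit = json.loads((args.classify / "cascade_audit.json").read_text())
    class_map = {
        tid: cls
        for tid, cls in audit["disposition"].items()
        if cls in ("lincRNA", "lncNAT")
    }
    class_map.update({g.gene_id: "mRNA" for g in annotation})
    regions = list(annotation) + [
        Gene(t.transcript_id, t.span, "unknown") for t in classified
    ]

    frames = {
        cond: me.as_site_frame(
            sio.read_cx_report(args.study / f"methylome_{cond}.cx.txt")
        )
        for cond in ("wt", "sa")
    }
    tables = {}
    for cond, frame in frames.items():
        frac = me.genome_wide_methylated_fraction(frame, args.min_cov)
        print(
            f"{cond}: methylated fractions "
            + ", ".join(f"{ctx} {100 * frac[ctx]:.1f}%" for ctx in frac)
        )
        tables[f"gene_rmc_{cond}"] = me.gene_promoter_rmc(
            regions, frame, min_cov=args.min_cov, chrom_lengths=chrom_lengths
        )
        tables[f"window_rmc_{cond}"] = me.chrom_window_rmc(
            frame, chrom_lengths, window_bp=10_000, min_cov=args.min_cov
        )
        tables[f"metagene_{cond}"] = me.metagene_profile(
            regions, frame, min_cov=args.min_cov
        )
    tables["condition_ratio"] = me.condition_ratio(
        tables["gene_rmc_wt"], tables["gene_rmc_sa"]
    )
    tables["h_base_composition"] = me.h_base_composition(frames["wt"], genome)
    sio.write_results(args.out, tables=tables)

    never = me.never_methylated_fraction(tables["gene_rmc_wt"], class_map)
    print(
        "never methylated (CpG+CHG, gene body): "
        + ", ".join(f"{cls} {100 * v:.1f}%" for cls, v in sorted(never.items()))
    )
    hb = tables["h_base_composition"]
    at = hb[(hb.context == "CHH") & hb.base.isin(["A", "T"])]["frequency"].sum()
    print(f"H-base A+T preference (CHH): {100 * at:.1f}%")
    ratio = tables["condition_ratio"]
    ok = ratio[~ratio["flagged"]]
    print(
        f"condition RMC ratio: median {ok['ratio'].median():.3f} over "
        f"{len(ok)} defined gene/region/context combinations"
    )


if __name__ == "__main__":
    main()
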