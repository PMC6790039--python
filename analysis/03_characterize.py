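#!/usr/bin/env python
"""Characterize the classified transcripts: length/exon statistics, repeat
and TE overlap, AU content, antisense coverage, chromosome windows,
expression classes with a chi-square of induced fractions, and nearest
genes.

Reads results/study/ + results/classify/, writes results/characterize/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from saltlnc import characterize as ch
from saltlnc import io as sio


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--study", type=Path, default=Path("results/study"))
    ap.add_argument("--classify", type=Path, default=Path("results/classify"))
    ap.add_argument("--out", type=Path, default=Path("results/characterize"))
    args = ap.parse_args()

    genome = sio.read_fasta(args.study / "genome.fa")
    chrom_lengths = {k: len(v) for k, v in genome.items()}
    annotation = sio.read_annotation_genes(args.study / "annotation.gtf")
    attrs = sio.read_attribute_table(args.study / "attributes.tsv")
    classified = sio.read_gtf(args.classify / "classified.gtf")
    audit = json.loads((args.classify / "cascade_audit.json").read_text())
    labels = {
        tid: cls
        for tid, cls in audit["disposition"].items()
        if cls in ("lincRNA", "lncNAT")
    }
    all_tx = sio.read_gtf(args.study / "transcripts.gtf")
    classes = {
        "lincRNA": [t for t in classified if labels[t.transcript_id] == "lincRNA"],
        "lncNAT": [t for t in classified if labels[t.transcript_id] == "lncNAT"],
        "mRNA": [
            t
            for t in all_tx
            if audit["disposition"].get(t.transcript_id) == "sense_overlap"
        ],
    }

    tables = {}
    stats = ch.length_exon_stats(classes)
    tables["length_exon_stats"] = stats.assign(
        exon_counts=stats["exon_counts"].map(json.dumps)
    )
    repeats = sio.read_bed_track(args.study / "repeat_track.bed")
    tables["repeat_overlap"] = pd.DataFrame(
        [
            {"class": cls, **vars(ch.feature_overlap_stats(txs, repeats))}
            for cls, txs in classes.items()
        ]
    )
    te = sio.read_bed_track(args.study / "te_track.bed")
    shares, mean_cov = ch.te_composition(classes["lincRNA"], te)
    tables["te_composition"] = pd.DataFrame(
        [{"superfamily": k, "share": v} for k, v in shares.items()]
    )
    tables["nat_coverage"] = ch.nat_coverage(classes["lncNAT"], annotation)
    tables["window_distribution"] = ch.window_distribution(
        classes, chrom_lengths, window_bp=10_000
    )
    ids = {cls: [t.transcript_id for t in txs] for cls, txs in classes.items()}
    expr, induced = ch.expression_classes(ids, attrs)
    tables["expression_classes"] = expr
    tables["nearest_genes"] = ch.nearest_gene_targets(classes["lincRNA"], annotation)

    sio.write_results(args.out, tables=tables)

    for cls, txs in classes.items():
        row = stats[stats["class"] == cls].iloc[0]
        print(
            f"{cls:<8s}: n={row['n']:<4d} mean length {row['mean_length']:7.1f} nt, "
            f"single-exon {100 * row['single_exon_fraction']:.1f}%"
        )
    ov = tables["repeat_overlap"].set_index("class")
    print(
        "repeat overlap (lincRNA): "
        f"{100 * ov.loc['lincRNA', 'fraction_by_number']:.1f}% by number, "
        f"{100 * ov.loc['lincRNA', 'fraction_by_length']:.1f}% by length"
    )
    if mean_cov == mean_cov:
        print(
            f"TE-overlapping lincRNAs: mean TE-covered fraction "
            f"{100 * mean_cov:.1f}%; superfamily shares "
            + ", ".join(f"{k} {100 * v:.1f}%" for k, v in shares.items())
        )
    full = tables["nat_coverage"]["fully_covered"].mean()
    print(f"lncNATs entirely antisense-covered: {100 * full:.1f}%")
    linc_ind, mrna_ind = induced["lincRNA"], induced["mRNA"]
    n_linc, n_mrna = len(ids["lincRNA"]), len(ids["mRNA"])
    table = [
        [round(linc_ind * n_linc), n_linc - round(linc_ind * n_linc)],
        [round(mrna_ind * n_mrna), n_mrna - round(mrna_ind * n_mrna)],
    ]
    stat, p = ch.induced_chi_square(table)
    print(
        f"induced: lincRNA {100 * linc_ind:.1f}% vs mRNA {100 * mrna_ind:.1f}% "
        f"(chi-square {stat:.1f}, P = {p:.2e})"
    )
    near = tables["nearest_genes"]
    print(
        f"nearest genes: {len(near)} targets, median distance "
        f"{near['distance'].median():.0f} bp, "
        f"{100 * (near['orientation'] == 'sense').mean():.1f}% sense"
    )


if __name__ == "__main__":
    main()
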