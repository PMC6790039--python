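"""Descriptive statistics: oracle equivalence and structural properties."""

import numpy as np
import pytest

from saltlnc import characterize as ch
from saltlnc.core import Gene, GenomicInterval, TranscriptAttributes, TranscriptModel


def tx(tid, start, end, strand="+", chrom="chr1", exons=None):
    exons = exons or [(start, end)]
    return TranscriptModel(
        tid, f"g_{tid}", tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    )


def gene(gid, start, end, strand="+", chrom="chr1"):
    return Gene(gid, GenomicInterval(chrom, start, end, strand))


def bitmap_covered(transcript, features, chrom_len=100_000):
    """Per-base oracle: exonic bases under any feature interval."""
    mask = np.zeros(chrom_len, dtype=bool)
    for iv, _lab in features:
        if iv.chrom == transcript.chrom:
            mask[iv.start : iv.end] = True
    return sum(int(mask[e.start : e.end].sum()) for e in transcript.exons)


class TestLengthExonStats:
    def test_mean_and_exons(self):
        classes = {"lincRNA": [tx("a", 0, 300), tx("b", 0, 450)]}
        df = ch.length_exon_stats(classes)
        assert df.loc[0, "mean_length"] == 375.0
        assert df.loc[0, "single_exon_fraction"] == 1.0

    def test_empty_class_flagged(self):
        df = ch.length_exon_stats({"lncNAT": []})
        assert df.loc[0, "n"] == 0 and np.isnan(df.loc[0, "mean_length"])

    def test_exon_histogram_matches_planted(self, small_study, small_transcripts):
        transcripts, _a, _h = small_transcripts
        by_id = {t.transcript_id: t for t in transcripts}
        lincs = [
            by_id[p.transcript_id]
            for p in small_study.planted
            if p.kind == "lincRNA"
        ]
        df = ch.length_exon_stats({"lincRNA": lincs})
        planted_counts = {}
        for p in small_study.planted:
            if p.kind == "lincRNA":
                planted_counts[len(p.exons)] = planted_counts.get(len(p.exons), 0) + 1
        assert df.loc[0, "exon_counts"] == planted_counts


class TestFeatureOverlap:
    def test_by_number_half(self):
        feats = [(GenomicInterval("chr1", 0, 50, "."), "r")]
        st = ch.feature_overlap_stats([tx("a", 0, 100), tx("b", 500, 600)], feats)
        assert st.fraction_by_number == 0.5

    def test_full_containment_contributes_full_length(self):
        feats = [(GenomicInterval("chr1", 0, 1000, "."), "r")]
        st = ch.feature_overlap_stats([tx("a", 100, 400)], feats)
        assert st.fraction_by_length == 1.0

    def test_double_counting_avoided_by_merge(self):
        feats = [
            (GenomicInterval("chr1", 0, 60, "."), "r1"),
            (GenomicInterval("chr1", 40, 100, "."), "r2"),
        ]
        st = ch.feature_overlap_stats([tx("a", 0, 100)], feats)
        assert st.fraction_by_length == 1.0  # not 1.6

    def test_matches_bitmap_oracle_random(self, rng):
        for _ in range(30):
            n_tx = int(rng.integers(1, 6))
            txs = []
            for i in range(n_tx):
                s = int(rng.integers(0, 5000))
                n_ex = int(rng.integers(1, 4))
                exons, pos = [], s
                for _e in range(n_ex):
                    L = int(rng.integers(20, 200))
                    exons.append((pos, pos + L))
                    pos += L + int(rng.integers(10, 80))
                txs.append(tx(f"t{i}", 0, 1, exons=exons))
            feats = [
                (
                    GenomicInterval(
                        "chr1", int(st_ := rng.integers(0, 6000)),
                        int(st_ + rng.integers(10, 400)), ".",
                    ),
                    "r",
                )
                for _f in range(int(rng.integers(1, 8)))
            ]
            st = ch.feature_overlap_stats(txs, feats)
            cov = sum(bitmap_covered(t, feats) for t in txs)
            tot = sum(t.spliced_length for t in txs)
            assert st.fraction_by_length == pytest.approx(cov / tot)
            by_num = np.mean([bitmap_covered(t, feats) > 0 for t in txs])
            assert st.fraction_by_number == pytest.approx(by_num)


class TestTeComposition:
    def test_all_rlg(self):
        te = [(GenomicInterval("chr1", 0, 80, "."), "RLG")]
        shares, mean_cov = ch.te_composition([tx("a", 0, 100)], te)
        assert shares == {"RLG": 1.0}
        assert mean_cov == pytest.approx(0.8)

    def test_mean_covered_fraction(self):
        te = [(GenomicInterval("chr1", 0, 87, "."), "RLC")]
        _s, mean_cov = ch.te_composition([tx("a", 0, 100)], te)
        assert mean_cov == pytest.approx(0.87)

    def test_planted_mixture_shares(self):
        # 60 RLG bases on one transcript, 40 DTM on another
        te = [
            (GenomicInterval("chr1", 0, 60, "."), "RLG"),
            (GenomicInterval("chr1", 500, 540, "."), "DTM"),
        ]
        shares, _ = ch.te_composition([tx("a", 0, 100), tx("b", 500, 600)], te)
        assert shares == pytest.approx({"RLG": 0.6, "DTM": 0.4})

    def test_non_overlapping_lincs_excluded(self):
        te = [(GenomicInterval("chr1", 0, 50, "."), "RLG")]
        _s, mean_cov = ch.te_composition([tx("a", 0, 100), tx("b", 900, 1000)], te)
        assert mean_cov == pytest.approx(0.5)  # only transcript a counts


class TestAuContent:
    GENOME = {"chr1": "AATTACGTGCGCGCGC" * 10}

    def test_ecdf_reaches_one(self):
        classes = {"lincRNA": [tx("a", 0, 8), tx("b", 4, 12)]}
        curves = ch.au_content_ecdf(classes, self.GENOME)
        for values in curves.values():
            x, y = ch.ecdf(values)
            assert y[-1] == 1.0
            assert np.all(np.diff(y) >= 0)

    def test_mrna_partitioned(self):
        t = TranscriptModel(
            "m1",
            "g1",
            (GenomicInterval("chr1", 0, 16, "+"),),
            cds=(GenomicInterval("chr1", 4, 12, "+"),),
            utr5=(GenomicInterval("chr1", 0, 4, "+"),),
            utr3=(GenomicInterval("chr1", 12, 16, "+"),),
        )
        curves = ch.au_content_ecdf({"mRNA": [t]}, self.GENOME)
        assert set(curves) == {"5'UTR", "CDS", "3'UTR"}
        # 5'UTR = AATT -> AU 1.0; CDS = ACGTGCGC -> one A + one T = 2/8
        assert curves["5'UTR"][0] == pytest.approx(1.0)
        assert curves["CDS"][0] == pytest.approx(2 / 8)

    def test_mrna_without_partition_skipped(self):
        curves = ch.au_content_ecdf({"mRNA": [tx("m", 0, 8)]}, self.GENOME)
        assert curves == {}


class TestNatCoverage:
    def test_fully_inside(self):
        df = ch.nat_coverage([tx("n", 100, 200, "+")], [gene("g", 0, 500, "-")])
        assert df.loc[0, "coverage"] == 1.0 and df.loc[0, "fully_covered"]

    def test_half_inside(self):
        df = ch.nat_coverage([tx("n", 0, 200, "+")], [gene("g", 100, 500, "-")])
        assert df.loc[0, "coverage"] == 0.5

    def test_max_over_antisense_genes(self):
        genes = [gene("g1", 0, 150, "-"), gene("g2", 150, 400, "-")]
        df = ch.nat_coverage([tx("n", 100, 300, "+")], genes)
        # enumerate-genes oracle: g1 covers 50/200, g2 covers 150/200
        assert df.loc[0, "coverage"] == pytest.approx(0.75)
        assert df.loc[0, "gene_id"] == "g2"

    def test_nat_without_antisense_gene_is_an_error(self):
        with pytest.raises(ValueError, match="antisense"):
            ch.nat_coverage([tx("n", 0, 100, "+")], [gene("g", 500, 900, "+")])


class TestWindows:
    LENGTHS = {"chr1": 2_500_000}

    def test_start_zero_in_window_zero(self):
        df = ch.window_distribution(
            {"lincRNA": [tx("a", 0, 300)]}, self.LENGTHS, 1_000_000
        )
        row = df[(df["class"] == "lincRNA") & (df["count"] > 0)].iloc[0]
        assert row["window"] == 0

    def test_exact_boundary_next_window(self):
        df = ch.window_distribution(
            {"lincRNA": [tx("a", 1_000_000, 1_000_300)]}, self.LENGTHS, 1_000_000
        )
        row = df[df["count"] > 0].iloc[0]
        assert row["window"] == 1

    def test_counts_conserved(self, small_study, small_transcripts):
        transcripts, _a, _h = small_transcripts
        classes = {"all": transcripts}
        df = ch.window_distribution(
            classes, small_study.chrom_lengths, 10_000
        )
        assert df["count"].sum() == len(transcripts)

    def test_transcript_beyond_chrom_errors(self):
        with pytest.raises(ValueError, match="beyond"):
            ch.window_distribution(
                {"x": [tx("a", 3_000_000, 3_000_100)]}, self.LENGTHS, 1_000_000
            )


class TestExpressionClasses:
    def attrs(self, wt, sa):
        return TranscriptAttributes(0.0, False, wt, sa)

    @pytest.mark.parametrize(
        "wt, sa, expected",
        [
            (0.0, 5.0, "activated"),
            (2.0, 5.0, "up_regulated"),
            (5.0, 2.0, "down_regulated"),
            (5.0, 0.0, "silenced"),
            (3.0, 4.0, "unchanged"),
            (0.0, 0.0, "unchanged"),
        ],
    )
    def test_classes(self, wt, sa, expected):
        cls, _fc = ch.classify_expression(self.attrs(wt, sa))
        assert cls == expected

    def test_partition_is_exhaustive_and_exclusive(self, small_transcripts):
        transcripts, attrs, _h = small_transcripts
        ids = [t.transcript_id for t in transcripts]
        df, induced = ch.expression_classes({"all": ids}, attrs)
        assert len(df) == len(ids)
        assert set(df["expr_class"]) <= {
            "activated", "up_regulated", "down_regulated", "silenced", "unchanged"
        }
        assert df["transcript_id"].is_unique

    def test_fold_change_defined_only_when_both_positive(self):
        df, _ = ch.expression_classes(
            {"c": ["a", "b"]},
            {"a": self.attrs(0.0, 5.0), "b": self.attrs(2.0, 5.0)},
        )
        by_id = df.set_index("transcript_id")
        assert np.isnan(by_id.loc["a", "fold_change"])
        assert by_id.loc["b", "fold_change"] == pytest.approx(2.5)

    def test_chi_square_hand_computed(self):
        # Pearson 2x2 without correction: [[10,0],[0,10]] -> 20.0
        stat, p = ch.induced_chi_square([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0)
        assert p < 0.001


class TestNearestGenes:
    def test_min_gap_chosen(self):
        genes = [gene("far", 2000, 2500, "-"), gene("near", 800, 900, "+")]
        df = ch.nearest_gene_targets([tx("l", 1000, 1300, "+")], genes)
        assert df.loc[0, "gene_id"] == "near"
        assert df.loc[0, "distance"] == 100
        assert df.loc[0, "orientation"] == "sense"

    def test_tie_prefers_sense(self):
        genes = [gene("anti", 1400, 1600, "-"), gene("sense", 700, 900, "+")]
        df = ch.nearest_gene_targets([tx("l", 1000, 1300, "+")], genes)
        assert df.loc[0, "gene_id"] == "sense"

    def test_brute_force_distance_oracle(self, small_study, small_transcripts):
        transcripts, _a, _h = small_transcripts
        by_id = {t.transcript_id: t for t in transcripts}
        lincs = [
            by_id[p.transcript_id]
            for p in small_study.planted
            if p.kind == "lincRNA"
        ]
        df = ch.nearest_gene_targets(lincs, small_study.genes).set_index(
            "transcript_id"
        )
        from saltlnc.core import gap_distance

        for t in lincs:
            cands = [
                gap_distance(t.span, g.span)
                for g in small_study.genes
                if g.span.chrom == t.chrom
            ]
            if not cands:
                assert t.transcript_id not in df.index
                continue
            assert df.loc[t.transcript_id, "distance"] == min(cands)

    def test_surviving_lincs_at_least_200_from_sense_targets(
        self, small_study, small_transcripts
    ):
        from saltlnc.classify import run_cascade

        transcripts, attrs, hits = small_transcripts
        res = run_cascade(
            transcripts, small_study.genes, attrs,
            small_study.hk_loci, small_study.mirna_loci, hits,
        )
        df = ch.nearest_gene_targets(res.lincRNAs, small_study.genes)
        sense = df[df["orientation"] == "sense"]
        assert (sense["distance"] >= 200).all()


class TestConservation:
    def test_presence_fractions(self):
        ids = {"lincRNA": ["a", "b"], "lncNAT": ["c"]}
        tables = {
            "wild_soybean": [("a", "s", 1e-20), ("b", "s", 1e-9), ("c", "s", 1e-8)],
            "common_bean": [("a", "s", 1e-3)],  # above threshold
        }
        matrix, fractions = ch.conservation_matrix(ids, tables)
        fx = fractions.set_index(["class", "genome"])["fraction_present"]
        assert fx[("lincRNA", "wild_soybean")] == 1.0
        assert fx[("lncNAT", "wild_soybean")] == 1.0
        assert fx[("lincRNA", "common_bean")] == 0.0
        assert matrix.loc["a", "wild_soybean"] and not matrix.loc["a", "common_bean"]

    def test_empty_hit_table_zero_presence(self):
        _m, fr = ch.conservation_matrix({"lincRNA": ["a"]}, {"g": []})
        assert fr["fraction_present"].iloc[0] == 0.0
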