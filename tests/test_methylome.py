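"""Context calling and RMC aggregation: oracles and invariants."""

import numpy as np
import pandas as pd
import pytest

from saltlnc import methylome as me
from saltlnc.core import CytosineSite, Gene, GenomicInterval
from saltlnc.simulate import SimulationConfig, simulate_genome, simulate_methylome
from tests.conftest import random_sequence

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def oracle_contexts(seq: str):
    """Independent per-position scan on both strands (no vectorization)."""
    out = []
    n = len(seq)
    for i, b in enumerate(seq):
        if b == "C":
            n1 = seq[i + 1] if i + 1 < n else None
            n2 = seq[i + 2] if i + 2 < n else None
            ctx = _ctx(n1, n2)
            if ctx:
                out.append((i, "+", ctx))
        if b == "G":
            n1 = COMP[seq[i - 1]] if i - 1 >= 0 else None
            n2 = COMP[seq[i - 2]] if i - 2 >= 0 else None
            ctx = _ctx(n1, n2)
            if ctx:
                out.append((i, "-", ctx))
    return sorted(out)


def _ctx(n1, n2):
    if n1 == "G":
        return "CpG"
    if n1 in ("A", "C", "T"):
        if n2 == "G":
            return "CHG"
        if n2 in ("A", "C", "T"):
            return "CHH"
    return None


def site(pos, strand="+", context="CpG", meth=0, unmeth=0, chrom="chr1"):
    return CytosineSite(chrom, pos, strand, context, meth, unmeth)


class TestCallContexts:
    def test_palindromic_cg(self):
        sites = me.call_contexts({"chr1": "ACGTAA"})
        cg = [(s.pos, s.strand) for s in sites if s.context == "CpG"]
        assert (1, "+") in cg and (2, "-") in cg

    def test_chg_plus_strand(self):
        sites = me.call_contexts({"chr1": "CAGTTT"})
        assert ("CHG", 0, "+") in {(s.context, s.pos, s.strand) for s in sites}

    def test_truncated_trinucleotide_skipped_unless_cpg(self):
        # final C has no following base: skipped; CG at end: CpG determinable
        sites = me.call_contexts({"chr1": "AAAC"})
        assert not [s for s in sites if s.strand == "+"]
        sites2 = me.call_contexts({"chr1": "AACG"})
        assert [(s.pos, s.context) for s in sites2 if s.strand == "+"] == [(2, "CpG")]

    @pytest.mark.parametrize("with_n", [False, True])
    def test_regex_oracle_equivalence(self, rng, with_n):
        for _ in range(10):
            seq = random_sequence(rng, 2_000, with_ambiguity=with_n)
            got = sorted(
                (s.pos, s.strand, s.context)
                for s in me.call_contexts({"chr1": seq})
            )
            assert got == oracle_contexts(seq)


class TestSiteState:
    @pytest.mark.parametrize(
        "meth, unmeth, min_cov, expected",
        [
            (3, 1, 4, "methylated"),
            (0, 10, 1, "unmethylated"),
            (1, 0, 4, "no_call"),
            (0, 0, 1, "no_call"),
        ],
    )
    def test_rules(self, meth, unmeth, min_cov, expected):
        assert me.call_site_state(site(0, meth=meth, unmeth=unmeth), min_cov) == expected


class TestRegionRmc:
    def test_three_of_four(self):
        sites = [site(p, meth=1 if p < 30 else 0, unmeth=0 if p < 30 else 1)
                 for p in (0, 10, 20, 30)]
        r = me.region_rmc(GenomicInterval("chr1", 0, 100), sites, "CpG")
        assert (r.n_sites, r.n_methylated, r.rmc) == (4, 3, 0.75)

    def test_empty_region_undefined(self):
        r = me.region_rmc(GenomicInterval("chr1", 0, 100), [], "CpG")
        assert r.n_sites == 0 and np.isnan(r.rmc)

    def test_brute_force_oracle_random(self, rng):
        for _ in range(25):
            sites = [
                site(
                    int(rng.integers(0, 500)),
                    strand=rng.choice(["+", "-"]),
                    context=rng.choice(["CpG", "CHG", "CHH"]),
                    meth=int(rng.integers(0, 4)),
                    unmeth=int(rng.integers(0, 4)),
                )
                for _ in range(int(rng.integers(5, 60)))
            ]
            lo = int(rng.integers(0, 400))
            hi = lo + int(rng.integers(10, 120))
            ctx = rng.choice(["CpG", "CHG", "CHH"])
            min_cov = int(rng.integers(1, 4))
            r = me.region_rmc(GenomicInterval("chr1", lo, hi), sites, ctx, min_cov)
            # enumeration oracle
            called = [
                s for s in sites
                if lo <= s.pos < hi and s.context == ctx and s.coverage >= min_cov
            ]
            n_meth = sum(1 for s in called if s.meth_reads >= 1)
            assert (r.n_sites, r.n_methylated) == (len(called), n_meth)

    def test_additive_over_partition(self, rng):
        sites = [site(int(p), meth=int(m), unmeth=1)
                 for p, m in zip(rng.integers(0, 300, 80), rng.integers(0, 2, 80))]
        whole = me.region_rmc(GenomicInterval("chr1", 0, 300), sites, "CpG")
        parts = [
            me.region_rmc(GenomicInterval("chr1", a, b), sites, "CpG")
            for a, b in ((0, 100), (100, 200), (200, 300))
        ]
        assert sum(p.n_sites for p in parts) == whole.n_sites
        assert sum(p.n_methylated for p in parts) == whole.n_methylated

    def test_min_cov_monotonicity(self, rng):
        sites = [
            site(int(p), meth=int(rng.integers(0, 3)), unmeth=int(rng.integers(0, 3)))
            for p in rng.integers(0, 200, 50)
        ]
        region = GenomicInterval("chr1", 0, 200)
        n_prev = None
        for min_cov in (1, 2, 3, 4, 5):
            n = me.region_rmc(region, sites, "CpG", min_cov).n_sites
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n


class TestPromoter:
    def test_plus_strand(self):
        g = Gene("g", GenomicInterval("chr1", 5000, 8000, "+"))
        assert me.promoter_interval(g) == GenomicInterval("chr1", 4000, 5000, "+")

    def test_minus_strand_upstream_after_end(self):
        g = Gene("g", GenomicInterval("chr1", 5000, 8000, "-"))
        assert me.promoter_interval(g) == GenomicInterval("chr1", 8000, 9000, "-")

    def test_clipped_at_chrom_start(self):
        g = Gene("g", GenomicInterval("chr1", 300, 900, "+"))
        assert me.promoter_interval(g) == GenomicInterval("chr1", 0, 300, "+")

    def test_minus_clipped_at_chrom_end(self):
        g = Gene("g", GenomicInterval("chr1", 300, 900, "-"))
        p = me.promoter_interval(g, chrom_length=1100)
        assert p == GenomicInterval("chr1", 900, 1100, "-")


class TestGenePromoterRmc:
    def test_six_records_per_gene(self):
        g = Gene("g", GenomicInterval("chr1", 2000, 3000, "+"))
        df = me.gene_promoter_rmc([g], [site(2500, meth=2)])
        assert len(df) == 6
        assert set(df["region"]) == {"gene", "promoter"}
        row = df[(df.region == "gene") & (df.context == "CpG")].iloc[0]
        assert row["rmc"] == 1.0

    def test_promoter_sites_counted(self):
        g = Gene("g", GenomicInterval("chr1", 2000, 3000, "+"))
        df = me.gene_promoter_rmc([g], [site(1500, meth=0, unmeth=3)])
        row = df[(df.region == "promoter") & (df.context == "CpG")].iloc[0]
        assert (row["n_sites"], row["rmc"]) == (1, 0.0)


class TestNeverMethylated:
    def test_fractions(self):
        rows = []
        for gid, m in (("a", 0), ("b", 2), ("c", 0)):
            for ctx in ("CpG", "CHG", "CHH"):
                rows.append(
                    {"gene_id": gid, "region": "gene", "context": ctx,
                     "n_sites": 4, "n_methylated": m if ctx != "CHH" else 9}
                )
        df = pd.DataFrame(rows)
        frac = me.never_methylated_fraction(
            df, {"a": "lincRNA", "b": "lincRNA", "c": "mRNA"}
        )
        # CHH methylation is ignored for the never-methylated rule
        assert frac == {"lincRNA": 0.5, "mRNA": 1.0}

    def test_zero_rate_simulation_all_never(self, small_study):
        cfg = SimulationConfig(seed=2, meth_rate_cpg=0.0, meth_rate_chg=0.0,
                               meth_rate_chh=0.0)
        genome = {"chr1": small_study.genome["chr1"][:20_000]}
        sites = simulate_methylome(cfg, genome, "wt")
        genes = [g for g in small_study.genes
                 if g.span.chrom == "chr1" and g.span.end < 20_000]
        df = me.gene_promoter_rmc(genes, me.as_site_frame(sites))
        frac = me.never_methylated_fraction(
            df, {g.gene_id: "mRNA" for g in genes}
        )
        assert frac == {"mRNA": 1.0}


class TestWindowRmc:
    def test_uniform_rate_one(self, small_study):
        cfg = SimulationConfig(seed=2, meth_rate_cpg=1.0, meth_rate_chg=1.0,
                               meth_rate_chh=1.0)
        genome = {"chr1": small_study.genome["chr1"][:10_000]}
        sites = simulate_methylome(cfg, genome, "wt")
        df = me.chrom_window_rmc(me.as_site_frame(sites), {"chr1": 10_000}, 2_000)
        defined = df[df["n_sites"] > 0]
        assert (defined["rmc"] == 1.0).all()

    def test_site_count_conservation(self, small_study):
        cfg = SimulationConfig(seed=2)
        genome = {"chr1": small_study.genome["chr1"][:10_000]}
        frame = me.as_site_frame(simulate_methylome(cfg, genome, "wt"))
        df = me.chrom_window_rmc(frame, {"chr1": 10_000}, 1_500)
        called = frame[(frame["meth"] + frame["unmeth"]) >= 1]
        assert df["n_sites"].sum() == len(called)

    def test_planted_gradient_recovered(self):
        # plant a linear CpG methylation gradient along the chromosome and
        # check the window profile is monotone toward the peak
        rng = np.random.default_rng(5)
        sites = []
        L = 50_000
        for pos in range(0, L, 25):
            p = pos / L  # rate rises toward the right end
            m = rng.random() < p
            sites.append(site(pos, meth=3 if m else 0, unmeth=0 if m else 3))
        df = me.chrom_window_rmc(me.as_site_frame(sites), {"chr1": L}, 10_000)
        prof = df[(df.context == "CpG") & (df.n_sites > 0)].sort_values("window")
        assert prof["rmc"].is_monotonic_increasing


class TestMetagene:
    def test_uniform_rate_flat_within_three_se(self, rng):
        genes = [
            Gene(f"g{i}", GenomicInterval("chr1", 3000 + i * 5000,
                                          3000 + i * 5000 + 3000, "+"))
            for i in range(8)
        ]
        rate = 0.5
        sites = []
        for p in range(0, 45_000, 3):
            m = rng.random() < rate
            sites.append(site(p, meth=3 if m else 0, unmeth=0 if m else 3))
        prof = me.metagene_profile(genes, me.as_site_frame(sites),
                                   n_body_bins=10, n_up_bins=5)
        cpg = prof[(prof.context == "CpG") & (prof.n_genes > 0)]
        # per-bin SE of a mean of per-gene binomial proportions
        sites_per_gene_bin = 3000 / 10 / 3
        se = np.sqrt(rate * (1 - rate) / sites_per_gene_bin / len(genes))
        assert (np.abs(cpg["mean_rmc"] - rate) < 3 * se).all()

    def test_minus_strand_reverses_bin_order(self):
        # methylated only in the genomic-left half of the gene
        gene_plus = Gene("gp", GenomicInterval("chr1", 1000, 2000, "+"))
        gene_minus = Gene("gm", GenomicInterval("chr1", 1000, 2000, "-"))
        sites = [site(p, meth=3 if p < 1500 else 0, unmeth=0 if p < 1500 else 3)
                 for p in range(1000, 2000, 10)]
        frame = me.as_site_frame(sites)
        prof_p = me.metagene_profile([gene_plus], frame, n_body_bins=4, n_up_bins=0)
        prof_m = me.metagene_profile([gene_minus], frame, n_body_bins=4, n_up_bins=0)
        p_vals = prof_p[prof_p.context == "CpG"]["mean_rmc"].to_numpy()
        m_vals = prof_m[prof_m.context == "CpG"]["mean_rmc"].to_numpy()
        assert np.allclose(p_vals, m_vals[::-1], equal_nan=True)
        assert p_vals[0] == 1.0 and p_vals[-1] == 0.0

    def test_zero_sites_all_bins_undefined(self):
        g = Gene("g", GenomicInterval("chr1", 1000, 2000, "+"))
        prof = me.metagene_profile([g], [], n_body_bins=5, n_up_bins=2)
        assert prof["mean_rmc"].isna().all()

    def test_short_gene_not_skipped(self):
        # gene shorter than the bin count still contributes its sites
        g = Gene("g", GenomicInterval("chr1", 100, 130, "+"))
        sites = [site(p, meth=3) for p in range(100, 130, 3)]
        prof = me.metagene_profile([g], me.as_site_frame(sites),
                                   n_body_bins=60, n_up_bins=0)
        assert prof["n_genes"].sum() > 0
        assert prof[prof.n_genes > 0]["mean_rmc"].eq(1.0).all()

    def test_upstream_bins_cover_promoter(self):
        g = Gene("g", GenomicInterval("chr1", 2000, 3000, "+"))
        sites = [site(1990, meth=3), site(1001, meth=0, unmeth=3)]
        prof = me.metagene_profile([g], me.as_site_frame(sites),
                                   n_body_bins=4, n_up_bins=20, upstream_bp=1000)
        cpg = prof[(prof.context == "CpG") & (prof.n_genes > 0)]
        # site at 1990 (10 bp upstream) -> last upstream bin (19);
        # site at 1001 (999 bp upstream) -> first upstream bin (0)
        assert set(cpg["bin"]) == {0, 19}
        assert cpg.set_index("bin").loc[19, "mean_rmc"] == 1.0
        assert cpg.set_index("bin").loc[0, "mean_rmc"] == 0.0


class TestConditionRatio:
    def frame(self, vals):
        return pd.DataFrame(
            [
                {"gene_id": g, "region": "gene", "context": "CpG",
                 "n_sites": 4, "n_methylated": 2, "rmc": v}
                for g, v in vals.items()
            ]
        )

    def test_ratio(self):
        out = me.condition_ratio(self.frame({"a": 0.5}), self.frame({"a": 0.25}))
        assert out.loc[0, "ratio"] == pytest.approx(0.5)
        assert not out.loc[0, "flagged"]

    def test_zero_control_flagged(self):
        out = me.condition_ratio(self.frame({"a": 0.0}), self.frame({"a": 0.3}))
        assert np.isnan(out.loc[0, "ratio"]) and out.loc[0, "flagged"]

    def test_identical_inputs_ratio_one(self):
        f = self.frame({"a": 0.4, "b": 0.9})
        out = me.condition_ratio(f, f)
        assert (out["ratio"] == 1.0).all()


class TestHComposition:
    def test_all_cag(self):
        seq = "CAG" * 20
        sites = [s for s in me.call_contexts({"chr1": seq}) if s.strand == "+"]
        chg = [s for s in sites if s.context == "CHG"]
        assert chg
        df = me.h_base_composition(chg, {"chr1": seq})
        chg_freq = df[df.context == "CHG"].set_index("base")["frequency"]
        assert chg_freq["A"] == 1.0

    def test_frequencies_sum_to_one(self, rng):
        seq = random_sequence(rng, 3_000)
        sites = me.call_contexts({"chr1": seq})
        df = me.h_base_composition(sites, {"chr1": seq})
        for ctx in ("CHG", "CHH"):
            total = df[df.context == ctx]["frequency"].sum()
            assert total == pytest.approx(1.0)

    def test_matches_direct_trinucleotide_scan(self, rng):
        seq = random_sequence(rng, 2_000)
        sites = me.call_contexts({"chr1": seq})
        df = me.h_base_composition(sites, {"chr1": seq})
        # oracle: recount H bases from the oracle context scan
        counts = {("CHG", b): 0 for b in "ATC"}
        counts.update({("CHH", b): 0 for b in "ATC"})
        for pos, strand, ctx in oracle_contexts(seq):
            if ctx == "CpG":
                continue
            if strand == "+":
                tri = seq[pos : pos + 3]
            else:
                tri = "".join(COMP[b] for b in seq[pos - 2 : pos + 1][::-1])
            for i in [1] if ctx == "CHG" else [1, 2]:
                counts[(ctx, tri[i])] += 1
        for ctx in ("CHG", "CHH"):
            total = sum(counts[(ctx, b)] for b in "ATC")
            for b in "ATC":
                got = df[(df.context == ctx) & (df.base == b)]["frequency"].iloc[0]
                assert got == pytest.approx(counts[(ctx, b)] / total)

    def test_g_at_h_position_is_an_error(self):
        bad = [site(0, context="CHG")]
        with pytest.raises(ValueError, match="H position"):
            me.h_base_composition(bad, {"chr1": "CGGTTT"})


class TestRateRecovery:
    def test_planted_rates_recovered_across_seeds(self):
        base = simulate_genome(
            SimulationConfig(seed=4, n_chroms=1, chrom_length=30_000,
                             n_coding_genes=4, n_lincRNAs=3, n_lncNATs=2)
        ).genome
        for seed in range(5):
            cfg = SimulationConfig(seed=seed)
            frame = me.as_site_frame(simulate_methylome(cfg, base, "wt"))
            frac = me.genome_wide_methylated_fraction(frame)
            for ctx, rate in cfg.meth_rates.items():
                n = (frame["context"] == ctx).sum()
                sd = np.sqrt(rate * (1 - rate) / n)
                assert abs(frac[ctx] - rate) < 3 * sd, (seed, ctx)
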