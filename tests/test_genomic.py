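"""Peak resizing, co-binding components, exclusivity, gene assignment, features."""

import numpy as np
import pandas as pd
import pytest

import bioidflow as bf
from bioidflow.errors import DataError

from conftest import peakset_from_tuples, random_intervals
from oracles import brute_cobind_counts, brute_shared_loci


def genes_from_rows(rows):
    return bf.GeneModels(
        pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    )


class TestResize:
    def test_midpoint_window(self):
        out = bf.resize_to_window(peakset_from_tuples([("chr1", 10_000, 10_200)]), 1000)
        assert out.intervals.loc[0, ["start", "end"]].tolist() == [9_600, 10_600]

    def test_left_clipping(self):
        out = bf.resize_to_window(peakset_from_tuples([("chr1", 100, 300)]), 1000)
        assert out.intervals.loc[0, ["start", "end"]].tolist() == [0, 700]

    def test_idempotent_on_centred_windows(self):
        peaks = peakset_from_tuples([("chr1", 9_600, 10_600), ("chr2", 0, 1_000)])
        once = bf.resize_to_window(peaks, 1000)
        twice = bf.resize_to_window(once, 1000)
        assert once.intervals.equals(twice.intervals)

    def test_odd_window_rejected(self):
        with pytest.raises(bf.ConfigError):
            bf.resize_to_window(peakset_from_tuples([("chr1", 0, 10)]), 999)


class TestCobind:
    def test_identical_single_peak(self):
        a = peakset_from_tuples([("chr1", 5_000, 5_200)], "A")
        b = peakset_from_tuples([("chr1", 5_000, 5_200)], "B")
        res = bf.cobind(a, b)
        assert (res.n_cobound, res.n_a_only, res.n_b_only) == (1, 0, 0)

    def test_distant_peaks_never_cobind(self):
        a = peakset_from_tuples([("chr1", 0, 200), ("chr1", 10_000, 10_200)], "A")
        b = peakset_from_tuples([("chr1", 4_000, 4_200), ("chr1", 20_000, 20_200)], "B")
        res = bf.cobind(a, b)
        assert res.n_cobound == 0
        assert res.n_a_only == 2
        assert res.n_b_only == 2

    def test_no_shared_chromosomes_warns_and_is_empty(self):
        a = peakset_from_tuples([("chr1", 0, 200)], "A")
        b = peakset_from_tuples([("chrX", 0, 200)], "B")
        with pytest.warns(UserWarning, match="no chromosome"):
            res = bf.cobind(a, b)
        assert len(res.loci) == 0

    def test_matches_brute_force_union_find(self):
        rng = np.random.default_rng(99)
        for trial in range(40):
            n_a, n_b = rng.integers(1, 100, size=2)
            ia = random_intervals(rng, int(n_a))
            ib = random_intervals(rng, int(n_b))
            res = bf.cobind(peakset_from_tuples(ia, "A"), peakset_from_tuples(ib, "B"))
            expected = brute_cobind_counts(ia, ib, 1000)
            assert (res.n_cobound, res.n_a_only, res.n_b_only) == expected

    def test_symmetric_in_cobound_count(self):
        rng = np.random.default_rng(5)
        ia = random_intervals(rng, 60)
        ib = random_intervals(rng, 80)
        a, b = peakset_from_tuples(ia, "A"), peakset_from_tuples(ib, "B")
        fwd, rev = bf.cobind(a, b), bf.cobind(b, a)
        assert fwd.n_cobound == rev.n_cobound
        assert fwd.n_a_only == rev.n_b_only

    def test_every_cobound_locus_has_both_contributors(self):
        rng = np.random.default_rng(2)
        a = peakset_from_tuples(random_intervals(rng, 120), "A")
        b = peakset_from_tuples(random_intervals(rng, 120), "B")
        res = bf.cobind(a, b)
        co = res.cobound
        assert ((co["n_a"] >= 1) & (co["n_b"] >= 1)).all()
        assert res.n_cobound + res.n_a_only == int((res.loci["n_a"] > 0).sum())


class TestSignatureExclusivity:
    def make(self, intervals_a, intervals_b):
        return bf.cobind(
            peakset_from_tuples(intervals_a, "A"), peakset_from_tuples(intervals_b, "B")
        )

    def test_identical_results_zero_exclusive(self):
        rng = np.random.default_rng(31)
        ia, ib = random_intervals(rng, 60), random_intervals(rng, 60)
        res = self.make(ia, ib)
        n_shared, e1, e2 = bf.signature_exclusivity(res, res)
        assert e1 == e2 == 0
        assert n_shared == res.n_cobound

    def test_disjoint_results_fully_exclusive(self):
        r1 = self.make([("chr1", 1_000, 1_200)], [("chr1", 1_100, 1_300)])
        r2 = self.make([("chr1", 50_000, 50_200)], [("chr1", 50_100, 50_300)])
        assert bf.signature_exclusivity(r1, r2) == (0, 100, 100)

    def test_shared_count_matches_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            r1 = self.make(random_intervals(rng, 50), random_intervals(rng, 50))
            r2 = self.make(random_intervals(rng, 50), random_intervals(rng, 50))
            n_shared, e1, e2 = bf.signature_exclusivity(r1, r2)
            loci1 = [(t.chrom, t.start, t.end) for t in r1.cobound.itertuples()]
            loci2 = [(t.chrom, t.start, t.end) for t in r2.cobound.itertuples()]
            bn, bs1, bs2 = brute_shared_loci(loci1, loci2)
            assert n_shared == bn
            if loci1:
                assert e1 == round(100 * (1 - bs1 / len(loci1)))
            if loci2:
                assert e2 == round(100 * (1 - bs2 / len(loci2)))


class TestFeatureClassification:
    @pytest.fixture
    def toy_genes(self):
        return genes_from_rows(
            [
                ("g_plus", "chr1", "+", 10_000, 15_000),  # promoter [8000, 10000)
                ("g_minus", "chr1", "-", 30_000, 34_000),  # promoter (33999, 35999]
            ]
        )

    def test_region_inside_plus_strand_promoter(self, toy_genes):
        assert bf.classify_feature(("chr1", 8_500, 9_000), toy_genes) == "promoter"

    def test_minus_strand_promoter_is_downstream_of_end(self, toy_genes):
        assert bf.classify_feature(("chr1", 34_500, 34_600), toy_genes) == "promoter"
        assert bf.classify_feature(("chr1", 36_500, 36_600), toy_genes) == "intergenic"

    def test_gene_body(self, toy_genes):
        assert bf.classify_feature(("chr1", 12_000, 12_100), toy_genes) == "gene_body"

    def test_isolated_region_is_intergenic(self, toy_genes):
        assert bf.classify_feature(("chr1", 500_000, 500_100), toy_genes) == "intergenic"

    def test_promoter_takes_precedence_over_gene_body(self):
        genes = genes_from_rows(
            [
                ("g1", "chr1", "+", 10_000, 15_000),
                ("g2", "chr1", "+", 4_000, 9_000),  # body overlaps g1's promoter window
            ]
        )
        # region overlaps g1 promoter [8000,10000) and g2 gene body
        assert bf.classify_feature(("chr1", 8_500, 8_700), genes) == "promoter"

    def test_exhaustive_labelling_on_toy_genome(self):
        """Sliding windows vs a direct per-position rule on a 2-gene toy genome."""
        genes = genes_from_rows(
            [("gp", "chr1", "+", 6_000, 9_000), ("gm", "chr1", "-", 14_000, 16_000)]
        )
        promoter = set(range(4_000, 6_000)) | set(range(16_000, 18_000))
        body = set(range(6_000, 9_000)) | set(range(14_000, 16_000))
        regions = [("chr1", s, s + 150) for s in range(0, 20_000, 137)]
        labels = bf.classify_features(regions, genes)
        for (chrom, s, e), label in zip(regions, labels):
            span = set(range(s, e))
            expect = (
                "promoter" if span & promoter
                else "gene_body" if span & body
                else "intergenic"
            )
            assert label == expect, (s, e)


class TestAssignGenes:
    def test_region_inside_single_gene_body(self):
        genes = genes_from_rows([("g1", "chr1", "+", 1_000, 5_000)])
        assert bf.assign_genes([("chr1", 2_000, 2_200)], genes) == [frozenset({"g1"})]

    def test_equidistant_tss_tie_keeps_both(self):
        genes = genes_from_rows(
            [("left", "chr1", "-", 5_000, 10_000), ("right", "chr1", "+", 20_000, 25_000)]
        )
        # TSS(left) = 9999, TSS(right) = 20000; region end-1 at 14999, start 14000
        # distances: 14000-9999 = 4001 ; 20000-14999 = 5001 -> pick nearer only
        out = bf.assign_genes([("chr1", 14_000, 15_000)], genes, max_distance=6_000)
        assert out == [frozenset({"left"})]
        # symmetric placement produces a tie: 14500-9999 = 4501 = 20000-15499
        out = bf.assign_genes([("chr1", 14_500, 15_500)], genes, max_distance=6_000)
        assert out == [frozenset({"left", "right"})]

    def test_beyond_max_distance_unassigned(self):
        genes = genes_from_rows([("g1", "chr1", "+", 1_000, 2_000)])
        assert bf.assign_genes([("chr1", 50_000, 50_100)], genes) == [frozenset()]

    def test_matches_exhaustive_assignment_on_toy_genome(self):
        rng = np.random.default_rng(77)
        cfg = bf.GenomeSimConfig(genome_length=400_000, n_genes=20, n_peaks_a=10,
                                 n_peaks_b=10, seed=13)
        genes, _, _, _ = bf.generate_genome_fixture(cfg)
        regions = [("chrSim", int(s), int(s) + 800) for s in rng.integers(0, 399_000, 60)]
        got = bf.assign_genes(regions, genes, promoter_upstream=2_000, max_distance=5_000)
        for (chrom, start, end), assigned in zip(regions, got):
            hits = set()
            for g in genes.genes.itertuples():
                if g.strand == "+":
                    ps, pe = max(0, g.tss - 2_000), g.tss
                else:
                    ps, pe = g.tss + 1, g.tss + 2_001
                if (ps < end and start < pe) or (g.start < end and start < g.end):
                    hits.add(g.gene_id)
            if not hits:
                dists = {}
                for g in genes.genes.itertuples():
                    if start <= g.tss < end:
                        d = 0
                    elif g.tss < start:
                        d = start - g.tss
                    else:
                        d = g.tss - (end - 1)
                    dists[g.gene_id] = d
                dmin = min(dists.values())
                if dmin <= 5_000:
                    hits = {g for g, d in dists.items() if d == dmin}
            assert assigned == hits, (start, end)


class TestExpressionOverlay:
    def test_saturation(self):
        ov = bf.expression_overlay({"a", "b"}, {"a", "b", "c"})
        assert ov.fraction_expressed == 1.0

    def test_genes_outside_universe_are_inactive(self):
        ov = bf.expression_overlay({"a", "b", "z"}, {"a"})
        assert (ov.n_expressed, ov.n_inactive) == (1, 2)

    def test_empty_gene_list_raises(self):
        with pytest.raises(DataError):
            bf.expression_overlay(set(), {"a"})

    def test_recovers_planted_expressed_fraction(self):
        """Unbiased peak placement: assigned genes expressed at the planted rate."""
        fracs, ns = [], []
        for seed in range(6):
            cfg = bf.GenomeSimConfig(fraction_expressed=0.8, seed=seed)
            genes, a, b, expressed = bf.generate_genome_fixture(cfg)
            res = bf.cobind(a, b, window=cfg.window)
            regions = [(t.chrom, t.start, t.end) for t in res.cobound.itertuples()]
            assigned = set().union(*bf.assign_genes(regions, genes))
            ov = bf.expression_overlay(assigned, expressed)
            fracs.append(ov.fraction_expressed)
            ns.append(len(assigned))
        pooled_n = sum(ns)
        pooled = sum(f * n for f, n in zip(fracs, ns)) / pooled_n
        se = np.sqrt(0.8 * 0.2 / pooled_n)
        assert abs(pooled - 0.8) <= 3 * se


def test_cobound_bed_export(tmp_path):
    cfg = bf.GenomeSimConfig(seed=3)
    genes, a, b, _ = bf.generate_genome_fixture(cfg)
    res = bf.cobind(a, b, window=cfg.window)
    regions = [(t.chrom, t.start, t.end) for t in res.cobound.itertuples()]
    gene_map = dict(enumerate(bf.assign_genes(regions, genes)))
    out = tmp_path / "cobound.bed"
    res.cobound_bed(out, gene_map)
    back = pd.read_csv(out, sep="\t", header=None,
                       names=["chrom", "start", "end", "name", "score"])
    assert len(back) == res.n_cobound
    assert (back["score"] >= 2).all()  # at least one contributor per side
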