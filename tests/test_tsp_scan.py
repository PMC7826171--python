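"""Cosmopolitan/TSP calling, annotation, thinning, and enrichment."""

import numpy as np
import pytest
from scipy import stats as sps

from balscan.formats_io import GeneModel, ReferenceSeq, SiteCounts
from balscan.poolseq_stats import StatFilters
from balscan.tsp_scan import (
    GenomeAnnotation,
    TspRecord,
    call_cosmopolitan,
    call_tsp,
    classify_ns_s,
    enrichment_test,
    filter_by_he,
    scan_sites,
    thin_by_distance,
)

FILTERS = StatFilters(min_coverage=10, max_coverage=10**6)


def _site(freqs, cov=100, pos=10):
    counts = []
    for f in freqs:
        t = int(round(cov * f))
        counts.append([cov - t, t, 0, 0, 0, 0])
    pops = tuple(f"p{i}" for i in range(len(freqs)))
    return SiteCounts("chr1", pos, "A", np.array(counts), pops)


class TestCosmopolitan:
    def test_segregating_everywhere(self):
        ok, ref, alt, freqs = call_cosmopolitan(_site([0.3, 0.4, 0.5]), 0.05, FILTERS)
        assert ok and (ref, alt) == ("A", "T")
        assert freqs == pytest.approx({"p0": 0.3, "p1": 0.4, "p2": 0.5})

    def test_one_population_below_threshold(self):
        ok, *_ = call_cosmopolitan(_site([0.3, 0.4, 0.02]), 0.05, FILTERS)
        assert not ok

    def test_fixed_in_one_population(self):
        ok, *_ = call_cosmopolitan(_site([0.3, 0.4, 1.0]), 0.05, FILTERS)
        assert not ok

    def test_coverage_failure_is_missing_data(self):
        site = _site([0.3, 0.4])
        site.counts[1] = [3, 2, 0, 0, 0, 0]
        ok, *_ = call_cosmopolitan(site, 0.05, FILTERS)
        assert not ok

    def test_triallelic_excluded(self):
        site = SiteCounts("chr1", 5, "A",
                          np.array([[40, 30, 30, 0, 0, 0]]), ("p0",))
        ok, ref, alt, _ = call_cosmopolitan(site, 0.05, FILTERS)
        assert not ok and ref is None


class TestTspCall:
    def _cosmo(self):
        site = _site([0.3, 0.4])
        return site, "A", "T", {"p0": 0.3, "p1": 0.4}

    def test_outgroup_het_is_tsp(self):
        rec = call_tsp(*self._cosmo(), outgroup_alleles=("A", "T"))
        assert rec.is_tsp and rec.outgroup_state == "both_alleles"

    def test_outgroup_hom_ref_not_tsp(self):
        rec = call_tsp(*self._cosmo(), outgroup_alleles=("A", "A"))
        assert not rec.is_tsp and rec.outgroup_state == "ref_only"

    def test_outgroup_absent_flagged_missing(self):
        rec = call_tsp(*self._cosmo(), outgroup_alleles=None)
        assert not rec.is_tsp and rec.outgroup_state == "missing"

    def test_outgroup_other_allele(self):
        rec = call_tsp(*self._cosmo(), outgroup_alleles=("C", "C"))
        assert rec.outgroup_state == "missing"


class TestThinning:
    def test_greedy_rule(self):
        sites = [("c", 100), ("c", 300), ("c", 700)]
        assert thin_by_distance(sites, 500) == [("c", 100), ("c", 700)]

    def test_single_site_kept(self):
        assert thin_by_distance([("c", 5)], 500) == [("c", 5)]

    def test_boundary_distance_kept(self):
        # distance exactly min_dist satisfies the >= rule
        assert thin_by_distance([("c", 100), ("c", 600)], 500) == [("c", 100), ("c", 600)]

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError, match="not sorted"):
            thin_by_distance([("c", 600), ("c", 100)], 500)

    def test_contigs_independent(self):
        sites = [("a", 100), ("a", 200), ("b", 150)]
        assert thin_by_distance(sites, 500) == [("a", 100), ("b", 150)]


@pytest.fixture()
def annotation():
    # + strand gene: exons 100-400 and 600-900 (1-based), CDS within both
    plus = GeneModel("gA", "gA.t1", "chr1", "+",
                     exons=[(99, 400), (599, 900)],
                     cds=[(149, 400), (599, 850)], cds_phase=[0, 1])
    # - strand gene downstream; promoter extends to the right of its TSS
    minus = GeneModel("gB", "gB.t1", "chr1", "-",
                      exons=[(1999, 2300)], cds=[(1999, 2300)], cds_phase=[0])
    return GenomeAnnotation({"gA": plus, "gB": minus}, promoter_bp=1000)


class TestGenomicClass:
    @pytest.mark.parametrize("pos,expected", [
        (200, "coding"),       # inside CDS
        (120, "utr5"),         # exon before CDS on + strand
        (880, "utr3"),         # exon after CDS
        (450, "intron"),       # between the exons
        (50, "promoter"),      # < 1 kb upstream of + strand TSS
        (2500, "promoter"),    # upstream of - strand TSS (to the right)
        (1500, "intergenic"),
    ])
    def test_priority_assignment(self, annotation, pos, expected):
        cls, _ = annotation.assign("chr1", pos)
        assert cls == expected

    def test_intron_beats_promoter_of_other_gene(self):
        a = GeneModel("gA", "gA.t1", "c", "+", exons=[(0, 100), (900, 1000)],
                      cds=[(0, 100), (900, 1000)], cds_phase=[0, 0])
        b = GeneModel("gB", "gB.t1", "c", "+", exons=[(1499, 1600)],
                      cds=[(1499, 1600)], cds_phase=[0])
        ann = GenomeAnnotation({"gA": a, "gB": b}, promoter_bp=1000)
        cls, gene = ann.assign("c", 600)  # in gA's intron and gB's promoter
        assert cls == "intron" and gene == "gA"

    def test_every_site_gets_exactly_one_class(self, annotation):
        for pos in range(1, 3000, 7):
            cls, _ = annotation.assign("chr1", pos)
            assert cls in {"coding", "utr5", "utr3", "intron", "promoter", "intergenic"}


class TestNsS:
    def _ref(self, seq):
        return ReferenceSeq("chr1", seq)

    def test_synonymous_third_position(self):
        # codon GAT -> GAC, both Asp
        ref = self._ref("GAT" * 10)
        m = GeneModel("g", "g.t", "chr1", "+", exons=[(0, 30)], cds=[(0, 30)], cds_phase=[0])
        assert classify_ns_s("chr1", 3, "T", "C", m, ref) == "S"

    def test_nonsynonymous_first_position(self):
        # GAT (Asp) -> CAT (His)
        ref = self._ref("GAT" * 10)
        m = GeneModel("g", "g.t", "chr1", "+", exons=[(0, 30)], cds=[(0, 30)], cds_phase=[0])
        assert classify_ns_s("chr1", 1, "G", "C", m, ref) == "NS"

    def test_minus_strand_classified_on_coding_strand(self):
        # genomic ...ATC... on - strand reads GAT; genomic C->T at the codon's
        # first coding position is G->A on the coding strand: GAT->AAT, Asp->Asn
        genomic = "ATC" * 10
        ref = self._ref(genomic)
        m = GeneModel("g", "g.t", "chr1", "-", exons=[(0, 30)], cds=[(0, 30)], cds_phase=[0])
        assert classify_ns_s("chr1", 30, "C", "T", m, ref) == "NS"
        # and a substitution that is synonymous on the coding strand
        # GAT->GAC: coding T->C at codon pos 3 = genomic A->G at position 28
        assert classify_ns_s("chr1", 28, "A", "G", m, ref) == "S"

    def test_codon_with_n_missing(self):
        ref = self._ref("GAN" + "GAT" * 9)
        m = GeneModel("g", "g.t", "chr1", "+", exons=[(0, 30)], cds=[(0, 30)], cds_phase=[0])
        assert classify_ns_s("chr1", 1, "G", "C", m, ref) is None

    def test_frame_broken_model_unusable(self):
        ref = self._ref("GATGATGATG")
        m = GeneModel("g", "g.t", "chr1", "+", exons=[(0, 10)], cds=[(0, 10)], cds_phase=[0])
        assert classify_ns_s("chr1", 1, "G", "C", m, ref) is None


class TestEnrichment:
    def _records(self, a, b, c, d):
        recs = []
        key = 0
        for n, cls, tsp in ((a, "coding", True), (b, "intergenic", True),
                            (c, "coding", False), (d, "intergenic", False)):
            for _ in range(n):
                key += 1
                r = TspRecord("c", key, "A", "T", {"p": 0.3}, tsp,
                              "both_alleles" if tsp else "missing")
                r.genomic_class = cls
                recs.append(r)
        tsps = [r for r in recs if r.is_tsp]
        return tsps, recs

    def test_worked_odds_ratio(self):
        tsps, recs = self._records(30, 70, 70, 830)
        res = {e.genomic_class: e for e in enrichment_test(tsps, recs)}
        assert res["coding"].odds_ratio == pytest.approx(5.0816, abs=1e-4)
        assert (res["coding"].a, res["coding"].b) == (30, 70)

    def test_margins_match_totals(self):
        tsps, recs = self._records(30, 70, 70, 830)
        for e in enrichment_test(tsps, recs):
            assert e.a + e.b == len(tsps)
            assert e.a + e.b + e.c + e.d == len(recs)

    def test_no_enrichment_gives_unit_odds(self):
        tsps, recs = self._records(10, 90, 10, 90)
        res = {e.genomic_class: e for e in enrichment_test(tsps, recs)}
        assert res["coding"].odds_ratio == pytest.approx(1.0)
        assert res["coding"].p_value == pytest.approx(1.0)

    def test_exact_p_matches_hypergeometric_oracle(self):
        """Two-sided Fisher p for (30,70,70,830) equals the sum of
        hypergeometric point probabilities <= the observed table's."""
        tsps, recs = self._records(30, 70, 70, 830)
        res = {e.genomic_class: e for e in enrichment_test(tsps, recs)}
        # margins: 100 TSPs, 100 coding sites, 1000 SNPs
        pmf = sps.hypergeom(1000, 100, 100).pmf(np.arange(0, 101))
        p_obs = pmf[30]
        oracle = pmf[pmf <= p_obs * (1 + 1e-12)].sum()
        assert res["coding"].p_value == pytest.approx(oracle, abs=1e-10)

    def test_bonferroni_across_classes(self):
        tsps, recs = self._records(30, 70, 70, 830)
        out = enrichment_test(tsps, recs)
        for e in out:
            assert e.adjusted_p == pytest.approx(min(1.0, e.p_value * len(out)))


class TestHeFilter:
    def _tsp(self, freqs):
        r = TspRecord("c", 1, "A", "T", {f"p{i}": f for i, f in enumerate(freqs)},
                      True, "both_alleles")
        r.he = {p: 2 * f * (1 - f) for p, f in r.alt_freq.items()}
        return r

    def test_high_he_kept(self):
        assert filter_by_he([self._tsp([0.5, 0.5, 0.5])], 0.30)

    def test_one_low_population_drops(self):
        assert filter_by_he([self._tsp([0.5, 0.5, 0.1])], 0.30) == []

    def test_boundary_strict_inequality(self):
        assert filter_by_he([self._tsp([0.18377, 0.5])], 0.30) == []


class TestScanOnSimulation:
    def test_pure_neutral_divergence_yields_zero_tsps(self):
        """Infinite-sites neutral simulation with a deep species split:
        no trans-species polymorphism (no homoplasy by construction)."""
        from balscan.simulate import SimConfig, sample_pool_reads, simulate_neutral_locus

        cfg = SimConfig(seed=21, populations=("P", "A", "B"),
                        pacific_populations=("P",), pool_size=12)
        n_tsp = 0
        for i in range(15):
            hs = simulate_neutral_locus(cfg, i)
            reads = sample_pool_reads(hs, cfg.pool_size, cfg.coverage_mean,
                                      cfg.error_rate, seed=1000 + i)
            og = [k for k, lab in enumerate(hs.labels) if lab.species == "outgroup"]

            def lookup(contig, pos, ref, alt, hs=hs, og=og):
                j = int(np.searchsorted(hs.positions, pos))
                if j >= hs.n_sites or hs.positions[j] != pos:
                    return None
                return tuple(hs.haplotypes[og, j])

            _, tsps = scan_sites(reads, lookup, 0.05)
            n_tsp += len(tsps)
        assert n_tsp == 0
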