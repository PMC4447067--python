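import pytest

from sigchip.annotate import (
    AttributionParams,
    classify_peak,
    join_prior_evidence,
    summarize_annotations,
)
from sigchip.formats_io import GeneFeature, GenomicInterval
from sigchip.regulon_tables import evidence_flags, fixture_total_peak_count


def gene(gene_id, start, end, strand, tss=()):
    return GeneFeature(GenomicInterval("c", start, end, strand), gene_id=gene_id, tss=tss)


class TestClassifyPeak:
    def test_single_downstream_gene_is_unequivocal(self):
        ann = [gene("g1", 5200, 5800, "+")]
        res = classify_peak(GenomicInterval("c", 5000, 5150), ann)
        assert res.context == "promoter_unequivocal"
        assert res.genes[0].gene_id == "g1"
        assert res.genes[0].distance == 50

    def test_divergent_pair_attributed_to_both(self):
        ann = [gene("gm", 3000, 3600, "-"), gene("gp", 4500, 5100, "+")]
        res = classify_peak(GenomicInterval("c", 3800, 4200), ann)
        assert res.context == "promoter_divergent"
        assert {g.gene_id for g in res.genes} == {"gm", "gp"}

    def test_unique_tss_containment_resolves_divergent_pair(self):
        ann = [
            gene("gm", 3000, 3600, "-"),
            gene("gp", 4500, 5100, "+", tss=(4000,)),
        ]
        res = classify_peak(GenomicInterval("c", 3800, 4200), ann)
        assert res.context == "promoter_unequivocal"
        assert res.genes[0].gene_id == "gp"
        assert res.genes[0].tss_contained

    def test_mid_orf_peak_with_no_nearby_start_is_intragenic(self):
        ann = [gene("host", 1000, 9000, "+"), gene("far", 20_000, 20_600, "+")]
        res = classify_peak(GenomicInterval("c", 4000, 4300), ann)
        assert res.context == "intragenic"
        assert res.genes == ()

    def test_peak_inside_host_orf_with_downstream_gene_is_internal(self):
        ann = [gene("host", 1000, 6000, "-"), gene("next", 5600, 6800, "+")]
        res = classify_peak(GenomicInterval("c", 5000, 5400), ann)
        assert res.context == "promoter_internal"
        assert res.genes[0].gene_id == "next"

    def test_many_contained_orfs_excluded(self):
        ann = [gene(f"g{i}", 1000 + 500 * i, 1300 + 500 * i, "+") for i in range(5)]
        res = classify_peak(GenomicInterval("c", 900, 4000), ann)
        assert res.context == "excluded_multiORF"

    def test_oversized_peak_kept_only_with_unique_candidate(self):
        single = [gene("g1", 5300, 5900, "+")]
        res = classify_peak(GenomicInterval("c", 4000, 5280), single)
        assert res.context == "promoter_unequivocal"
        pair = single + [gene("g0", 3400, 3980, "-")]
        res2 = classify_peak(GenomicInterval("c", 4000, 5280), pair)
        assert res2.context == "excluded_multiORF"

    def test_same_strand_tie_reported_ambiguous(self):
        ann = [gene("a", 5200, 5800, "+"), gene("b", 5200, 5700, "+")]
        # same tx_start -> identical distance; never guess
        res = classify_peak(GenomicInterval("c", 4800, 5100), ann)
        assert res.context == "ambiguous"
        assert len(res.genes) == 2

    def test_nearer_same_strand_gene_wins(self):
        ann = [gene("near", 5200, 5800, "+"), gene("farther", 5400, 6000, "+")]
        res = classify_peak(GenomicInterval("c", 4800, 5100), ann)
        assert res.context == "promoter_unequivocal"
        assert res.genes[0].gene_id == "near"

    def test_peak_on_unannotated_chromosome_rejected(self):
        ann = [gene("g1", 100, 700, "+")]
        with pytest.raises(ValueError, match="unannotated"):
            classify_peak(GenomicInterval("other", 10, 60), ann)

    def test_gene_transcribing_toward_peak_is_not_a_candidate(self):
        # '+' gene left of the peak points into it: not its promoter
        ann = [gene("g1", 3000, 3600, "+"), gene("g2", 4300, 4900, "+")]
        res = classify_peak(GenomicInterval("c", 4000, 4200), ann)
        assert [g.gene_id for g in res.genes] == ["g2"]


class TestFixtureReproduction:
    def test_all_63_categories_reproduced(self, fixture_tables):
        records, annotation = fixture_tables
        for rec in records:
            res = classify_peak(rec, annotation)
            if rec.category_truth == "unequivocal":
                assert res.context in ("promoter_unequivocal", "promoter_internal"), rec
                assert res.genes[0].gene_id == rec.candidates[0].gene_id
            else:
                assert res.context == "promoter_divergent", rec
                assert {g.gene_id for g in res.genes} == {
                    c.gene_id for c in rec.candidates
                }

    def test_exactly_two_internal_promoters(self, fixture_tables):
        records, annotation = fixture_tables
        internal = [
            rec.candidates[0].gene_id
            for rec in records
            if classify_peak(rec, annotation).context == "promoter_internal"
        ]
        assert sorted(internal) == ["tfaS", "wbbI"]

    def test_published_accounting(self, fixture_tables):
        records, annotation = fixture_tables
        anns = [classify_peak(r, annotation) for r in records]
        report = summarize_annotations(anns, fixture_total_peak_count())
        assert report["n_promoter"] == 63
        assert report["n_unequivocal"] == 50
        assert report["n_divergent"] == 13
        assert report["n_intergenic"] == 61
        assert report["n_intragenic_or_excluded"] == 15
        assert report["pct_nonpromoter"] == 19

    def test_prior_evidence_counts(self, fixture_tables):
        records, annotation = fixture_tables
        anns = [classify_peak(r, annotation) for r in records]
        assert join_prior_evidence(anns, evidence_flags(records)) == (27, 36)


class TestSummarize:
    def test_empty_annotations_all_zero(self):
        report = summarize_annotations([], 0)
        assert report["n_promoter"] == 0
        assert report["pct_nonpromoter"] == 0

    def test_single_unequivocal(self):
        ann = [gene("g1", 5200, 5800, "+")]
        res = classify_peak(GenomicInterval("c", 5000, 5150), ann)
        report = summarize_annotations([res], 1)
        assert report["n_promoter"] == 1
        assert report["pct_nonpromoter"] == 0

    def test_total_called_must_cover_promoter_peaks(self):
        ann = [gene("g1", 5200, 5800, "+")]
        res = classify_peak(GenomicInterval("c", 5000, 5150), ann)
        with pytest.raises(ValueError):
            summarize_annotations([res], 0)

    def test_contexts_mutually_exclusive_and_exhaustive(self, fixture_tables):
        records, annotation = fixture_tables
        from sigchip.annotate import CONTEXTS

        for rec in records:
            res = classify_peak(rec, annotation)
            assert res.context in CONTEXTS


class TestJoinPriorEvidence:
    def test_all_flags_false_gives_zero(self, fixture_tables):
        records, annotation = fixture_tables
        anns = [classify_peak(r, annotation) for r in records]
        flags = {g: False for g in evidence_flags(records)}
        assert join_prior_evidence(anns, flags) == (0, 0)

    def test_unknown_gene_rejected(self, fixture_tables):
        records, annotation = fixture_tables
        anns = [classify_peak(records[0], annotation)]
        with pytest.raises(ValueError, match="flag"):
            join_prior_evidence(anns, {})


class TestSyntheticAttribution:
    def test_unequivocal_layout_attribution_is_exact(self):
        """Called peaks on planted unequivocal layouts attribute to the true gene."""
        from sigchip.peaks import call_peaks
        from sigchip.synthetic import (
            SimulationParams,
            generate_genome,
            simulate_libraries,
        )
        from sigchip.tracks import coverage_from_fragments

        p = SimulationParams(n_sites=10, depth=200_000, seed=11)
        seq, genes, truth = generate_genome(p)
        ip, inp = simulate_libraries(seq, truth.sites, p)
        peaks = call_peaks(coverage_from_fragments(ip), coverage_from_fragments(inp))
        checked = 0
        for site in truth.sites:
            hits = [pk for pk in peaks if pk.interval.contains(site.position)]
            assert len(hits) == 1
            res = classify_peak(hits[0], genes)
            if site.layout == "unequivocal":
                assert res.context in ("promoter_unequivocal", "promoter_internal")
                assert res.genes[0].gene_id == site.gene_ids[0]
            else:
                assert res.context == "promoter_divergent"
                assert {g.gene_id for g in res.genes} == set(site.gene_ids)
            checked += 1
        assert checked == 10
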