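import pytest

from matepairsv import datasets
from matepairsv.annotate_select import (
    SelectionConfig,
    annotate_genes,
    primer_flanks,
    select_candidates,
)
from matepairsv.core_io import GeneModel
from matepairsv.sv_calling import SVCall


def _call(region_a, region_b, type_="deletion", support=4, sample="s1",
          call_id="c0", correlation=None):
    c = SVCall(call_id, sample, type_, region_a, region_b, "same",
               support, [f"{call_id}m{i}" for i in range(support)])
    c.correlation = correlation
    return c


@pytest.fixture
def plus_gene():
    # exons 1..4 at 10k,20k,30k,40k (width 500)
    return GeneModel("PLUS1", "chr1", "+",
                     [(10_000, 10_500), (20_000, 20_500),
                      (30_000, 30_500), (40_000, 40_500)])


@pytest.fixture
def minus_gene():
    return GeneModel("MINUS1", "chr1", "-",
                     [(110_000, 110_500), (120_000, 120_500),
                      (130_000, 130_500)])


class TestLabels:
    def test_exon_hit(self, plus_gene, model):
        call = _call(("chr1", 20_100, 20_200), ("chr1", 26_000, 26_100))
        ann = annotate_genes(call, [plus_gene], model)
        assert ("PLUS1", "exon 2") in ann.disrupted

    def test_intron_hit(self, plus_gene, model):
        call = _call(("chr1", 21_000, 21_100), ("chr1", 25_000, 25_100))
        ann = annotate_genes(call, [plus_gene], model)
        assert ann.disrupted == [("PLUS1", "intron 2–3")]

    def test_minus_strand_numbering(self, minus_gene, model):
        # genomically first exon of a 3-exon minus-strand gene is exon 3
        call = _call(("chr1", 110_100, 110_200), ("chr1", 114_000, 114_100))
        ann = annotate_genes(call, [minus_gene], model)
        assert ("MINUS1", "exon 3") in ann.disrupted
        call2 = _call(("chr1", 111_000, 111_100), ("chr1", 114_000, 114_100))
        ann2 = annotate_genes(call2, [minus_gene], model)
        assert ("MINUS1", "intron 2–3") in ann2.disrupted

    def test_far_call_not_near_gene(self, plus_gene, model):
        # 10 kb beyond the gene end exceeds the 2 x 2500 window
        call = _call(("chr1", 50_600, 50_700), ("chr1", 56_000, 56_100))
        ann = annotate_genes(call, [plus_gene], model)
        assert ann.disrupted == [] and not ann.near_gene

    def test_nearby_call_is_near_gene(self, plus_gene, model):
        call = _call(("chr1", 43_000, 43_100), ("chr1", 49_000, 49_100))
        ann = annotate_genes(call, [plus_gene], model)
        assert ann.near_gene and ann.disrupted == []


class TestTable2Fixture:
    def test_every_breakpoint_reproduces_its_printed_label(self, model):
        """Each printed breakpoint, annotated against the packaged synthetic
        exon structures, yields exactly the printed gene labels."""
        table2 = datasets.load_table2()
        genes = datasets.load_table2_genes()
        for row in table2.itertuples(index=False):
            call = _call((row.chrom1, int(row.pos1) - 1, int(row.pos1)),
                         (row.chrom2, int(row.pos2) - 1, int(row.pos2)),
                         type_=("translocation" if row.chrom1 != row.chrom2
                                else row.type))
            ann = annotate_genes(call, genes, model)
            expected = set(datasets.parse_gene_labels(row.genes1)) | \
                set(datasets.parse_gene_labels(row.genes2))
            assert set(ann.disrupted) == expected, (row.sample, row.pos1)

    def test_twenty_nine_distinct_genes(self):
        assert len(datasets.distinct_disrupted_genes(datasets.load_table2())) == 29


class TestSelection:
    def _cohort(self, model, support=4, recurrent=True, **cfg):
        genes = [GeneModel("G", "chr1", "+", [(9_000, 9_500), (15_000, 15_500)])]
        a = annotate_genes(_call(("chr1", 10_000, 10_500),
                                 ("chr1", 16_000, 16_500), support=support,
                                 sample="t1", call_id="a"), genes, model)
        cohort = {"t1": [a]}
        if recurrent:
            b = annotate_genes(_call(("chr1", 10_200, 10_700),
                                     ("chr1", 16_200, 16_700), support=5,
                                     sample="t2", call_id="b"), genes, model)
            cohort["t2"] = [b]
        return cohort

    def test_all_three_criteria_selects(self, model):
        cohort = self._cohort(model)
        selected = select_candidates(cohort, model)
        assert {a.call.call_id for a in selected} == {"a", "b"}
        assert all(a.primer_flanks is not None for a in selected)

    def test_low_support_rejected(self, model):
        cohort = self._cohort(model, support=3)
        selected = select_candidates(cohort, model)
        assert "a" not in {a.call.call_id for a in selected}

    def test_non_recurrent_rejected_in_strict_mode_only(self, model):
        cohort = self._cohort(model, recurrent=False)
        assert select_candidates(cohort, model) == []
        relaxed = select_candidates(cohort, model,
                                    SelectionConfig(strict=False))
        assert {a.call.call_id for a in relaxed} == {"a"}

    def test_recurrence_is_symmetric(self, model):
        cohort = self._cohort(model)
        select_candidates(cohort, model)
        assert cohort["t1"][0].recurrent and cohort["t2"][0].recurrent

    def test_deep_sample_needs_support_and_correlation(self, model):
        from matepairsv.anchor_stats import CorrelationResult
        fail = CorrelationResult(0.1, 0.8, 40, "+", False, "fail")
        ok = CorrelationResult(0.97, 1e-9, 40, "+", True, "pass")
        genes = [GeneModel("G", "chr1", "+", [(9_000, 9_500), (15_000, 15_500)])]
        cfg = SelectionConfig(deep_samples={"deep"}, strict=False)
        for corr, expect in ((fail, False), (ok, True)):
            call = _call(("chr1", 10_000, 10_500), ("chr2", 16_000, 16_500),
                         type_="translocation", support=40, sample="deep",
                         correlation=corr)
            ann = annotate_genes(call, genes, model)
            got = select_candidates({"deep": [ann]}, model, cfg)
            assert bool(got) is expect
        low = _call(("chr1", 10_000, 10_500), ("chr2", 16_000, 16_500),
                    type_="translocation", support=39, sample="deep",
                    correlation=ok)
        ann = annotate_genes(low, genes, model)
        assert select_candidates({"deep": [ann]}, model, cfg) == []

    def test_selection_monotone_in_support_threshold(self, model):
        cohort4 = self._cohort(model, support=4)
        sel4 = {a.call.call_id for a in select_candidates(cohort4, model,
                SelectionConfig(min_support=4))}
        cohort5 = self._cohort(model, support=4)
        sel5 = {a.call.call_id for a in select_candidates(cohort5, model,
                SelectionConfig(min_support=5))}
        assert sel5 <= sel4


class TestPrimerFlanks:
    def test_flanks_immediately_outside_regions(self):
        call = _call(("chr1", 10_000, 10_500), ("chr1", 16_000, 16_500))
        left, right = primer_flanks(call)
        assert left == ("chr1", 9_800, 10_000)
        assert right == ("chr1", 16_500, 16_700)

    def test_truncated_at_chromosome_start(self):
        call = _call(("chr1", 50, 400), ("chr1", 6_000, 6_400))
        left, _right = primer_flanks(call)
        assert left == ("chr1", 0, 50)

    def test_translocation_flanks_on_both_chromosomes(self, genome):
        call = _call(("chr1", 10_000, 10_500), ("chr2", 9_999_900, 9_999_950),
                     type_="translocation")
        left, right = primer_flanks(call, genome=genome)
        assert left[0] == "chr1" and right[0] == "chr2"
        assert right == ("chr2", 9_999_950, 10_000_000)  # clipped at chrom end
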