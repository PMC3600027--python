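import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from matepairsv.core_io import (
    Anchor,
    EstimationError,
    GenomeModel,
    InsertEstimationConfig,
    MatePairRecord,
    ParseError,
    RegionSet,
    ValidationError,
    chrom_sort_key,
    estimate_insert_model,
    merge_intervals,
    read_bed,
    read_genes,
    read_mate_pairs,
    write_genes,
    write_mate_pairs,
)


def _write(tmp_path, lines, name="pairs.tsv"):
    p = tmp_path / name
    p.write_text("".join(line + "\n" for line in lines))
    return p


class TestReadMatePairs:
    def test_ambiguous_rows_are_dropped(self, tmp_path):
        p = _write(tmp_path, [
            "s\tp1\tchr1\t100\t+\tchr1\t2550\t+",
            "s\tp2\tchr1\t200\t+\tchr1\t2650\t+\tambiguous",
            "s\tp3\tchr1\t300\t+\tchr1\t2750\t+",
        ])
        records = read_mate_pairs(p)
        assert [r.pair_id for r in records] == ["p1", "p3"]

    def test_identical_anchor_pairs_collapse(self, tmp_path):
        line = "s\tp1\tchr1\t100\t+\tchr1\t2550\t+"
        p = _write(tmp_path, [line, line])
        assert len(read_mate_pairs(p)) == 1

    def test_empty_file(self, tmp_path):
        assert read_mate_pairs(_write(tmp_path, [])) == []

    def test_anchors_canonicalized_natural_chrom_order(self, tmp_path):
        # "2" must sort before "11" (natural order, not lexicographic)
        p = _write(tmp_path, ["s\tp1\t11\t500\t+\t2\t100\t+"])
        (rec,) = read_mate_pairs(p)
        assert rec.anchor1.chrom == "2" and rec.anchor2.chrom == "11"

    def test_malformed_line_names_line_number(self, tmp_path):
        p = _write(tmp_path, ["s\tp1\tchr1\tnotanint\t+\tchr1\t2550\t+"])
        with pytest.raises(ParseError, match="line 1"):
            read_mate_pairs(p)

    def test_unknown_chromosome_with_genome(self, tmp_path):
        p = _write(tmp_path, ["s\tp1\tchrZ\t100\t+\tchrZ\t2550\t+"])
        genome = GenomeModel(chromosomes={"chr1": 10_000})
        with pytest.raises(ValidationError, match="chrZ"):
            read_mate_pairs(p, genome=genome)

    def test_write_read_round_trip(self, tmp_path):
        records = [
            MatePairRecord("s", f"p{i}", Anchor("chr1", 100 * i, "+"),
                           Anchor("chr2", 5000 + i, "-")).canonicalized()
            for i in range(5)
        ]
        path = tmp_path / "rt.tsv"
        write_mate_pairs(records, path)
        back = read_mate_pairs(path)
        assert [(r.anchor1, r.anchor2) for r in back] == \
            [(r.anchor1, r.anchor2) for r in records]


class TestInsertModel:
    def test_constant_separations_hit_sigma_floor(self):
        recs = pd.DataFrame({
            "chrom1": "chr1", "pos1": np.zeros(200, int),
            "strand1": "+", "chrom2": "chr1",
            "pos2": np.full(200, 2500), "strand2": "+",
        })
        m = estimate_insert_model(recs)
        assert m.median == 2500 and m.sigma == 125
        assert (m.lo, m.hi) == (2125, 2875)

    def test_seeded_normal_separations(self):
        rng = np.random.default_rng(1)
        sep = rng.normal(2500, 150, size=10_000)
        recs = pd.DataFrame({
            "chrom1": "chr1", "pos1": 0, "strand1": "+",
            "chrom2": "chr1", "pos2": sep.astype(int), "strand2": "+",
        })
        m = estimate_insert_model(recs)
        assert abs(m.median - 2500) < 10
        assert abs(m.sigma - 150) < 15

    def test_too_few_candidates_suggests_fallback(self):
        with pytest.raises(EstimationError, match="fallback"):
            estimate_insert_model(pd.DataFrame(
                columns=["chrom1", "pos1", "strand1", "chrom2", "pos2",
                         "strand2"]))
        fb = InsertEstimationConfig().fallback_model()
        assert (fb.median, fb.sigma, fb.lo, fb.hi) == (2500, 125, 2125, 2875)


class TestRegions:
    def test_read_bed_single_interval(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t100\n")
        rs = read_bed(p)
        assert rs.intervals == [("chr1", 0, 100)]
        assert rs.total_length == 100

    def test_overlapping_intervals_merge(self):
        rs = RegionSet("x", [("chr1", 0, 100), ("chr1", 50, 150)])
        assert rs.total_length == 150

    def test_end_le_start_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t100\n")
        with pytest.raises(ValidationError):
            read_bed(p)

    @given(st.lists(
        st.tuples(st.sampled_from(["chr1", "chr2"]),
                  st.integers(0, 1000), st.integers(1, 500)),
        max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_merge_idempotent(self, raw):
        intervals = [(c, s, s + w) for c, s, w in raw]
        once = merge_intervals(intervals)
        assert merge_intervals(once) == once
        # merged set never exceeds its bounding span
        assert sum(e - s for _c, s, e in once) <= \
            sum(w for _c, _s, w in raw)

    def test_contains_many(self):
        rs = RegionSet("x", [("chr1", 100, 200), ("chr2", 0, 50)])
        hits = rs.contains_many(["chr1", "chr1", "chr2", "chr3"],
                                [150, 250, 10, 10])
        assert list(hits) == [True, False, True, False]


class TestGenes:
    def test_bed12_round_trip_and_exon_numbering(self, tmp_path):
        from matepairsv.core_io import GeneModel
        plus = GeneModel("G1", "chr1", "+", [(100, 200), (300, 400), (500, 600)])
        minus = GeneModel("G2", "chr1", "-", [(1000, 1100), (1200, 1300)])
        path = tmp_path / "genes.bed"
        write_genes([plus, minus], path)
        g1, g2 = read_genes(path)
        assert g1.exons == plus.exons and g2.strand == "-"
        assert g1.exon_number(0) == 1
        # minus strand: genomically first exon has the highest number
        assert g2.exon_number(0) == 2 and g2.exon_number(1) == 1

    def test_overlapping_exons_rejected(self):
        from matepairsv.core_io import GeneModel
        with pytest.raises(ValidationError):
            GeneModel("bad", "chr1", "+", [(100, 300), (200, 400)])


def test_chrom_sort_key_orders_naturally():
    names = ["11", "2", "X", "1", "21"]
    assert sorted(names, key=chrom_sort_key) == ["1", "2", "11", "21", "X"]


def test_genome_model_rejects_out_of_bounds_exclusions():
    with pytest.raises(ValidationError):
        GenomeModel(chromosomes={"chr1": 1000},
                    excluded=[("chr1", 500, 2000, "gap")])
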