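import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from matepairsv import datasets
from matepairsv.core_io import GenomeModel, RegionSet, ValidationError
from matepairsv.enrichment_stats import (
    binomial_enrichment,
    breakpoint_overlap_test,
    expected_overlap_fraction,
    gene_set_enrichment,
    log_binomial_cdf,
    log_binomial_sf,
    null_rejection_rate,
    regions_hit,
    summarize_validation,
)


def oracle_log10_sf(n, k, p0_frac: Fraction) -> float:
    """Independent exact-summation oracle (rational arithmetic)."""
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * p0_frac**i * (1 - p0_frac)**(n - i)
    return math.log10(float(total))


class TestExpectedFraction:
    def test_array_painting_region_total(self):
        genome = GenomeModel({"1": 500_000_000}, effective_length=3.0e9)
        regions = RegionSet("painting", [("1", 0, 456_615_397)])
        frac = expected_overlap_fraction(regions, genome)
        assert frac == pytest.approx(0.1522, abs=1e-4)
        assert round(frac * 100) == 15

    def test_fragile_site_region_total(self):
        genome = GenomeModel({"1": 500_000_000}, effective_length=3.0e9)
        regions = RegionSet("fragile", [("1", 0, 402_989_448)])
        frac = expected_overlap_fraction(regions, genome)
        assert round(frac * 100, 1) == 13.4

    def test_empty_region_set(self):
        genome = GenomeModel({"1": 1_000}, effective_length=3.0e9)
        assert expected_overlap_fraction(RegionSet("e", []), genome) == 0.0


class TestLogBinomial:
    def test_single_coin(self):
        assert log_binomial_sf(1, 1, 0.5) == pytest.approx(math.log10(0.5))

    def test_small_example_against_oracle(self):
        want = oracle_log10_sf(10, 8, Fraction(3, 20))
        assert log_binomial_sf(10, 8, 0.15) == pytest.approx(want, rel=1e-9)
        assert 10 ** want == pytest.approx(8.67e-6, rel=1e-2)

    def test_k_zero_and_k_equal_n(self):
        assert log_binomial_sf(50, 0, 0.3) == 0.0
        assert log_binomial_sf(50, 50, 0.3) == pytest.approx(50 * math.log10(0.3))

    def test_deep_tail_stability(self):
        # far below 1e-250: linear-space arithmetic would underflow
        val = log_binomial_sf(5000, 4990, 0.01)
        assert -10100 < val < -9000 and np.isfinite(val)

    def test_invalid_p0_rejected(self):
        for bad in (0.0, 1.0, -0.1):
            with pytest.raises(ValidationError):
                log_binomial_sf(10, 5, bad)

    def test_monotone_in_k_and_p0(self):
        vals = [log_binomial_sf(100, k, 0.15) for k in range(10, 60, 5)]
        assert vals == sorted(vals, reverse=True)
        k = 40
        by_p = [log_binomial_sf(100, k, p) for p in (0.1, 0.2, 0.3, 0.4)]
        assert by_p == sorted(by_p)

    def test_lower_tail_complements_upper(self):
        n, p0 = 80, 0.3
        for k in (10, 24, 50):
            total = 10 ** log_binomial_cdf(n, k, p0) + \
                10 ** log_binomial_sf(n, k + 1, p0)
            assert total == pytest.approx(1.0, abs=1e-12)


class TestBreakpointOverlap:
    def _setup(self):
        genome = GenomeModel({"chr1": 1_000_000}, effective_length=1_000_000)
        regions = RegionSet("half", [("chr1", 0, 500_000)])
        return genome, regions

    def test_all_inside_closed_form(self):
        genome, regions = self._setup()
        bps = [("chr1", i * 1000) for i in range(10)]
        res = breakpoint_overlap_test(bps, regions, genome)
        assert res.k == 10 and res.direction == "above"
        assert res.log10_p == pytest.approx(10 * math.log10(0.5))

    def test_absent_chromosome_contributes_zero(self):
        genome, regions = self._setup()
        res = breakpoint_overlap_test(
            [("chrZ", 100), ("chr1", 100)], regions, genome)
        assert res.k == 1

    def test_uniform_null_is_not_significant(self):
        genome = GenomeModel({"chr1": 10_000_000}, effective_length=10_000_000)
        regions = RegionSet("p15", [
            ("chr1", i * 100_000, i * 100_000 + 15_000) for i in range(100)
        ])
        rng = np.random.default_rng(3)
        bps = [("chr1", int(p)) for p in rng.uniform(0, 10_000_000, 2000)]
        res = breakpoint_overlap_test(bps, regions, genome)
        assert abs(res.observed_fraction - 0.15) < 0.025
        assert res.log10_p > -3

    def test_regions_hit_counting(self):
        regions = RegionSet("r", [("chr1", i * 1000, i * 1000 + 100)
                                  for i in range(5)])
        inside = [("chr1", 10), ("chr1", 20), ("chr1", 30)]
        assert regions_hit(inside, regions) == 1
        assert regions_hit([], regions) == 0
        one_each = [("chr1", i * 1000 + 50) for i in range(5)]
        assert regions_hit(one_each, regions) == 5

    def test_null_rejection_rate_close_to_alpha(self):
        genome = GenomeModel({"chr1": 10_000_000}, effective_length=10_000_000)
        regions = RegionSet("p15", [
            ("chr1", i * 100_000, i * 100_000 + 15_000) for i in range(100)
        ])
        rate = null_rejection_rate(genome, regions, n_breakpoints=500,
                                   n_replicates=400, alpha=0.01,
                                   rng=np.random.default_rng(8))
        assert 0.0 <= rate <= 0.025


class TestGeneSetEnrichment:
    def test_no_hits_gives_p_one(self):
        res = gene_set_enrichment({"A", "B"}, {"C"}, 100)
        assert res.log10_p == 0.0 and res.k == 0

    def test_against_oracle(self):
        res = gene_set_enrichment(
            {f"g{i}" for i in range(29)},
            {"g0", "g1", "g2", "g3"} | {f"x{i}" for i in range(416)},
            21_000)
        want = oracle_log10_sf(29, 4, Fraction(420, 21_000))
        assert res.log10_p == pytest.approx(want, rel=1e-9)
        assert res.p_value == pytest.approx(2.5e-3, rel=0.03)

    def test_all_hits_closed_form(self):
        genes = {f"g{i}" for i in range(29)}
        big_set = genes | {f"x{i}" for i in range(391)}
        res = gene_set_enrichment(genes, big_set, 21_000)
        assert res.log10_p == pytest.approx(29 * math.log10(420 / 21_000))

    def test_gene_set_larger_than_universe_rejected(self):
        with pytest.raises(ValidationError):
            gene_set_enrichment({"a"}, {"a", "b", "c"}, 2)


class TestValidationSummary:
    def test_fixture_aggregates(self):
        agg = summarize_validation(datasets.load_table1())
        assert agg["attempted"] == 165
        assert agg["validated"] == 100
        assert agg["constitutional"] == 60
        assert agg["somatic"] == 40
        assert agg["somatic_by_type"] == {
            "deletion": 8, "inversion": 6, "translocation": 26}

    def test_fixture_ratios(self):
        agg = summarize_validation(datasets.load_table1())
        assert agg["translocation_constitutional_fraction"] == pytest.approx(0.35)
        assert agg["interchromosomal_somatic_fraction"] == pytest.approx(0.65)
        assert agg["inter_intra_ratio"] == pytest.approx(26 / 14)
        # the table-derived germline-deletion fraction (43 of 51 validated)
        assert agg["germline_deletion_fraction"] == pytest.approx(43 / 51)

    def test_inconsistent_row_is_named(self):
        bad = pd.DataFrame([{"sample": "s1", "type": "deletion",
                             "attempted": 5, "non_validated": 1,
                             "constitutional": 1, "somatic": 1}])
        with pytest.raises(ValidationError, match="s1"):
            summarize_validation(bad)

    def test_empty_table(self):
        empty = pd.DataFrame(columns=["sample", "type", "attempted",
                                      "non_validated", "constitutional",
                                      "somatic"])
        agg = summarize_validation(empty)
        assert agg["attempted"] == 0 and agg["somatic"] == 0
        assert math.isnan(agg["inter_intra_ratio"])
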