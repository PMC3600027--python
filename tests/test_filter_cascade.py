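import pytest

from matepairsv.core_io import RegionSet
from matepairsv.filter_cascade import (
    ConfigurationError,
    FilterConfig,
    apply_filters,
    passing,
)
from matepairsv.sv_calling import SVCall


def _call(start_a, start_b, type_="deletion", chrom_a="chr1", chrom_b=None,
          support=5, sample="s1", call_id="c0"):
    chrom_b = chrom_b or chrom_a
    members = [f"{call_id}m{i}" for i in range(support)]
    return SVCall(call_id, sample, type_,
                  (chrom_a, start_a, start_a + 100),
                  (chrom_b, start_b, start_b + 100),
                  "same", support, members)


class TestStages:
    def test_near_excluded_within_two_insert_lengths(self, genome, model):
        # centromere starts at 4,950,000; a call 4,000 bp away is inside the
        # 2 x 2500 bp exclusion margin, one 6,000 bp away is not
        near = _call(4_945_900, 4_941_000)
        far = _call(4_943_900, 4_939_000)
        apply_filters([near, far], genome, model, FilterConfig())
        assert "near_excluded" in near.filter_flags
        assert "near_excluded" not in far.filter_flags

    def test_call_seen_in_control_flagged(self, genome, model):
        call = _call(1_000_000, 1_006_000)
        control = _call(1_000_200, 1_006_300, sample="ctrl")
        apply_filters([call], genome, model,
                      FilterConfig(control_call_sets=[[control]]))
        assert "in_control" in call.filter_flags

    def test_control_match_is_type_aware(self, genome, model):
        call = _call(1_000_000, 1_006_000, type_="deletion")
        control = _call(1_000_000, 1_006_000, type_="inversion", sample="ctrl")
        apply_filters([call], genome, model,
                      FilterConfig(control_call_sets=[[control]]))
        assert "in_control" not in call.filter_flags

    def test_known_variant_matched_ignoring_type(self, genome, model):
        call = _call(1_000_000, 1_006_000)
        known = RegionSet("dgv", [("chr1", 1_000_050, 1_006_050)])
        apply_filters([call], genome, model, FilterConfig(known_variants=known))
        assert "known_variant" in call.filter_flags

    def test_low_support_threshold(self, genome, model):
        call = _call(1_000_000, 1_006_000, support=3)
        apply_filters([call], genome, model, FilterConfig(min_support=4))
        assert "low_support" in call.filter_flags

    def test_matched_normal_subtraction(self, genome, model):
        call = _call(2_000_000, 2_006_000)
        normal = _call(2_000_100, 2_006_100, sample="normal")
        apply_filters([call], genome, model,
                      FilterConfig(matched_normal=[normal]))
        assert "in_matched_normal" in call.filter_flags

    def test_deep_sample_threshold(self, genome, model):
        call = _call(1_000_000, 1_006_000, support=10, sample="deep1")
        apply_filters([call], genome, model,
                      FilterConfig(deep_samples={"deep1"}))
        assert "low_support" in call.filter_flags

    def test_flags_are_independent(self, genome, model):
        # a call matching several criteria carries every applicable flag
        call = _call(4_945_900, 4_941_000, support=2)
        control = _call(4_945_900, 4_941_000, sample="ctrl")
        apply_filters([call], genome, model,
                      FilterConfig(control_call_sets=[[control]]))
        assert {"near_excluded", "low_support", "in_control"} <= call.filter_flags

    def test_missing_excluded_track_is_configuration_error(self, model):
        from matepairsv.core_io import GenomeModel
        bare = GenomeModel(chromosomes={"chr1": 10_000_000})
        with pytest.raises(ConfigurationError):
            apply_filters([_call(1_000_000, 1_006_000)], bare, model,
                          FilterConfig())


class TestProperties:
    def _cohort(self, genome, model, min_support):
        calls = [
            _call(1_000_000, 1_006_000, support=3, call_id="a"),
            _call(2_000_000, 2_006_000, support=4, call_id="b"),
            _call(3_000_000, 3_006_000, support=10, call_id="c"),
        ]
        apply_filters(calls, genome, model,
                      FilterConfig(min_support=min_support))
        return {c.call_id for c in passing(calls)}

    def test_support_threshold_subset_property(self, genome, model):
        strict = self._cohort(genome, model, 4)
        relaxed = self._cohort(genome, model, 3)
        assert strict <= relaxed

    def test_report_counts_and_fractions(self, genome, model):
        calls = [
            _call(1_000_000, 1_006_000, support=3),
            _call(4_945_900, 4_941_000, support=5),
            _call(2_000_000, 2_006_000, support=5),
        ]
        _, report = apply_filters(calls, genome, model, FilterConfig())
        stages = dict((s, (n, k)) for s, n, k, _f in report.stages)
        assert stages["low_support"] == (3, 1)
        assert stages["near_excluded"] == (3, 1)
        assert report.removed_fraction_total == pytest.approx(2 / 3)
        assert report.removed_fraction_cascade == pytest.approx(1 / 3)

    def test_zero_noise_cohort_only_loses_low_support(self):
        """With no chimeras, decoys or germline implants, nothing but the
        support threshold removes calls."""
        from matepairsv.core_io import estimate_insert_model
        from matepairsv.filter_cascade import evidence_calls
        from matepairsv.pipeline import PipelineConfig, call_from_frame
        from matepairsv.synthetic_data import SimulationConfig, simulate_cohort

        config = SimulationConfig(
            seed=42, chimera_rate=0.0, n_decoys=0, germline_fraction=0.0,
            chromosome_lengths=(5_000_000, 5_000_000),
            n_deletions=3, n_insertions=2, n_inversions=2, n_translocations=3,
        )
        genome, _genes, truth, frames = simulate_cohort(config)
        mdl = estimate_insert_model(frames["tumor"])
        _cls, calls, _members = call_from_frame(
            frames["tumor"], mdl, PipelineConfig())
        control_sets = [
            evidence_calls(call_from_frame(frames[f"control{i+1}"], mdl,
                                           PipelineConfig())[1])
            for i in range(2)
        ]
        normal = evidence_calls(
            call_from_frame(frames["normal"], mdl, PipelineConfig())[1])
        _, report = apply_filters(
            calls, genome, mdl,
            FilterConfig(control_call_sets=control_sets,
                         matched_normal=normal))
        flagged = {s: k for s, _n, k, _f in report.stages}
        assert flagged["known_variant"] == 0
        # single-pair clusters from the insert-length tail may land anywhere
        # (low_support removes them); genuine clusters must carry no
        # cascade flag at all
        supported = [c for c in calls if c.support >= 4]
        assert supported, "expected implanted clusters"
        assert all(not (c.filter_flags - {"low_support"}) for c in supported)
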