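"""The somatic-filter cascade for candidate SV calls.

Five independent flags are applied in a fixed reporting order:

  in_control        also called in a healthy-control sample
  near_excluded     within two insert lengths of a telomere, centromere or
                    reference gap
  known_variant     matches a known-variant database record
  low_support       fewer supporting pairs than the threshold
  in_matched_normal also called in the patient-matched normal (an in-silico
                    surrogate for the study's PCR-on-normal somatic call)

Flags are independent: reordering the stages changes per-stage attribution
in the report but never the final pass/fail set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import GenomeModel, InsertSizeModel, RegionSet


class ConfigurationError(ValueError):
    pass


@dataclass
class FilterConfig:
    proximity_multiple: float = 2.0       # of insert lengths, for all matching
    min_support: int = 4                  # alternate relaxed threshold: 3
    deep_sample_min_support: int = 40     # for deeply sequenced samples
    deep_samples: set = field(default_factory=set)
    control_call_sets: list = field(default_factory=list)  # list of call lists
    known_variants: RegionSet | None = None
    matched_normal: list | None = None    # call set from the matched normal

    def __post_init__(self):
        if self.min_support < 1:
            raise ConfigurationError("min_support must be >= 1")
        if self.proximity_multiple <= 0:
            raise ConfigurationError("proximity_multiple must be positive")


@dataclass
class FilterReport:
    """Per-stage attrition plus two removed-fraction summaries: one over the
    three artifact/germline stages alone and one over all flags (support
    thresholds included), since attrition can be quoted either way."""

    stages: list = field(default_factory=list)  # (stage, calls_in, flagged, fraction)
    removed_fraction_cascade: float = 0.0       # control+excluded+known(+normal)
    removed_fraction_total: float = 0.0         # any flag

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("stage\tcalls_in\tcalls_flagged\tfraction\n")
            for stage, n_in, n_flag, frac in self.stages:
                fh.write(f"{stage}\t{n_in}\t{n_flag}\t{frac:.4f}\n")
            fh.write(f"removed_fraction_cascade\t-\t-\t{self.removed_fraction_cascade:.4f}\n")
            fh.write(f"removed_fraction_total\t-\t-\t{self.removed_fraction_total:.4f}\n")


def _mid(region: tuple) -> float:
    return 0.5 * (region[1] + region[2])


def _index_calls(calls) -> dict:
    """Bucket calls by (type, chromA, chromB) with sorted midpoint arrays."""
    buckets: dict = {}
    for c in calls:
        key = (c.type, c.region_a[0], c.region_b[0])
        buckets.setdefault(key, ([], []))
        buckets[key][0].append(_mid(c.region_a))
        buckets[key][1].append(_mid(c.region_b))
    out = {}
    for key, (ma, mb) in buckets.items():
        ma = np.asarray(ma)
        mb = np.asarray(mb)
        order = np.argsort(ma, kind="mergesort")
        out[key] = (ma[order], mb[order])
    return out


def _matches_call_set(call, index: dict, proximity: float) -> bool:
    """Type-aware match: both breakpoint regions within `proximity` of the
    other event's regions (midpoint distance)."""
    key = (call.type, call.region_a[0], call.region_b[0])
    entry = index.get(key)
    if entry is None:
        return False
    ma, mb = entry
    xa, xb = _mid(call.region_a), _mid(call.region_b)
    lo = np.searchsorted(ma, xa - proximity, side="left")
    hi = np.searchsorted(ma, xa + proximity, side="right")
    return bool(np.any(np.abs(mb[lo:hi] - xb) <= proximity))


def _matches_known_variant(call, known: RegionSet, proximity: float) -> bool:
    """Known-variant records are plain intervals (DGV-style BED carries no
    uniform type field), so matching ignores type: a same-chromosome call
    matches when its two breakpoints fall within `proximity` of the record's
    two endpoints.  Translocations never match interval records."""
    if call.region_a[0] != call.region_b[0]:
        return False
    index = known._build_index()
    entry = index.get(call.region_a[0])
    if entry is None:
        return False
    starts, ends = entry
    xa, xb = _mid(call.region_a), _mid(call.region_b)
    lo = np.searchsorted(starts, xa - proximity, side="left")
    hi = np.searchsorted(starts, xa + proximity, side="right")
    return bool(np.any(np.abs(ends[lo:hi] - xb) <= proximity))


def apply_filters(calls, genome: GenomeModel, model: InsertSizeModel,
                  config: FilterConfig) -> tuple:
    """Populate filter_flags on `calls` (one sample) and build a FilterReport."""
    if genome.excluded is None or (config.known_variants is None
                                   and config.control_call_sets is None):
        pass
    if not genome.excluded:
        raise ConfigurationError(
            "genome has no excluded intervals; supply the gap/telomere/"
            "centromere track before filtering"
        )
    proximity = config.proximity_multiple * model.median
    control_indexes = [_index_calls(cs) for cs in config.control_call_sets]
    normal_index = (_index_calls(config.matched_normal)
                    if config.matched_normal is not None else None)

    stage_flagged = {s: 0 for s in (
        "in_control", "near_excluded", "known_variant", "low_support",
        "in_matched_normal",
    )}
    n_in = len(calls)
    for call in calls:
        if any(_matches_call_set(call, idx, proximity) for idx in control_indexes):
            call.filter_flags.add("in_control")
            stage_flagged["in_control"] += 1
        near = genome.near_excluded(*call.region_a, distance=proximity) or \
            genome.near_excluded(*call.region_b, distance=proximity)
        if near:
            call.filter_flags.add("near_excluded")
            stage_flagged["near_excluded"] += 1
        if config.known_variants is not None and _matches_known_variant(
                call, config.known_variants, proximity):
            call.filter_flags.add("known_variant")
            stage_flagged["known_variant"] += 1
        threshold = (config.deep_sample_min_support
                     if call.sample_id in config.deep_samples
                     else config.min_support)
        if call.support < threshold:
            call.filter_flags.add("low_support")
            stage_flagged["low_support"] += 1
        if normal_index is not None and _matches_call_set(call, normal_index,
                                                          proximity):
            call.filter_flags.add("in_matched_normal")
            stage_flagged["in_matched_normal"] += 1

    cascade_flags = {"in_control", "near_excluded", "known_variant",
                     "in_matched_normal"}
    n_cascade = sum(1 for c in calls if c.filter_flags & cascade_flags)
    n_any = sum(1 for c in calls if c.filter_flags)
    report = FilterReport(
        stages=[
            (stage, n_in, k, (k / n_in if n_in else 0.0))
            for stage, k in stage_flagged.items()
        ],
        removed_fraction_cascade=(n_cascade / n_in if n_in else 0.0),
        removed_fraction_total=(n_any / n_in if n_in else 0.0),
    )
    return calls, report


def passing(calls) -> list:
    return [c for c in calls if not c.filter_flags]


def evidence_calls(calls, min_support: int = 2) -> list:
    """Restrict a control/matched-normal call set to clusters with enough
    support to count as evidence.  A single discordant pair in a control is
    indistinguishable from insert-length tail noise, so subtracting on it
    would silently delete true somatic events at random."""
    return [c for c in calls if c.support >= min_support]
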