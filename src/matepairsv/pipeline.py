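"""End-to-end orchestration: read -> classify -> cluster -> filter ->
correlate -> annotate/select -> enrich, plus the synthetic-cohort
benchmark used to validate the pipeline against implanted truth."""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import annotate_select, filter_cascade
from .anchor_stats import screen_translocations
from .core_io import (
    GenomeModel,
    InsertEstimationConfig,
    InsertSizeModel,
    estimate_insert_model,
    read_bed,
    read_chrom_sizes,
    read_genes,
    read_labeled_bed,
    read_mate_pair_frame,
    write_bedpe,
)
from .filter_cascade import FilterConfig, apply_filters, evidence_calls, passing
from .sv_calling import ClusterConfig, classify_frame, cluster_events
from .synthetic_data import SimulationConfig, simulate_cohort


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    alignments: dict = field(default_factory=dict)  # sample_id -> pairs TSV
    tumor_sample: str = "tumor"
    matched_normal_sample: str | None = "normal"
    control_samples: tuple = ("control1", "control2")
    chrom_sizes: str | None = None
    excluded_bed: str | None = None
    known_variants_bed: str | None = None
    genes_bed: str | None = None
    region_sets: dict = field(default_factory=dict)  # name -> BED path
    outdir: str = "results"
    read_length: int = 50
    min_support: int = 4
    deep_samples: set = field(default_factory=set)
    alpha: float = 0.05
    min_pairs: int = 4
    cluster_window: float | None = None
    control_min_support: int = 2  # evidence threshold for control/normal sets
    insert_fallback: bool = False
    seed: int = 0

    @classmethod
    def from_bundle(cls, bundle_dir: str, outdir: str, **kwargs):
        """Configure from a `simulate` output directory."""
        samples = {}
        for fn in sorted(os.listdir(bundle_dir)):
            if fn.endswith(".pairs.tsv"):
                samples[fn[: -len(".pairs.tsv")]] = os.path.join(bundle_dir, fn)
        return cls(
            alignments=samples,
            chrom_sizes=os.path.join(bundle_dir, "genome.chrom.sizes"),
            excluded_bed=os.path.join(bundle_dir, "excluded.bed"),
            known_variants_bed=os.path.join(bundle_dir, "known_variants.bed"),
            genes_bed=os.path.join(bundle_dir, "genes.bed"),
            outdir=outdir,
            **kwargs,
        )


def _load_genome(config: PipelineConfig) -> GenomeModel:
    if config.chrom_sizes is None or not os.path.exists(config.chrom_sizes):
        raise PipelineError("read", f"missing chromosome sizes: {config.chrom_sizes}")
    sizes = read_chrom_sizes(config.chrom_sizes)
    excluded = []
    if config.excluded_bed and os.path.exists(config.excluded_bed):
        excluded = read_labeled_bed(config.excluded_bed)
    return GenomeModel(chromosomes=sizes, excluded=excluded)


def call_from_frame(frame: pd.DataFrame, model: InsertSizeModel,
                    config: PipelineConfig):
    classified = classify_frame(frame, model, read_length=config.read_length)
    calls = cluster_events(
        classified, model, ClusterConfig(config.cluster_window),
        read_length=config.read_length,
    )
    disc = classified[classified["category"] != "concordant"]
    members = dict(zip(disc["pair_id"].astype(str),
                       zip(disc["pos1"], disc["pos2"])))
    return classified, calls, members


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the output bundle.

    Outputs: calls BEDPE, somatic-table TSV, filter report TSV, enrichment
    TSV (when region sets are configured), Circos-style link file of passing
    somatic translocations, and a JSON run log echoing seed and config.
    Stage errors propagate as PipelineError naming the stage; partially
    written outputs are removed.
    """
    os.makedirs(config.outdir, exist_ok=True)
    written: list = []
    try:
        return _run_stages(config, written)
    except PipelineError:
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise
    except Exception as exc:  # pragma: no cover - defensive wrapper
        for path in written:
            if os.path.exists(path):
                os.remove(path)
        raise PipelineError("internal", str(exc)) from exc


def _run_stages(config: PipelineConfig, written: list) -> dict:
    genome = _load_genome(config)
    if config.tumor_sample not in config.alignments:
        raise PipelineError("read", f"no alignments for tumor sample "
                                    f"{config.tumor_sample!r}")
    frames = {}
    for sample, path in config.alignments.items():
        if not os.path.exists(path):
            raise PipelineError("read", f"missing alignments: {path}")
        frames[sample] = read_mate_pair_frame(path)
        frames[sample]["sample_id"] = sample

    tumor = frames[config.tumor_sample]
    try:
        model = estimate_insert_model(tumor)
    except Exception as exc:
        if config.insert_fallback:
            model = InsertEstimationConfig().fallback_model()
        else:
            raise PipelineError("classify", str(exc)) from exc

    _classified, calls, members = call_from_frame(tumor, model, config)
    n_pairs = len(tumor)
    n_discordant = int((_classified["category"] != "concordant").sum())

    control_sets = []
    for sample in config.control_samples:
        if sample in frames:
            control_sets.append(evidence_calls(
                call_from_frame(frames[sample], model, config)[1],
                config.control_min_support))
    normal_calls = None
    if (config.matched_normal_sample
            and config.matched_normal_sample in frames):
        normal_calls = evidence_calls(
            call_from_frame(frames[config.matched_normal_sample], model,
                            config)[1],
            config.control_min_support)

    known = None
    if config.known_variants_bed and os.path.exists(config.known_variants_bed):
        try:
            known = read_bed(config.known_variants_bed, "known_variants")
        except Exception as exc:
            raise PipelineError("filter", str(exc)) from exc
        if not known.intervals:
            known = None
    fcfg = FilterConfig(
        min_support=config.min_support,
        deep_samples=config.deep_samples,
        control_call_sets=control_sets,
        known_variants=known,
        matched_normal=normal_calls,
    )
    try:
        calls, report = apply_filters(calls, genome, model, fcfg)
    except filter_cascade.ConfigurationError as exc:
        raise PipelineError("filter", str(exc)) from exc

    screen_counts = screen_translocations(
        calls, members, alpha=config.alpha, min_pairs=config.min_pairs)
    somatic = passing(calls)

    genes = []
    if config.genes_bed and os.path.exists(config.genes_bed):
        genes = read_genes(config.genes_bed)
    annotated = [annotate_select.annotate_genes(c, genes, model)
                 for c in somatic]
    annotate_select.select_candidates(
        {config.tumor_sample: annotated}, model,
        annotate_select.SelectionConfig(
            min_support=config.min_support, deep_samples=config.deep_samples,
            strict=False,
        ),
    )

    enrichment = {}
    if config.region_sets:
        from .enrichment_stats import breakpoint_overlap_test
        breakpoints = []
        for c in somatic:
            if c.type == "translocation":
                breakpoints.append((c.region_a[0], (c.region_a[1] + c.region_a[2]) // 2))
                breakpoints.append((c.region_b[0], (c.region_b[1] + c.region_b[2]) // 2))
        for name, path in config.region_sets.items():
            regions = read_bed(path, name)
            genome_for_test = GenomeModel(
                chromosomes=genome.chromosomes, excluded=genome.excluded,
                effective_length=genome.total_length,
            )
            if breakpoints:
                enrichment[name] = breakpoint_overlap_test(
                    breakpoints, regions, genome_for_test)

    out = {}

    def _path(name):
        p = os.path.join(config.outdir, name)
        written.append(p)
        return p

    out["calls_bedpe"] = _path("calls.bedpe")
    write_bedpe(calls, out["calls_bedpe"])
    out["somatic_table"] = _path("somatic_table.tsv")
    pd.DataFrame(annotate_select.table2_style_rows(annotated)).to_csv(
        out["somatic_table"], sep="\t", index=False)
    out["filter_report"] = _path("filter_report.tsv")
    report.to_tsv(out["filter_report"])
    if enrichment:
        from .enrichment_stats import enrichment_rows_to_tsv
        out["enrichment"] = _path("enrichment.tsv")
        enrichment_rows_to_tsv(enrichment, out["enrichment"])
    out["circos_links"] = _path("circos_links.txt")
    with open(out["circos_links"], "w") as fh:
        for c in somatic:
            if c.type == "translocation":
                fh.write(
                    f"{c.region_a[0]} {c.region_a[1]} {c.region_a[2]} "
                    f"{c.region_b[0]} {c.region_b[1]} {c.region_b[2]}\n"
                )
    out["run_log"] = _path("run_log.json")
    with open(out["run_log"], "w") as fh:
        json.dump({
            "seed": config.seed,
            "insert_model": vars(model),
            "n_pairs": n_pairs,
            "n_discordant": n_discordant,
            "discordant_fraction": n_discordant / n_pairs if n_pairs else 0.0,
            "n_calls": len(calls),
            "n_passing": len(somatic),
            "screen_counts": screen_counts,
            "filter_stages": [list(s) for s in report.stages],
            "config": {k: sorted(v) if isinstance(v, set) else v
                       for k, v in vars(config).items()
                       if isinstance(v, (int, float, str, list, tuple, set,
                                         dict, type(None)))},
        }, fh, indent=2, default=str)
    out["summary"] = {
        "n_pairs": n_pairs,
        "discordant_fraction": n_discordant / n_pairs if n_pairs else 0.0,
        "n_calls": len(calls),
        "n_passing_somatic": len(somatic),
        "screen_counts": screen_counts,
    }
    return out


# ---------------------------------------------------------------------------
# Synthetic-cohort benchmark: recover implanted truth end to end
# ---------------------------------------------------------------------------

@dataclass
class CohortMetrics:
    n_eligible: int = 0
    n_recovered: int = 0
    n_final_calls: int = 0
    n_final_true: int = 0
    germline_seen: int = 0
    germline_flagged: int = 0
    decoy_screened: int = 0
    decoy_failed: int = 0
    true_screened: int = 0
    true_passed: int = 0
    discordant_fraction: float = 0.0

    @property
    def recall(self) -> float:
        return self.n_recovered / self.n_eligible if self.n_eligible else float("nan")

    @property
    def precision(self) -> float:
        return self.n_final_true / self.n_final_calls if self.n_final_calls else float("nan")


def _majority_source(call, source_by_pair: dict) -> str | None:
    tally: dict = {}
    for pid in call.members:
        src = source_by_pair.get(pid)
        if src is None:
            continue
        base = src.split(":")[0]
        tally[base] = tally.get(base, 0) + 1
    if not tally:
        return None
    best, count = max(tally.items(), key=lambda kv: kv[1])
    return best if count * 2 >= len(call.members) else None


def _contains_truth(call, sv, pad: int = 0) -> bool:
    (ca, sa, ea), (cb, sb, eb) = call.region_a, call.region_b
    return (
        ca == sv.chrom_a and cb == sv.chrom_b
        and sa - pad <= sv.bp_a <= ea + pad
        and sb - pad <= sv.bp_b <= eb + pad
    )


def run_cohort(config: SimulationConfig, min_members_for_screen: int = 5
               ) -> CohortMetrics:
    """Simulate one cohort, run the full somatic pipeline, score vs truth.

    Eligibility for recall: somatic implants with >= 4 junction-spanning
    tumor pairs (implants are placed away from excluded regions by
    construction).  A final call counts as true when most of its members
    were emitted for a somatic implant of the same type and both true
    breakpoints lie inside its bracketing regions.
    """
    genome, _genes, truth, frames = simulate_cohort(config)
    tumor = frames["tumor"]
    model = estimate_insert_model(tumor)
    pcfg = PipelineConfig(read_length=config.read_length)

    classified, calls, members = call_from_frame(tumor, model, pcfg)
    source_by_pair = dict(zip(tumor["pair_id"].astype(str), tumor["source"]))

    control_sets = [
        evidence_calls(call_from_frame(frames[f"control{i + 1}"], model,
                                       pcfg)[1])
        for i in range(config.n_controls)
    ]
    normal_calls = evidence_calls(
        call_from_frame(frames["normal"], model, pcfg)[1])
    fcfg = FilterConfig(
        control_call_sets=control_sets,
        known_variants=(truth.known_variants
                        if truth.known_variants.intervals else None),
        matched_normal=normal_calls,
    )
    calls, _report = apply_filters(calls, genome, model, fcfg)
    screen_translocations(calls, members)
    final = passing(calls)

    m = CohortMetrics()
    m.discordant_fraction = float(
        (classified["category"] != "concordant").mean())
    m.n_final_calls = len(final)

    truth_by_id = {sv.sv_id: sv for sv in truth.svs}
    recovered_ids = set()
    for call in final:
        src = _majority_source(call, source_by_pair)
        sv = truth_by_id.get(src) if src else None
        if (sv is not None and sv.status == "somatic" and sv.type == call.type
                and _contains_truth(call, sv)):
            m.n_final_true += 1
            recovered_ids.add(sv.sv_id)
    for sv in truth.somatic():
        if sv.spanning.get("tumor", 0) >= 4:
            m.n_eligible += 1
            if sv.sv_id in recovered_ids:
                m.n_recovered += 1

    # germline implants present in the matched normal: flagged?
    germline_called = set()
    for call in calls:
        src = _majority_source(call, source_by_pair)
        sv = truth_by_id.get(src) if src else None
        if sv is not None and sv.status == "germline" and sv.type == call.type:
            if sv.sv_id in germline_called:
                continue
            germline_called.add(sv.sv_id)
            m.germline_seen += 1
            if "in_matched_normal" in call.filter_flags:
                m.germline_flagged += 1

    # anchor-correlation screen tallies on translocation clusters
    decoy_ids = {d.decoy_id for d in truth.decoys}
    for call in calls:
        if call.type != "translocation" or call.support < min_members_for_screen:
            continue
        if call.correlation is None:
            continue
        src = _majority_source(call, source_by_pair)
        if src in decoy_ids:
            m.decoy_screened += 1
            if call.correlation.verdict == "fail":
                m.decoy_failed += 1
        elif src in truth_by_id and truth_by_id[src].type == "translocation":
            m.true_screened += 1
            if call.correlation.verdict == "pass":
                m.true_passed += 1
    return m


def aggregate_cohorts(metrics: list) -> dict:
    tot = CohortMetrics()
    for m in metrics:
        for f in ("n_eligible", "n_recovered", "n_final_calls", "n_final_true",
                  "germline_seen", "germline_flagged", "decoy_screened",
                  "decoy_failed", "true_screened", "true_passed"):
            setattr(tot, f, getattr(tot, f) + getattr(m, f))
    return {
        "recall": tot.recall,
        "precision": tot.precision,
        "germline_flag_rate": (tot.germline_flagged / tot.germline_seen
                               if tot.germline_seen else float("nan")),
        "decoy_fail_rate": (tot.decoy_failed / tot.decoy_screened
                            if tot.decoy_screened else float("nan")),
        "true_pass_rate": (tot.true_passed / tot.true_screened
                           if tot.true_screened else float("nan")),
        "mean_discordant_fraction": float(
            np.mean([m.discordant_fraction for m in metrics])),
        "totals": vars(tot),
    }
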