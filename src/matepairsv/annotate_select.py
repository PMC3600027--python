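"""Gene-disruption annotation, validation-candidate selection, primer flanks.

Each breakpoint region overlapping a gene is labeled "exon k" when it
intersects an exon and "intron k-(k+1)" when it lies wholly between two
exons; exon numbering follows transcript orientation, so the genomically
last exon of a minus-strand gene is exon 1.  Candidates for validation must
(1) fall in or within two insert lengths of a gene, (2) have at least four
supporting pairs, and (3) recur within two insert lengths of a similar
rearrangement in another tumor; deeply sequenced samples additionally need
40 supporting pairs and a passing anchor correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import GeneModel, GenomeModel, InsertSizeModel

EN_DASH = "–"  # intron labels print as e.g. "intron 10–11"


@dataclass
class SelectionConfig:
    min_support: int = 4
    deep_samples: set = field(default_factory=set)
    deep_sample_min_support: int = 40
    proximity_multiple: float = 2.0
    strict: bool = True  # require recurrence (criterion 3); relaxed mode drops it


@dataclass
class AnnotatedSV:
    call: object  # SVCall
    disrupted: list = field(default_factory=list)  # [(symbol, label)]
    near_gene: bool = False
    recurrent: bool = False
    selected: bool = False
    primer_flanks: tuple | None = None


def _label_region(gene: GeneModel, start: int, end: int) -> str | None:
    """Exon/intron label for a region overlapping this gene, or None.

    If the region intersects any exon, the label is the first intersected
    exon in transcript order; otherwise, if it lies inside the gene body,
    the intron containing it (the first overlapped intron in transcript
    order when it spans beyond one).
    """
    if end <= gene.start or start >= gene.end:
        return None
    exon_hits = [
        gene.exon_number(i)
        for i, (es, ee) in enumerate(gene.exons)
        if start < ee and end > es
    ]
    if exon_hits:
        return f"exon {min(exon_hits)}"
    intron_hits = []
    for i in range(gene.n_exons - 1):
        gap_s, gap_e = gene.exons[i][1], gene.exons[i + 1][0]
        if start < gap_e and end > gap_s:
            t1, t2 = sorted((gene.exon_number(i), gene.exon_number(i + 1)))
            intron_hits.append((t1, t2))
    if intron_hits:
        t1, t2 = min(intron_hits)
        return f"intron {t1}{EN_DASH}{t2}"
    return None


def annotate_genes(call, genes, model: InsertSizeModel) -> AnnotatedSV:
    """Annotate one call's two breakpoint regions against gene models.

    An empty disrupted list is a valid outcome; near_gene is true when any
    gene body lies within two insert lengths of either breakpoint region.
    """
    window = 2.0 * model.median
    disrupted = []
    near = False
    for region in (call.region_a, call.region_b):
        chrom, start, end = region
        for gene in genes:
            if gene.chrom != chrom:
                continue
            if start < gene.end + window and end > gene.start - window:
                near = True
            label = _label_region(gene, start, end)
            if label is not None and (gene.symbol, label) not in disrupted:
                disrupted.append((gene.symbol, label))
    return AnnotatedSV(call=call, disrupted=disrupted, near_gene=near)


def primer_flanks(call, flank: int = 200,
                  genome: GenomeModel | None = None) -> tuple:
    """The 200-bp windows immediately outside each breakpoint-bracketing
    interval, oriented toward the junction; truncated at chromosome ends."""
    ca, sa, _ea = call.region_a
    cb, _sb, eb = call.region_b
    left = (ca, max(0, sa - flank), sa)
    length_b = genome.chromosomes.get(cb) if genome else None
    hi = eb + flank if length_b is None else min(eb + flank, length_b)
    right = (cb, eb, hi)
    return left, right


def _recurrence(cohort: dict, proximity: float) -> None:
    """Mark calls recurrent when another sample has a same-type call with
    both breakpoints within `proximity` (midpoint distance).  Symmetric."""
    entries = []
    for sample, annotated in cohort.items():
        for ann in annotated:
            c = ann.call
            entries.append((
                sample, ann, c.type, c.region_a[0], c.region_b[0],
                0.5 * (c.region_a[1] + c.region_a[2]),
                0.5 * (c.region_b[1] + c.region_b[2]),
            ))
    for i, (s1, a1, t1, ca1, cb1, ma1, mb1) in enumerate(entries):
        for s2, a2, t2, ca2, cb2, ma2, mb2 in entries[i + 1:]:
            if s1 == s2 or t1 != t2 or ca1 != ca2 or cb1 != cb2:
                continue
            if abs(ma1 - ma2) <= proximity and abs(mb1 - mb2) <= proximity:
                a1.recurrent = True
                a2.recurrent = True


def select_candidates(cohort: dict, model: InsertSizeModel,
                      config: SelectionConfig | None = None) -> list:
    """Apply the three selection criteria across a cohort.

    cohort maps sample_id -> list of AnnotatedSV (annotate_genes output).
    Strict mode requires near_gene AND support AND recurrence; relaxed mode
    drops recurrence (the study also validated non-recurrent events).  In
    deep samples the support cutoff rises and a passing anchor correlation
    is required wherever a correlation result exists.  Returns the selected
    AnnotatedSVs; also sets .recurrent/.selected in place.
    """
    config = config or SelectionConfig()
    proximity = config.proximity_multiple * model.median
    _recurrence(cohort, proximity)
    selected = []
    for sample, annotated in cohort.items():
        deep = sample in config.deep_samples
        threshold = config.deep_sample_min_support if deep else config.min_support
        for ann in annotated:
            ok = ann.near_gene and ann.call.support >= threshold
            if config.strict:
                ok = ok and ann.recurrent
            if deep and ann.call.correlation is not None:
                ok = ok and ann.call.correlation.verdict == "pass"
            ann.selected = ok
            if ok:
                ann.primer_flanks = primer_flanks(ann.call)
                selected.append(ann)
    return selected


def table2_style_rows(annotated) -> list:
    """Rows mirroring the published somatic-SV table: sample, chromosomes,
    1-based breakpoint region starts, and the disrupted-gene labels."""
    rows = []
    for ann in annotated:
        c = ann.call
        genes = ", ".join(f"{sym} ({label})" for sym, label in ann.disrupted)
        rows.append({
            "sample": c.sample_id,
            "type": c.type,
            "chrom1": c.region_a[0],
            "breakpoint1": c.region_a[1] + 1,
            "chrom2": c.region_b[0],
            "breakpoint2": c.region_b[1] + 1,
            "disrupted_genes": genes,
        })
    return rows
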