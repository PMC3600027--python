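# Methods

## Coordinate and naming conventions

Internal coordinates are 0-based half-open (BED); human-readable reports
are 1-based inclusive. Chromosome order is *natural* ("2" before "11",
letters after numbers) and is used for anchor canonicalization, call
ordering, and the upstream/downstream assignment in the anchor-correlation
statistic: the canonical first anchor of a pair is the upstream one. A
pure lexicographic order would sort "11" before "2" and contradict the
canonicalization used everywhere else, so it is not offered.

## Insert-size model

The concordance window is estimated from same-chromosome, same-strand
pairs with separations inside a plausibility range (100 bp – 20 kb):
median separation *m*, robust scale σ = 1.4826·MAD floored at 0.05·*m*,
window [*m*−3σ, *m*+3σ]. The floor prevents a degenerate zero-width
window on constant-separation inputs (and caps how aggressively a very
tight library classifies tail pairs as discordant). Every "two insert
lengths" rule in the pipeline uses *m*; the library's fallback model is
(2500, 125, [2125, 2875]), matching a nominal ~2.5 kb library. With
Gaussian insert lengths a ±3σ window leaves ~0.3% of perfectly ordinary
pairs outside it; these surface as single-pair "calls" and are the reason
a support threshold exists at all.

## Classification and clustering

Classification is a total function on canonicalized pairs (order of
tests: chromosome, strand, separation). Insertion-type pairs whose
separation falls below the read length are additionally flagged
`anchors_crossed`: their implied size approaches the full insert and the
size estimate is unreliable, but they are never silently reclassified.

Clustering is single-linkage within a window of one insert length on
*both* anchors, stratified by (type, orientation, chromosome pair).
Single linkage makes the partition independent of input order, and the
call count is monotone non-increasing in the window because the edge set
only grows. Ties are broken by lowest pair id; output ordering and call
ids are deterministic.

Breakpoint regions are *bracketing* intervals: on the side where reads
precede the junction the region is [rightmost read end, + one insert
length]; where reads follow it, [leftmost read start − one insert length,
leftmost read start]. Which side each breakpoint takes follows from the
call type and orientation (e.g. a same-orientation translocation has its
first breakpoint right of its chrA reads and its second left of its chrB
reads). The bracketing choice — rather than an intersection of per-pair
implied intervals — is deliberately conservative: it is guaranteed to
contain the true junction whenever the member pairs do span it, which is
the property the recovery benchmark asserts.

## Filter cascade

Flags are independent (reordering stages changes per-stage attribution in
the report, never the final pass set) and are reported in a fixed order:
`in_control`, `near_excluded`, `known_variant`, `low_support`,
`in_matched_normal`. Call-to-call matching (controls, matched normal) is
type-aware and requires both breakpoint-region midpoints within two insert
lengths. Known-variant records are bare intervals (database dialects carry
no uniform type field), so that match ignores type and compares the call's
two breakpoints to the record's endpoints; translocations never match
interval records. Because the filter report can be read before or after
support thresholds, it exposes both removed fractions
(`removed_fraction_cascade` over the control/excluded/known/normal flags,
`removed_fraction_total` over all flags).

Control and matched-normal call sets are restricted to clusters with at
least 2 supporting pairs (`control_min_support`). A single discordant pair
in a control is indistinguishable from insert-tail noise; subtracting on
it deletes true somatic events essentially at random (~5–8% per call in
simulation), while requiring two pairs leaves the germline-detection rate
effectively unchanged (a germline SV at 8-fold clone coverage has
Poisson(≈7.7) spanning pairs in the normal; P(≤1) ≈ 0.4%).

## Anchor-correlation screen

For translocation and insertion calls, Pearson *r* between upstream and
downstream anchor starts, two-sided p from the t-transform with n−2 df
(a permutation p-value is available for users unwilling to assume
near-normality). Expected sign: positive for same-orientation, negative
for inverted. Verdicts: `indeterminate` below `min_pairs` (default 4) or
on degenerate coordinates; `pass` when the sign matches and p < α
(default 0.05); otherwise `fail`, which sets the `correlation_fail` flag.
α, `min_pairs` and the p-value method are configuration, since only the
statistic itself — not its operating point — is fixed by the design.

## Gene annotation and candidate selection

Exon numbering follows transcript orientation (the genomically last exon
of a minus-strand gene is exon 1). A breakpoint region intersecting an
exon is labeled "exon k" (first intersected exon in transcript order if
several); a region wholly inside the gene body between exons is labeled
"intron k–(k+1)". Selection is strict by default — in/near a gene (two
insert lengths) AND ≥4 supporting pairs AND recurrence within two insert
lengths in another tumor — with a relaxed mode dropping recurrence, since
validated non-recurrent events exist and the strict reading of "all three
criteria" is in tension with them; the switch documents the tension
rather than resolving it. Deeply sequenced samples raise the support
cutoff to 40 and additionally require a passing anchor correlation.
Primer flanks are the 200 bp immediately outside each bracketing region,
truncated at chromosome ends.

## Enrichment statistics

Binomial tails are exact log-space summations of
C(n,k)·p₀^k·(1−p₀)^(n−k) via log-gamma + logsumexp; no normal
approximation anywhere, stable for tails far below 10⁻²⁵⁰. Tests are
one-sided in the direction of the observed deviation. The effective
genome length defaults to 3.0×10⁹ bp — the value that reproduces both
published expected overlap fractions (15% for 456,615,397 bp of
array-painting breakpoint regions; 13.4% for 402,989,448 bp of fragile
sites) — and is configurable. The null-calibration experiment measures
the size of the *enrichment* decision (direction "above" with tail ≤ α),
which is the decision the analysis acts on; rejecting on either
directional tail would have size ≈ 2α by construction.

The gene-universe default for gene-set enrichment is 21,000
protein-coding genes. The packaged census stand-in has 487 members, of
which 4 are the real census hits among the 29 disrupted genes; with any
plausible census size the enrichment p lands at ~1×10⁻³–4×10⁻³.

## Synthetic cohorts

The simulator works at **mapped-coordinate level**: no nucleotide
sequence and no aligner, because the pipeline consumes alignments, not
reads. Platform-specific tag semantics are abstracted into a single
concordance convention — concordant pairs map to the same chromosome and
strand at the model separation.

Defaults define the study conditions: insert median 2500 bp, σ 150 bp,
50 bp reads, 8-fold clone coverage; a tumor, its matched normal and two
healthy controls; three 10 Mb chromosomes with telomere/centromere/gap
excluded tracks (a deliberately scaled-down genome that keeps a full
cohort run at ~1 s while preserving ~10⁵ pairs per sample); 6 deletions
(3–10 kb), 4 insertions (0.5–1.5 kb), 4 inversions (5–50 kb) and 6
translocations per cohort, half germline; half of germline SVs shared
with the controls and half of intrachromosomal germline SVs listed in the
known-variant database; 1% uniform chimeric pairs; 4 repeat-decoy
clusters.

Fragments of Normal(m, σ) length are tiled to the requested clone
coverage; a fragment spanning an implanted junction emits the discordant
pair geometry of its SV type (both junctions for inversions), inverting
the donor→reference map. Insertion sizes must stay below the insert
length minus two read lengths to leave mappable flanks, so large
insertions naturally lose spanning support — the same detectability bound
the real library has.

Decoy clusters have clustered first anchors and second anchors uniform
over **two insert lengths** (5 kb). Wider scatter (a 100 kb repeat) never
survives the both-anchor clustering window, so no call would exist for
the correlation screen to reject; 5 kb is wide enough to destroy the
anchor correlation yet narrow enough to cluster, which is precisely the
artifact class the screen exists for. The anchor-statistic unit tests
additionally exercise the 100 kb geometry on directly constructed calls.

What the simulator does **not** model: sequencing error, colorspace,
mappability structure, coverage waviness, tumor purity/subclonality, or
chromothripsis-specific clustering (a high-count translocation
configuration approximates it). Passing the recovery benchmark therefore
demonstrates the *computational* pipeline — classification geometry,
clustering, filter logic, screening and bookkeeping — not robustness to
alignment artifacts of real data. The simulated discordant fraction
(~1.5%) is deliberately not tuned to the ~8% seen in real tumors, whose
artifact/SV composition is unknown; it only needs to provide a nonzero
filterable background.

## Benchmark scoring

A final call counts as a true somatic discovery when most of its members
were emitted for a somatic implant of the same type *and* both true
breakpoints lie inside the call's bracketing regions (provenance prevents
crediting coincidental overlaps; containment enforces the bracketing
contract). Recall is over somatic implants with ≥4 junction-spanning
tumor pairs. Residual misses are stochastic: a borderline correlation on
a 4–5-member insertion, an insert-length tail dropping one member below
threshold, or a chance match to a control cluster.

## Known limitations

- Breakpoints are bracketed, never base-precise (no split-read
  refinement; the original study resolved exact junctions only by
  capillary sequencing).
- The two-junction geometry of translocations is collapsed to "earlier
  chromosome left of the junction"; the strand-pattern orientation call
  (same/inverted) is correct, but which *side* of each breakpoint the
  derivative retains is not modeled.
- Known-variant matching ignores type; a deletion can be masked by a
  size-matched inversion record in the database.
- The packaged exon structures are synthetic scaffolds anchored at the
  published breakpoint coordinates; they reproduce the published
  disruption labels but are not real transcript models.
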