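"""Breakpoint/region overlap tests, gene-set enrichment and cohort tables.

Overlap significance uses an exact binomial tail computed by log-space term
summation (no normal approximation), stable far below 1e-250: under a
uniform null a breakpoint lands inside a merged region set with probability
p0 = total region length / effective genome length, and k observed hits
among n breakpoints are scored with the one-sided tail in the direction of
the deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .core_io import GenomeModel, RegionSet, ValidationError

LOG10_E = np.log10(np.e)


@dataclass(frozen=True)
class EnrichmentResult:
    n: int
    k: int
    p0: float
    observed_fraction: float
    log10_p: float
    direction: str  # 'above' | 'below'

    @property
    def p_value(self) -> float:
        return 10.0 ** self.log10_p


def expected_overlap_fraction(regions: RegionSet, genome: GenomeModel) -> float:
    """Uniform-null probability that a breakpoint lands in `regions`:
    merged total length over the genome's effective length."""
    if genome.effective_length <= 0:
        raise ValidationError("effective_length must be positive")
    return regions.total_length / genome.effective_length


def _check_np(n: int, k: int, p0: float) -> None:
    if not 0 <= k <= n:
        raise ValidationError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0.0 < p0 < 1.0:
        raise ValidationError(f"p0 must be in (0, 1), got {p0}")


def _log_pmf_terms(n: int, ks: np.ndarray, p0: float) -> np.ndarray:
    ks = ks.astype(float)
    return (
        gammaln(n + 1) - gammaln(ks + 1) - gammaln(n - ks + 1)
        + ks * np.log(p0) + (n - ks) * np.log1p(-p0)
    )


def log_binomial_sf(n: int, k: int, p0: float) -> float:
    """log10 P(X >= k) for X ~ Binomial(n, p0), by exact log-space summation."""
    _check_np(n, k, p0)
    if k == 0:
        return 0.0
    ks = np.arange(k, n + 1)
    return float(logsumexp(_log_pmf_terms(n, ks, p0)) * LOG10_E)


def log_binomial_cdf(n: int, k: int, p0: float) -> float:
    """log10 P(X <= k), same exact summation on the lower tail."""
    _check_np(n, k, p0)
    if k == n:
        return 0.0
    ks = np.arange(0, k + 1)
    return float(logsumexp(_log_pmf_terms(n, ks, p0)) * LOG10_E)


def binomial_enrichment(n: int, k: int, p0: float) -> EnrichmentResult:
    """One-sided exact tail in the direction of the deviation from n*p0."""
    _check_np(n, k, p0)
    observed = k / n if n else 0.0
    if observed >= p0:
        return EnrichmentResult(n, k, p0, observed, log_binomial_sf(n, k, p0),
                                "above")
    return EnrichmentResult(n, k, p0, observed, log_binomial_cdf(n, k, p0),
                            "below")


def breakpoint_overlap_test(breakpoints, regions: RegionSet,
                            genome: GenomeModel) -> EnrichmentResult:
    """Overlap of breakpoints (each translocation contributes BOTH of its
    breakpoints) with a merged region set, against the uniform null."""
    p0 = expected_overlap_fraction(regions, genome)
    chroms = [b[0] for b in breakpoints]
    positions = [b[1] for b in breakpoints]
    n = len(breakpoints)
    k = int(regions.contains_many(chroms, positions).sum()) if n else 0
    return binomial_enrichment(n, k, p0)


def regions_hit(breakpoints, regions: RegionSet) -> int:
    """Number of merged regions containing at least one breakpoint."""
    return regions.count_regions_hit(
        [b[0] for b in breakpoints], [b[1] for b in breakpoints]
    )


def gene_set_enrichment(affected, gene_set, total_genes: int) -> EnrichmentResult:
    """Upper-tail enrichment of a gene set among affected genes.

    n = |affected|, k = |affected ∩ gene_set|, p0 = |gene_set|/total_genes.
    """
    affected = set(affected)
    gene_set = set(gene_set)
    if total_genes < len(gene_set):
        raise ValidationError("total_genes smaller than the gene set")
    n = len(affected)
    k = len(affected & gene_set)
    p0 = len(gene_set) / total_genes
    if k == 0:
        return EnrichmentResult(n, k, p0, 0.0, 0.0, "above")
    return EnrichmentResult(n, k, p0, k / n, log_binomial_sf(n, k, p0), "above")


# ---------------------------------------------------------------------------
# Validation-summary aggregation (per-sample attempted / non-validated /
# constitutional / somatic counts per SV type)
# ---------------------------------------------------------------------------

VALIDATION_COLUMNS = ["sample", "type", "attempted", "non_validated",
                      "constitutional", "somatic"]


def read_validation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(VALIDATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"validation table missing columns {sorted(missing)}")
    return df


def summarize_validation(table: pd.DataFrame) -> dict:
    """Cohort aggregates of a per-sample validation table.

    Each row must satisfy attempted = non_validated + constitutional +
    somatic.  Returns totals, per-type splits, the constitutional fraction of
    validated translocations, the interchromosomal fraction of somatic
    events, and the interchromosomal:intrachromosomal somatic ratio
    (translocations over deletions+inversions).  Ratios over empty
    denominators are NaN.
    """
    for idx, row in table.iterrows():
        if row["attempted"] != row["non_validated"] + row["constitutional"] + row["somatic"]:
            raise ValidationError(
                f"row {idx} ({row['sample']}, {row['type']}): attempted != "
                "non_validated + constitutional + somatic"
            )
    by_type = table.groupby("type")[["attempted", "non_validated",
                                     "constitutional", "somatic"]].sum()
    totals = by_type.sum()

    def _get(type_, col):
        return int(by_type.loc[type_, col]) if type_ in by_type.index else 0

    def _ratio(num, den):
        return num / den if den else float("nan")

    validated_by_type = {
        t: _get(t, "attempted") - _get(t, "non_validated")
        for t in ("deletion", "inversion", "translocation")
    }
    somatic_by_type = {t: _get(t, "somatic")
                       for t in ("deletion", "inversion", "translocation")}
    somatic_total = int(totals["somatic"])
    intra_somatic = somatic_by_type["deletion"] + somatic_by_type["inversion"]
    return {
        "attempted": int(totals["attempted"]),
        "validated": int(totals["attempted"] - totals["non_validated"]),
        "constitutional": int(totals["constitutional"]),
        "somatic": somatic_total,
        "validated_by_type": validated_by_type,
        "somatic_by_type": somatic_by_type,
        "constitutional_by_type": {
            t: _get(t, "constitutional")
            for t in ("deletion", "inversion", "translocation")
        },
        "translocation_constitutional_fraction": _ratio(
            _get("translocation", "constitutional"),
            validated_by_type["translocation"],
        ),
        "germline_deletion_fraction": _ratio(
            _get("deletion", "constitutional"), validated_by_type["deletion"]
        ),
        "interchromosomal_somatic_fraction": _ratio(
            somatic_by_type["translocation"], somatic_total
        ),
        "inter_intra_ratio": _ratio(
            somatic_by_type["translocation"], intra_somatic
        ),
    }


def enrichment_rows_to_tsv(rows: dict, path) -> None:
    """rows: {test name: EnrichmentResult}; TSV export."""
    with open(path, "w") as fh:
        fh.write("test\tn\tk\tp0\tobserved\tlog10_p\tdirection\n")
        for name, r in rows.items():
            fh.write(
                f"{name}\t{r.n}\t{r.k}\t{r.p0:.6g}\t{r.observed_fraction:.6g}\t"
                f"{r.log10_p:.6g}\t{r.direction}\n"
            )


def null_rejection_rate(genome: GenomeModel, regions: RegionSet,
                        n_breakpoints: int, n_replicates: int,
                        alpha: float, rng: np.random.Generator) -> float:
    """Size of the one-sided enrichment decision under a uniform null.

    Draws `n_breakpoints` uniform positions per replicate and counts how
    often the test declares significant enrichment (direction 'above' with
    tail <= alpha).  The enrichment direction is the decision the analysis
    actually acts on; rejecting on either directional tail would double the
    size by construction.
    """
    chroms = list(genome.chromosomes)
    lengths = np.array([genome.chromosomes[c] for c in chroms], float)
    cum = np.cumsum(lengths)
    total = cum[-1]
    p0 = regions.total_length / total
    # critical value: smallest k with upper tail <= alpha
    ks = np.arange(0, n_breakpoints + 1)
    log_terms = _log_pmf_terms(n_breakpoints, ks, p0)
    # log10 upper tails via reverse cumulative logsumexp
    rev = np.logaddexp.accumulate(log_terms[::-1])[::-1] * LOG10_E
    above = np.where(rev <= np.log10(alpha))[0]
    k_crit = int(above[0]) if len(above) else n_breakpoints + 1

    draws = rng.uniform(0, total, size=(n_replicates, n_breakpoints))
    idx = np.searchsorted(cum, draws, side="right")
    offset = draws - np.concatenate(([0.0], cum))[idx]
    rejections = 0
    chrom_arr = np.array(chroms, dtype=object)
    for rep in range(n_replicates):
        hits = regions.contains_many(chrom_arr[idx[rep]],
                                     offset[rep].astype(int))
        if int(hits.sum()) >= k_crit:
            rejections += 1
    return rejections / n_replicates
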