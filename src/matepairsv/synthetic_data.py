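"""Synthetic mate-pair cohorts with implanted rearrangements.

The simulator works at mapped-coordinate level (no nucleotide sequence, no
aligner): it tiles fragments of Normal(median, sigma) length over a donor
genome carrying implanted SVs and emits anchor coordinates in reference
space by inverting the donor->reference map, so fragments spanning an
implanted junction yield discordant pairs whose geometry matches the SV.
Defaults emulate the sequencing design the pipeline targets: ~2.5 kb
inserts (sigma 150), 50 bp reads, 8-fold clone coverage, a tumor with a
patient-matched normal and two healthy controls.  Repeat-decoy clusters
(clustered first anchors, uniformly scattered second anchors) and a uniform
chimeric-pair background provide the artifact classes the filter cascade
and the anchor-correlation screen exist to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_io import GeneModel, GenomeModel, RegionSet, canonicalize_frame


class GenerationError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    # genome
    chromosome_lengths: tuple = (10_000_000, 10_000_000, 10_000_000)
    telomere_length: int = 50_000
    centromere_length: int = 100_000
    n_gaps_per_chrom: int = 1
    gap_length: int = 20_000
    n_genes: int = 30
    # library
    insert_median: float = 2500.0
    insert_sigma: float = 150.0
    read_length: int = 50
    clone_coverage: float = 8.0
    # implanted SVs
    n_deletions: int = 6
    deletion_size: tuple = (3000, 10000)
    n_insertions: int = 4
    insertion_size: tuple = (500, 1500)
    n_inversions: int = 4
    inversion_size: tuple = (5000, 50000)
    n_translocations: int = 6
    germline_fraction: float = 0.5
    common_fraction: float = 0.5   # of germline SVs, shared with controls
    known_db_fraction: float = 0.5  # of intrachromosomal germline SVs, in the
    # known-variant database handed to the filter cascade
    min_sv_separation: int = 100_000
    # artifacts
    n_decoys: int = 4
    decoy_width: float = 5000.0        # two insert lengths: wide enough to be
    # uncorrelated, narrow enough that the cluster holds together
    decoy_support: tuple = (8, 16)
    chimera_rate: float = 0.01
    # cohort
    n_controls: int = 2
    seed: int = 0

    def __post_init__(self):
        for n in (self.n_deletions, self.n_insertions, self.n_inversions,
                  self.n_translocations, self.n_decoys, self.n_controls):
            if n < 0:
                raise ValueError("counts must be >= 0")
        if self.clone_coverage <= 0:
            raise ValueError("clone_coverage must be positive")
        for lo, hi in (self.deletion_size, self.insertion_size,
                       self.inversion_size):
            if not (0 < lo <= hi):
                raise ValueError("size ranges must be positive")


@dataclass
class ImplantedSV:
    """One implanted rearrangement with exact breakpoints.

    For a deletion, (bp_a, bp_b) bound the deleted segment [bp_a, bp_b); an
    insertion has bp_a == bp_b (the insertion site); an inversion's
    breakpoints bound the inverted segment; a translocation joins chrom_a
    left of bp_a to chrom_b at bp_b (reading direction set by orientation).
    """

    sv_id: str
    type: str
    chrom_a: str
    bp_a: int
    chrom_b: str
    bp_b: int
    size: int
    orientation: str  # 'same' | 'inverted'
    status: str  # 'somatic' | 'germline'
    in_controls: bool = False
    in_known_db: bool = False
    spanning: dict = field(default_factory=dict)  # sample -> emitted pair count


@dataclass
class DecoyCluster:
    decoy_id: str
    chrom_a: str
    start_a: int
    chrom_b: str
    start_b: int
    width: float
    n_pairs: int


@dataclass
class SyntheticTruth:
    svs: list
    decoys: list
    known_variants: RegionSet

    def somatic(self) -> list:
        return [s for s in self.svs if s.status == "somatic"]

    def germline(self) -> list:
        return [s for s in self.svs if s.status == "germline"]


def simulate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None):
    """Build a GenomeModel with telomere/centromere/gap excluded intervals
    and synthetic multi-exon genes placed uniformly outside them."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    chromosomes = {
        f"chr{i + 1}": int(length)
        for i, length in enumerate(config.chromosome_lengths)
    }
    excluded = []
    for name, length in chromosomes.items():
        t = min(config.telomere_length, length // 4)
        if t > 0:
            excluded.append((name, 0, t, "telomere"))
            excluded.append((name, length - t, length, "telomere"))
        c = min(config.centromere_length, length // 4)
        if c > 0:
            mid = length // 2
            excluded.append((name, mid - c // 2, mid - c // 2 + c, "centromere"))
        for _ in range(config.n_gaps_per_chrom):
            g = config.gap_length
            start = int(rng.integers(t + g, length - t - 2 * g))
            excluded.append((name, start, start + g, "gap"))
    genome = GenomeModel(chromosomes=chromosomes, excluded=excluded)

    genes = []
    occupied: dict = {name: [] for name in chromosomes}
    for gi in range(config.n_genes):
        placed = False
        for _attempt in range(200):
            chrom = str(rng.choice(list(chromosomes)))
            n_exons = int(rng.integers(4, 11))
            exon_len = rng.integers(150, 301, size=n_exons)
            intron_len = rng.integers(2000, 8001, size=n_exons - 1)
            span = int(exon_len.sum() + intron_len.sum())
            length = chromosomes[chrom]
            start = int(rng.integers(0, max(1, length - span)))
            if genome.near_excluded(chrom, start, start + span, 0):
                continue
            if any(start < e and start + span > s for s, e in occupied[chrom]):
                continue
            exons = []
            pos = start
            for j in range(n_exons):
                exons.append((pos, pos + int(exon_len[j])))
                pos += int(exon_len[j])
                if j < n_exons - 1:
                    pos += int(intron_len[j])
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(f"SYNGENE{gi:03d}", chrom, strand, exons))
            occupied[chrom].append((start, start + span))
            placed = True
            break
        if not placed:
            raise GenerationError(
                f"could not place gene {gi} after bounded retries; "
                "reduce gene count or density"
            )
    return genome, genes


def _free_position(genome: GenomeModel, rng, margin: float,
                   taken: list, min_sep: int, chrom: str | None = None,
                   max_tries: int = 500) -> tuple:
    chroms = list(genome.chromosomes)
    for _ in range(max_tries):
        c = chrom if chrom is not None else str(rng.choice(chroms))
        length = genome.chromosomes[c]
        pos = int(rng.integers(int(margin), int(length - margin)))
        if genome.near_excluded(c, pos, pos + 1, margin):
            continue
        if any(tc == c and abs(tp - pos) < min_sep for tc, tp in taken):
            continue
        return c, pos
    raise GenerationError("could not place SV after bounded retries")


def implant_svs(genome: GenomeModel, config: SimulationConfig,
                rng: np.random.Generator | None = None) -> SyntheticTruth:
    """Implant mutually non-overlapping SVs, each labeled somatic or germline;
    a configurable share of germline SVs is also present in the healthy
    controls and/or listed in the known-variant database."""
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    margin = 4 * config.insert_median + max(
        config.deletion_size[1], config.inversion_size[1]
    )
    taken: list = []
    svs: list = []

    def _status():
        return "germline" if rng.random() < config.germline_fraction else "somatic"

    if config.n_translocations > 0 and len(genome.chromosomes) < 2:
        raise GenerationError("translocations need at least two chromosomes")

    spec = (
        [("deletion", config.deletion_size)] * config.n_deletions
        + [("insertion", config.insertion_size)] * config.n_insertions
        + [("inversion", config.inversion_size)] * config.n_inversions
        + [("translocation", None)] * config.n_translocations
    )
    for i, (type_, size_range) in enumerate(spec):
        status = _status()
        if type_ == "translocation":
            chrom_a, bp_a = _free_position(genome, rng, margin, taken,
                                           config.min_sv_separation)
            others = [c for c in genome.chromosomes if c != chrom_a]
            chrom_b = str(rng.choice(others))
            chrom_b, bp_b = _free_position(genome, rng, margin, taken,
                                           config.min_sv_separation,
                                           chrom=chrom_b)
            # canonical order: earlier chromosome carries breakpoint A
            order = list(genome.chromosomes)
            if order.index(chrom_a) > order.index(chrom_b):
                chrom_a, bp_a, chrom_b, bp_b = chrom_b, bp_b, chrom_a, bp_a
            orientation = "same" if rng.random() < 0.5 else "inverted"
            sv = ImplantedSV(f"sv{i:03d}", type_, chrom_a, bp_a, chrom_b,
                             bp_b, 0, orientation, status)
            taken += [(chrom_a, bp_a), (chrom_b, bp_b)]
        else:
            size = int(rng.integers(size_range[0], size_range[1] + 1))
            chrom, bp = _free_position(genome, rng, margin, taken,
                                       config.min_sv_separation)
            if type_ == "insertion":
                bp_a = bp_b = bp
            else:
                bp_a, bp_b = bp, bp + size
            sv = ImplantedSV(f"sv{i:03d}", type_, chrom, bp_a, chrom, bp_b,
                             size, "same", status)
            taken.append((chrom, bp))
        if status == "germline":
            sv.in_controls = rng.random() < config.common_fraction
            if sv.chrom_a == sv.chrom_b:
                sv.in_known_db = rng.random() < config.known_db_fraction
        svs.append(sv)

    decoys = []
    for d in range(config.n_decoys):
        chrom_a, start_a = _free_position(genome, rng, margin, taken,
                                          config.min_sv_separation)
        others = [c for c in genome.chromosomes if c != chrom_a]
        chrom_b = str(rng.choice(others)) if others else chrom_a
        chrom_b, start_b = _free_position(genome, rng, margin, taken,
                                          config.min_sv_separation,
                                          chrom=chrom_b)
        n_pairs = int(rng.integers(config.decoy_support[0],
                                   config.decoy_support[1] + 1))
        decoys.append(DecoyCluster(f"decoy{d:02d}", chrom_a, start_a, chrom_b,
                                   start_b, config.decoy_width, n_pairs))
        taken += [(chrom_a, start_a), (chrom_b, start_b)]

    known = [
        (s.chrom_a, max(0, s.bp_a - 500), s.bp_b + 500)
        for s in svs if s.in_known_db
    ]
    known_set = RegionSet("known_variants", known) if known else \
        RegionSet("known_variants", [])
    return SyntheticTruth(svs=svs, decoys=decoys, known_variants=known_set)


# ---------------------------------------------------------------------------
# Read-pair emission
# ---------------------------------------------------------------------------

_COLS = ["sample_id", "pair_id", "chrom1", "pos1", "strand1",
         "chrom2", "pos2", "strand2", "source"]


def _fragment_lengths(rng, n, config) -> np.ndarray:
    lo = 2 * config.read_length + 20
    return np.maximum(rng.normal(config.insert_median, config.insert_sigma,
                                 size=n), lo)


def _background(sample: str, genome: GenomeModel, config: SimulationConfig,
                rng) -> pd.DataFrame:
    frames = []
    for chrom, length in genome.chromosomes.items():
        n = int(round(config.clone_coverage * length / config.insert_median))
        ell = _fragment_lengths(rng, n, config)
        x1 = rng.uniform(0, length - ell)
        x2 = x1 + ell - config.read_length
        frames.append(pd.DataFrame({
            "chrom1": chrom, "pos1": x1.astype(np.int64),
            "strand1": "+",
            "chrom2": chrom, "pos2": x2.astype(np.int64),
            "strand2": "+",
            "source": "bg",
        }))
    df = pd.concat(frames, ignore_index=True)
    # uniform chimeric noise: replace the second anchor of a random subset
    n_chim = rng.binomial(len(df), config.chimera_rate)
    if n_chim:
        idx = rng.choice(len(df), size=n_chim, replace=False)
        chroms = list(genome.chromosomes)
        lengths = np.array([genome.chromosomes[c] for c in chroms], float)
        pick = rng.choice(len(chroms), size=n_chim, p=lengths / lengths.sum())
        df.loc[idx, "chrom2"] = np.array(chroms, dtype=object)[pick]
        df.loc[idx, "pos2"] = (rng.uniform(0, lengths[pick])).astype(np.int64)
        df.loc[idx, "strand2"] = np.where(rng.random(n_chim) < 0.5, "+", "-")
        df.loc[idx, "source"] = "chimera"
    df.insert(0, "sample_id", sample)
    return df


def _junction_pairs(sv: ImplantedSV, sample: str, config: SimulationConfig,
                    rng) -> pd.DataFrame:
    """Fragments spanning an implanted junction, anchors in reference space."""
    r = config.read_length
    rows = []
    rate = config.clone_coverage * max(
        0.0, (config.insert_median - 2 * r) / config.insert_median
    )

    def _draw(n):
        ell = _fragment_lengths(rng, n, config)
        return ell

    if sv.type == "deletion":
        n = rng.poisson(rate)
        ell = _draw(n)
        u = rng.uniform(r, ell - r)
        pos1 = sv.bp_a - u
        pos2 = sv.bp_b + (ell - u) - r
        rows.append((pos1, "+", sv.chrom_a, pos2, "+", sv.chrom_b, "j"))
    elif sv.type == "insertion":
        n = rng.poisson(rate)
        ell = _draw(n)
        keep = ell > sv.size + 2 * r
        ell = ell[keep]
        u = rng.uniform(r, ell - sv.size - r)
        pos1 = sv.bp_a - u
        pos2 = sv.bp_a + (ell - u - sv.size) - r
        rows.append((pos1, "+", sv.chrom_a, pos2, "+", sv.chrom_b, "j"))
    elif sv.type == "inversion":
        p, q = sv.bp_a, sv.bp_b
        for side in ("L", "R"):
            n = rng.poisson(rate)
            ell = _draw(n)
            u = rng.uniform(r, ell - r)
            if side == "L":
                pos1 = p - u
                pos2 = q - (ell - u)
                s1, s2 = "+", "-"
            else:
                pos1 = p + u - r
                pos2 = q + (ell - u) - r
                s1, s2 = "-", "+"
            rows.append((pos1, s1, sv.chrom_a, pos2, s2, sv.chrom_b, side))
    else:  # translocation
        n = rng.poisson(rate)
        ell = _draw(n)
        u = rng.uniform(r, ell - r)
        pos1 = sv.bp_a - u
        if sv.orientation == "same":
            pos2 = sv.bp_b + (ell - u) - r
            s2 = "+"
        else:
            pos2 = sv.bp_b - (ell - u)
            s2 = "-"
        rows.append((pos1, "+", sv.chrom_a, pos2, s2, sv.chrom_b, "j"))

    frames = []
    total = 0
    best = 0
    for pos1, s1, c1, pos2, s2, c2, side in rows:
        n = len(np.atleast_1d(pos1))
        total += n
        best = max(best, n)
        frames.append(pd.DataFrame({
            "chrom1": c1, "pos1": np.atleast_1d(pos1).astype(np.int64),
            "strand1": s1,
            "chrom2": c2, "pos2": np.atleast_1d(pos2).astype(np.int64),
            "strand2": s2,
            "source": f"{sv.sv_id}:{side}",
        }))
    # detectability bookkeeping: per-junction spanning count (max over the
    # two junctions of an inversion)
    sv.spanning[sample] = best
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=_COLS[2:])
    df.insert(0, "sample_id", sample)
    return df


def _decoy_pairs(decoy: DecoyCluster, sample: str, config: SimulationConfig,
                 rng) -> pd.DataFrame:
    n = decoy.n_pairs
    pos1 = rng.uniform(decoy.start_a, decoy.start_a + 1.5 * config.insert_median,
                       size=n)
    pos2 = rng.uniform(decoy.start_b, decoy.start_b + decoy.width, size=n)
    df = pd.DataFrame({
        "chrom1": decoy.chrom_a, "pos1": pos1.astype(np.int64), "strand1": "+",
        "chrom2": decoy.chrom_b, "pos2": pos2.astype(np.int64), "strand2": "+",
        "source": decoy.decoy_id,
    })
    df.insert(0, "sample_id", sample)
    return df


def simulate_mate_pairs(genome: GenomeModel, truth: SyntheticTruth,
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> dict:
    """Emit mapped mate pairs for tumor, matched normal and healthy controls.

    Somatic SVs appear in the tumor only; germline SVs also in the matched
    normal; common germline SVs additionally in the controls.  Decoy-repeat
    clusters are emitted in the tumor (they model artifact clusters the
    anchor screen must reject).  Returns {sample_id: DataFrame} with a
    `source` provenance column; identical seed and config give identical
    output.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    samples = ["tumor", "normal"] + [
        f"control{i + 1}" for i in range(config.n_controls)
    ]
    out = {}
    for sample in samples:
        parts = [_background(sample, genome, config, rng)]
        for sv in truth.svs:
            present = (
                sample == "tumor"
                or (sv.status == "germline" and sample == "normal")
                or (sv.status == "germline" and sv.in_controls
                    and sample.startswith("control"))
            )
            if present:
                parts.append(_junction_pairs(sv, sample, config, rng))
            elif sample in ("tumor", "normal") or sample.startswith("control"):
                sv.spanning.setdefault(sample, 0)
        if sample == "tumor":
            for decoy in truth.decoys:
                parts.append(_decoy_pairs(decoy, sample, config, rng))
        df = pd.concat(parts, ignore_index=True)
        df["pair_id"] = [f"{sample}-{i:07d}" for i in range(len(df))]
        df = canonicalize_frame(df)
        out[sample] = df[_COLS].reset_index(drop=True)
    return out


def write_simulation(outdir, genome: GenomeModel, genes, truth: SyntheticTruth,
                     frames: dict) -> None:
    """Write the bundle as plain-text files: chrom sizes, excluded BED, genes
    BED12, known-variant BED, per-sample pairs TSV, truth table."""
    import os

    from .core_io import write_genes

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "genome.chrom.sizes"), "w") as fh:
        for name, length in genome.chromosomes.items():
            fh.write(f"{name}\t{length}\n")
    with open(os.path.join(outdir, "excluded.bed"), "w") as fh:
        for chrom, start, end, label in genome.excluded:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\n")
    write_genes(genes, os.path.join(outdir, "genes.bed"))
    with open(os.path.join(outdir, "known_variants.bed"), "w") as fh:
        for chrom, start, end in truth.known_variants.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")
    for sample, df in frames.items():
        df.drop(columns=["source"]).to_csv(
            os.path.join(outdir, f"{sample}.pairs.tsv"),
            sep="\t", header=False, index=False,
        )
    rows = []
    for sv in truth.svs:
        rows.append({
            "sv_id": sv.sv_id, "type": sv.type,
            "chrom_a": sv.chrom_a, "bp_a": sv.bp_a,
            "chrom_b": sv.chrom_b, "bp_b": sv.bp_b,
            "size": sv.size, "orientation": sv.orientation,
            "status": sv.status, "in_controls": sv.in_controls,
            "in_known_db": sv.in_known_db,
            "tumor_spanning": sv.spanning.get("tumor", 0),
        })
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "truth.tsv"), sep="\t",
                              index=False)


def simulate_cohort(config: SimulationConfig):
    """One-call convenience: genome, genes, truth and per-sample frames."""
    rng = np.random.default_rng(config.seed)
    genome, genes = simulate_genome(config, rng)
    truth = implant_svs(genome, config, rng)
    frames = simulate_mate_pairs(genome, truth, config, rng)
    return genome, genes, truth, frames
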