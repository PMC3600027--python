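"""Domain types, coordinate conventions and readers/writers.

All internal coordinates are 0-based half-open (BED convention); anything
printed for a human (Table-2-style reports) is 1-based inclusive.  An
*anchor* is the mapped location of one read of a mate pair: chromosome,
leftmost aligned base, strand.  Pairs are canonicalized so that anchor1 <=
anchor2 under natural chromosome order (so "2" sorts before "11") then
position; that ordering is used everywhere downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree


class ParseError(ValueError):
    """A malformed line in an input file; message names the line number."""


class ValidationError(ValueError):
    """Input violates a documented invariant (bounds, ordering, schema)."""


class EstimationError(RuntimeError):
    """Too little data to estimate a model; use a fixed fallback instead."""


_NAT_SPLIT = re.compile(r"(\d+)")


def chrom_sort_key(name: str) -> tuple:
    """Natural sort key for chromosome names: "2" < "11" < "X"."""
    parts = _NAT_SPLIT.split(name)
    return tuple(int(p) if p.isdigit() else p for p in parts)


@dataclass(frozen=True)
class Anchor:
    """One mapped read: chromosome, leftmost aligned base (0-based), strand."""

    chrom: str
    start: int
    strand: str  # '+' or '-'

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class MatePairRecord:
    """One mapped fragment with two anchors, canonically ordered."""

    sample_id: str
    pair_id: str
    anchor1: Anchor
    anchor2: Anchor
    read_length: int = 50
    ambiguous: bool = False
    duplicate: bool = False

    def canonicalized(self) -> "MatePairRecord":
        a, b = self.anchor1, self.anchor2
        if (chrom_sort_key(a.chrom), a.start) > (chrom_sort_key(b.chrom), b.start):
            return replace(self, anchor1=b, anchor2=a)
        return self


@dataclass
class InsertSizeModel:
    """Concordance window for mate-pair separations.

    median is the nominal insert length used by every "two insert lengths"
    rule; sigma is a robust scale (1.4826*MAD, floored); [lo, hi] is the
    separation window inside which a same-chromosome, same-strand pair is
    concordant.
    """

    median: float
    sigma: float
    lo: float
    hi: float

    def __post_init__(self):
        if not (self.lo < self.median < self.hi):
            raise ValidationError("insert model requires lo < median < hi")
        if self.sigma <= 0:
            raise ValidationError("sigma must be positive")


DEFAULT_INSERT_MODEL = dict(median=2500.0, sigma=125.0, lo=2125.0, hi=2875.0)


@dataclass
class GenomeModel:
    """Chromosome lengths plus excluded regions and an effective length.

    excluded intervals (gaps, telomeres, centromeres) are 0-based half-open
    and labeled; effective_length is the denominator of uniform-null overlap
    fractions (default 3.0e9, which reproduces both printed expected
    fractions of the region-overlap analyses).
    """

    chromosomes: dict  # name -> length, insertion-ordered
    excluded: list = field(default_factory=list)  # (chrom, start, end, label)
    effective_length: float = 3.0e9

    def __post_init__(self):
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValidationError(f"chromosome {name} has length {length}")
        if self.effective_length <= 0:
            raise ValidationError("effective_length must be positive")
        for chrom, start, end, _label in self.excluded:
            if chrom not in self.chromosomes:
                raise ValidationError(f"excluded interval on unknown chromosome {chrom}")
            if not (0 <= start < end <= self.chromosomes[chrom]):
                raise ValidationError(
                    f"excluded interval {chrom}:{start}-{end} outside chromosome bounds"
                )
        self._trees = None

    @property
    def total_length(self) -> int:
        return int(sum(self.chromosomes.values()))

    def chrom_index(self, name: str) -> int:
        return list(self.chromosomes).index(name)

    def _excluded_trees(self) -> dict:
        if self._trees is None:
            trees: dict = {}
            for chrom, start, end, _label in self.excluded:
                trees.setdefault(chrom, IntervalTree()).addi(start, end)
            self._trees = trees
        return self._trees

    def near_excluded(self, chrom: str, start: int, end: int, distance: float) -> bool:
        """True if [start, end) lies within `distance` bp of any excluded interval."""
        tree = self._excluded_trees().get(chrom)
        if tree is None:
            return False
        return bool(tree.overlap(start - distance, end + distance))


@dataclass
class RegionSet:
    """A named set of merged genomic intervals (0-based half-open)."""

    name: str
    intervals: list  # [(chrom, start, end)], merged and sorted

    def __post_init__(self):
        self.intervals = merge_intervals(self.intervals)
        self._index = None

    @property
    def total_length(self) -> int:
        return int(sum(e - s for _c, s, e in self.intervals))

    def merged(self) -> "RegionSet":
        return RegionSet(self.name, list(self.intervals))

    def validate_against(self, genome: GenomeModel) -> None:
        for chrom, start, end, in self.intervals:
            if chrom not in genome.chromosomes:
                raise ValidationError(f"region on unknown chromosome {chrom}")
            if not (0 <= start < end <= genome.chromosomes[chrom]):
                raise ValidationError(f"region {chrom}:{start}-{end} out of bounds")

    def _build_index(self) -> dict:
        if self._index is None:
            by_chrom: dict = {}
            for chrom, start, end in self.intervals:
                by_chrom.setdefault(chrom, ([], []))
                by_chrom[chrom][0].append(start)
                by_chrom[chrom][1].append(end)
            self._index = {
                c: (np.asarray(s), np.asarray(e)) for c, (s, e) in by_chrom.items()
            }
        return self._index

    def contains(self, chrom: str, pos: int) -> bool:
        return bool(self.contains_many([chrom], [pos])[0])

    def contains_many(self, chroms: Sequence[str], positions) -> np.ndarray:
        """Vectorized point-in-region query (intervals are merged & sorted)."""
        index = self._build_index()
        chroms = np.asarray(chroms, dtype=object)
        positions = np.asarray(positions)
        out = np.zeros(len(positions), dtype=bool)
        for chrom in pd.unique(chroms):
            starts_ends = index.get(chrom)
            if starts_ends is None:
                continue
            starts, ends = starts_ends
            mask = chroms == chrom
            pos = positions[mask]
            i = np.searchsorted(starts, pos, side="right") - 1
            hit = (i >= 0) & (pos < ends[np.clip(i, 0, len(ends) - 1)])
            out[mask] = hit
        return out

    def count_regions_hit(self, chroms: Sequence[str], positions) -> int:
        """Number of merged intervals containing at least one of the points."""
        index = self._build_index()
        hit_keys = set()
        for chrom, pos in zip(chroms, positions):
            starts_ends = index.get(chrom)
            if starts_ends is None:
                continue
            starts, ends = starts_ends
            i = int(np.searchsorted(starts, pos, side="right")) - 1
            if i >= 0 and pos < ends[i]:
                hit_keys.add((chrom, i))
        return len(hit_keys)


def merge_intervals(intervals: Iterable[tuple]) -> list:
    """Merge overlapping/adjacent-overlap intervals; idempotent."""
    out: list = []
    for chrom, start, end in sorted(
        intervals, key=lambda iv: (chrom_sort_key(iv[0]), iv[1], iv[2])
    ):
        if end <= start:
            raise ValidationError(f"interval {chrom}:{start}-{end} has end <= start")
        if out and out[-1][0] == chrom and start <= out[-1][2]:
            prev = out[-1]
            out[-1] = (chrom, prev[1], max(prev[2], end))
        else:
            out.append((chrom, int(start), int(end)))
    return out


@dataclass
class GeneModel:
    """A gene as an ordered exon chain; numbering follows transcript orientation.

    exons are genomic-sorted, non-overlapping (start, end) pairs; for a
    minus-strand gene the genomically last exon is exon 1.
    """

    symbol: str
    chrom: str
    strand: str
    exons: list  # [(start, end)] genomic-sorted

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.symbol}: bad strand {self.strand!r}")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ValidationError(f"gene {self.symbol}: exon {start}-{end} empty")
            if prev_end is not None and start < prev_end:
                raise ValidationError(f"gene {self.symbol}: exons overlap or unsorted")
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def exon_number(self, genomic_index: int) -> int:
        """Transcript-orientation exon number of the i-th genomic exon (0-based i)."""
        if self.strand == "+":
            return genomic_index + 1
        return self.n_exons - genomic_index


# ---------------------------------------------------------------------------
# Mate-pair TSV dialect
#
# sample_id  pair_id  chrom1  pos1  strand1  chrom2  pos2  strand2  [flags]
# pos is the leftmost aligned base, 0-based; flags is a comma-separated
# subset of {ambiguous, duplicate}.
# ---------------------------------------------------------------------------

MATE_PAIR_COLUMNS = [
    "sample_id", "pair_id", "chrom1", "pos1", "strand1",
    "chrom2", "pos2", "strand2",
]


def read_mate_pairs(path, genome: GenomeModel | None = None,
                    read_length: int = 50) -> list:
    """Read the 8/9-column mate-pair TSV into canonicalized records.

    Records flagged ambiguous are dropped; records identical in
    (sample, both anchors) are collapsed to one; anchors are put in
    canonical order.  With a genome attached, unknown chromosomes and
    out-of-bounds positions raise ValidationError.
    """
    records = []
    seen = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (8, 9):
                raise ParseError(f"line {lineno}: expected 8 or 9 fields, got {len(fields)}")
            try:
                sample, pair_id = fields[0], fields[1]
                a1 = Anchor(fields[2], int(fields[3]), fields[4])
                a2 = Anchor(fields[5], int(fields[6]), fields[7])
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            flags = set(fields[8].split(",")) if len(fields) == 9 and fields[8] else set()
            if genome is not None:
                for anc in (a1, a2):
                    if anc.chrom not in genome.chromosomes:
                        raise ValidationError(
                            f"line {lineno}: unknown chromosome {anc.chrom}"
                        )
                    if not (0 <= anc.start < genome.chromosomes[anc.chrom]):
                        raise ValidationError(
                            f"line {lineno}: position {anc.start} outside {anc.chrom}"
                        )
            if "ambiguous" in flags:
                continue
            rec = MatePairRecord(
                sample, pair_id, a1, a2,
                read_length=read_length,
                duplicate="duplicate" in flags,
            ).canonicalized()
            key = (rec.sample_id, rec.anchor1, rec.anchor2)
            if key in seen:
                continue
            seen.add(key)
            records.append(rec)
    return records


def write_mate_pairs(records: Iterable[MatePairRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            flags = ",".join(f for f in ("duplicate",) if getattr(r, f))
            fh.write(
                "\t".join([
                    r.sample_id, r.pair_id,
                    r.anchor1.chrom, str(r.anchor1.start), r.anchor1.strand,
                    r.anchor2.chrom, str(r.anchor2.start), r.anchor2.strand,
                    flags,
                ]) + "\n"
            )


def read_mate_pair_frame(path) -> pd.DataFrame:
    """Read the mate-pair TSV into the columnar in-memory form.

    The frame is the container the pipeline computes on (classification is
    vectorized); `read_mate_pairs` is the row-level API.  Ambiguous rows are
    dropped and (sample, anchors) duplicates collapsed, as for records.
    """
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=MATE_PAIR_COLUMNS + ["flags"], dtype={"flags": str},
    )
    df["flags"] = df["flags"].fillna("")
    df = df[~df["flags"].str.contains("ambiguous")]
    df = canonicalize_frame(df)
    df = df.drop_duplicates(
        subset=["sample_id", "chrom1", "pos1", "strand1", "chrom2", "pos2", "strand2"]
    )
    return df.reset_index(drop=True)


def canonicalize_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Order each row's anchors by natural chromosome order then position."""
    chroms = sorted(set(df["chrom1"]) | set(df["chrom2"]), key=chrom_sort_key)
    rank = {c: i for i, c in enumerate(chroms)}
    k1 = df["chrom1"].map(rank)
    k2 = df["chrom2"].map(rank)
    swap = (k1 > k2) | ((k1 == k2) & (df["pos1"] > df["pos2"]))
    if swap.any():
        df = df.copy()
        for a, b in (("chrom1", "chrom2"), ("pos1", "pos2"), ("strand1", "strand2")):
            av, bv = df.loc[swap, a].copy(), df.loc[swap, b].copy()
            df.loc[swap, a], df.loc[swap, b] = bv.values, av.values
    return df


def frame_to_records(df: pd.DataFrame, read_length: int = 50) -> list:
    return [
        MatePairRecord(
            row.sample_id, str(row.pair_id),
            Anchor(row.chrom1, int(row.pos1), row.strand1),
            Anchor(row.chrom2, int(row.pos2), row.strand2),
            read_length=read_length,
        )
        for row in df.itertuples(index=False)
    ]


def records_to_frame(records: Sequence[MatePairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "pair_id": [r.pair_id for r in records],
            "chrom1": [r.anchor1.chrom for r in records],
            "pos1": [r.anchor1.start for r in records],
            "strand1": [r.anchor1.strand for r in records],
            "chrom2": [r.anchor2.chrom for r in records],
            "pos2": [r.anchor2.start for r in records],
            "strand2": [r.anchor2.strand for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Insert-size estimation
# ---------------------------------------------------------------------------

@dataclass
class InsertEstimationConfig:
    min_candidates: int = 50
    plausible: tuple = (100, 20000)  # separation range for candidate pairs
    sigma_floor_frac: float = 0.05   # floor on sigma, fraction of median
    n_sigma: float = 3.0             # half-width of the concordance window
    fallback: dict = field(default_factory=lambda: dict(DEFAULT_INSERT_MODEL))

    def fallback_model(self) -> InsertSizeModel:
        return InsertSizeModel(**self.fallback)


def estimate_insert_model(records, config: InsertEstimationConfig | None = None
                          ) -> InsertSizeModel:
    """Estimate the concordance window from same-chromosome, same-strand pairs.

    median = median separation of candidate pairs; sigma = 1.4826 * MAD
    floored at sigma_floor_frac * median; window = median +/- n_sigma * sigma.
    Raises EstimationError (suggesting the config fallback) with too few
    candidates.
    """
    config = config or InsertEstimationConfig()
    if isinstance(records, pd.DataFrame):
        same = (records["chrom1"] == records["chrom2"]) & (
            records["strand1"] == records["strand2"]
        )
        sep = (records.loc[same, "pos2"] - records.loc[same, "pos1"]).to_numpy(float)
    else:
        sep = np.array(
            [
                r.anchor2.start - r.anchor1.start
                for r in records
                if r.anchor1.chrom == r.anchor2.chrom
                and r.anchor1.strand == r.anchor2.strand
            ],
            dtype=float,
        )
    lo_p, hi_p = config.plausible
    sep = sep[(sep >= lo_p) & (sep <= hi_p)]
    if len(sep) < config.min_candidates:
        raise EstimationError(
            f"only {len(sep)} candidate pairs (< {config.min_candidates}); "
            "consider the fixed fallback model from the config"
        )
    median = float(np.median(sep))
    mad = float(np.median(np.abs(sep - median)))
    sigma = max(1.4826 * mad, config.sigma_floor_frac * median)
    return InsertSizeModel(
        median=median,
        sigma=sigma,
        lo=median - config.n_sigma * sigma,
        hi=median + config.n_sigma * sigma,
    )


# ---------------------------------------------------------------------------
# BED / BED12 / chrom-sizes readers, BEDPE writer
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict:
    sizes = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                name, length = line.split("\t")[:2]
                sizes[name] = int(length)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    return sizes


def read_bed(path, name: str | None = None) -> RegionSet:
    """Read a BED3+ file into a merged RegionSet (extra columns ignored)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: BED needs >= 3 fields")
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if end <= start:
                raise ValidationError(f"line {lineno}: end <= start")
            intervals.append((chrom, start, end))
    import os
    return RegionSet(name or os.path.basename(str(path)), intervals)


def read_labeled_bed(path) -> list:
    """BED4 -> [(chrom, start, end, label)], e.g. a gap/telomere/centromere track."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: BED needs >= 3 fields")
            label = fields[3] if len(fields) > 3 else "excluded"
            out.append((fields[0], int(fields[1]), int(fields[2]), label))
    return out


def read_genes(path) -> list:
    """Read gene models from BED12 (one transcript per line)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(f"line {lineno}: BED12 needs 12 fields")
            try:
                chrom = fields[0]
                start = int(fields[1])
                symbol = fields[3]
                strand = fields[5]
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                offsets = [int(x) for x in fields[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ParseError(f"line {lineno}: block count mismatch")
            exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
            genes.append(GeneModel(symbol, chrom, strand, exons))
    return genes


def write_genes(genes: Iterable[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            start, end = g.start, g.end
            sizes = ",".join(str(e - s) for s, e in g.exons)
            offsets = ",".join(str(s - start) for s, _e in g.exons)
            fh.write(
                "\t".join([
                    g.chrom, str(start), str(end), g.symbol, "0", g.strand,
                    str(start), str(end), "0", str(g.n_exons), sizes, offsets,
                ]) + "\n"
            )


BEDPE_HEADER = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2", "name", "score",
    "strand1", "strand2", "sample_id", "sv_type", "support", "orientation",
    "filter_flags", "corr_r", "corr_p", "corr_n", "corr_verdict", "members",
]


def write_bedpe(calls, path) -> None:
    """Export calls as BEDPE; columns 7+ carry type, support, orientation,
    filter flags and the anchor-correlation columns."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BEDPE_HEADER) + "\n")
        for c in calls:
            corr = c.correlation
            fh.write(
                "\t".join([
                    c.region_a[0], str(c.region_a[1]), str(c.region_a[2]),
                    c.region_b[0], str(c.region_b[1]), str(c.region_b[2]),
                    c.call_id, str(c.support), ".", ".",
                    c.sample_id, c.type, str(c.support), c.orientation,
                    ",".join(sorted(c.filter_flags)) or ".",
                    f"{corr.r:.6g}" if corr is not None else ".",
                    f"{corr.p_value:.6g}" if corr is not None else ".",
                    str(corr.n) if corr is not None else ".",
                    corr.verdict if corr is not None else ".",
                    ",".join(c.members),
                ]) + "\n"
            )


def read_bedpe(path) -> list:
    """Round-trip reader for `write_bedpe` output."""
    from .sv_calling import SVCall
    from .anchor_stats import CorrelationResult

    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            corr = None
            if f[15] != ".":
                r = float(f[15])
                p = float(f[16])
                n = int(f[17])
                corr = CorrelationResult(
                    r=r, p_value=p, n=n,
                    expected_sign="+", consistent=f[18] == "pass", verdict=f[18],
                )
            calls.append(
                SVCall(
                    call_id=f[6],
                    sample_id=f[10],
                    type=f[11],
                    region_a=(f[0], int(f[1]), int(f[2])),
                    region_b=(f[3], int(f[4]), int(f[5])),
                    orientation=f[13],
                    support=int(f[12]),
                    members=f[19].split(",") if f[19] else [],
                    filter_flags=set() if f[14] == "." else set(f[14].split(",")),
                    correlation=corr,
                )
            )
    return calls
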