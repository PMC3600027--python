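"""Discordant-pair classification and greedy clustering into SV calls.

A mate pair is classified by comparing its mapped geometry against the
insert-size model: different chromosomes -> translocation; same chromosome
but opposite strands -> inversion; same chromosome and strand with a
separation outside the concordance window -> deletion (too far) or
insertion (too close); otherwise concordant.  Same-type pairs at the same
chromosomal position are greedily clustered (single linkage, both anchors
within one insert length by default) into SVCall objects whose breakpoint
regions bracket, rather than pinpoint, the true junctions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    InsertSizeModel,
    MatePairRecord,
    chrom_sort_key,
    records_to_frame,
)

SV_TYPES = ("deletion", "insertion", "inversion", "translocation")


@dataclass(frozen=True)
class PairClass:
    """Classification of one mate pair.

    implied_size is present only for deletion/insertion and equals
    |separation - median|.  anchors_crossed flags insertion-like pairs whose
    anchors (nearly) overlap -- implied size approaching the full insert --
    where the size estimate is unreliable.
    """

    category: str
    implied_size: float | None = None
    anchors_crossed: bool = False


def classify_pair(record: MatePairRecord, model: InsertSizeModel) -> PairClass:
    """Classify a single canonicalized mate pair (total on valid records)."""
    a, b = record.anchor1, record.anchor2
    if a.chrom != b.chrom:
        return PairClass("translocation")
    if a.strand != b.strand:
        return PairClass("inversion")
    sep = b.start - a.start
    if sep > model.hi:
        return PairClass("deletion", implied_size=sep - model.median)
    if sep < model.lo:
        return PairClass(
            "insertion",
            implied_size=model.median - sep,
            anchors_crossed=sep < record.read_length,
        )
    return PairClass("concordant")


def classify_frame(df: pd.DataFrame, model: InsertSizeModel,
                   read_length: int = 50) -> pd.DataFrame:
    """Vectorized classification; adds category/implied_size/anchors_crossed."""
    df = df.copy()
    sep = (df["pos2"] - df["pos1"]).to_numpy(float)
    diff_chrom = (df["chrom1"] != df["chrom2"]).to_numpy()
    diff_strand = (df["strand1"] != df["strand2"]).to_numpy()
    category = np.full(len(df), "concordant", dtype=object)
    category[sep > model.hi] = "deletion"
    category[sep < model.lo] = "insertion"
    category[diff_strand] = "inversion"
    category[diff_chrom] = "translocation"
    implied = np.full(len(df), np.nan)
    is_del = category == "deletion"
    is_ins = category == "insertion"
    implied[is_del] = sep[is_del] - model.median
    implied[is_ins] = model.median - sep[is_ins]
    df["category"] = category
    df["implied_size"] = implied
    df["anchors_crossed"] = is_ins & (sep < read_length)
    return df


@dataclass
class SVCall:
    """A clustered rearrangement with bracketing breakpoint regions."""

    call_id: str
    sample_id: str
    type: str
    region_a: tuple  # (chrom, start, end)
    region_b: tuple
    orientation: str  # 'same' or 'inverted'
    support: int
    members: list  # pair_ids
    filter_flags: set = field(default_factory=set)
    correlation: object = None  # CorrelationResult, set by anchor screening

    def __post_init__(self):
        if self.support != len(self.members) or self.support < 1:
            raise ValueError("support must equal |members| >= 1")
        if (self.type == "translocation") != (self.region_a[0] != self.region_b[0]):
            raise ValueError("translocation iff cross-chromosome regions")

    @property
    def passes(self) -> bool:
        return not self.filter_flags


@dataclass
class ClusterConfig:
    """cluster_window defaults to one insert length (the clone-length
    resolution of the library); orientation-stratified single linkage."""

    cluster_window: float | None = None

    def window(self, model: InsertSizeModel) -> float:
        return self.cluster_window if self.cluster_window is not None else model.median


def _orientation(type_: str, strand1: str, strand2: str) -> str:
    """Junction-side orientation label used for clustering stratification and
    the anchor-correlation sign rule.

    For translocations, equal strands mean the joined segments retain their
    reference orientation ('same', expected positive anchor correlation) and
    unequal strands mean one segment is flipped ('inverted', expected
    negative).  Inversions always have unequal strands; the two strand
    patterns distinguish the two junctions of an inverted segment and are
    kept apart so the junctions cluster separately.
    """
    if type_ in ("deletion", "insertion"):
        return "same"
    if type_ == "translocation":
        return "same" if strand1 == strand2 else "inverted"
    # inversion: (+,-) -> 'same' pattern (left junction), (-,+) -> 'inverted'
    return "same" if (strand1, strand2) == ("+", "-") else "inverted"


# Which side of its supporting reads each breakpoint lies on, by
# (type, orientation): 'R' = junction right of the reads (region starts at
# the rightmost read end), 'L' = junction left of the reads.
_FACING = {
    ("deletion", "same"): ("R", "L"),
    ("insertion", "same"): ("R", "L"),
    ("inversion", "same"): ("R", "R"),
    ("inversion", "inverted"): ("L", "L"),
    ("translocation", "same"): ("R", "L"),
    ("translocation", "inverted"): ("R", "R"),
}


def _bracket(face: str, starts: np.ndarray, read_length: int, width: float,
             chrom: str) -> tuple:
    if face == "R":
        lo = int(starts.max()) + read_length
        hi = int(lo + width)
    else:
        hi = int(starts.min())
        lo = int(max(0, hi - width))
    if hi <= lo:
        hi = lo + 1
    return (chrom, lo, hi)


def _single_linkage(p1: np.ndarray, p2: np.ndarray, window: float) -> list:
    """Connected components under |dp1| <= w and |dp2| <= w (single linkage).

    Input is sorted by p1; a windowed scan over the p1-sorted order finds all
    edges because any edge has p1-gap <= w.
    """
    n = len(p1)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        j = i + 1
        while j < n and p1[j] - p1[i] <= window:
            if abs(p2[j] - p2[i]) <= window:
                union(i, j)
            j += 1
    comps: dict = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(i)
    return list(comps.values())


def cluster_events(classified: pd.DataFrame, model: InsertSizeModel,
                   config: ClusterConfig | None = None,
                   read_length: int = 50) -> list:
    """Greedy single-linkage clustering of discordant pairs into SV calls.

    `classified` is the output of `classify_frame` for ONE sample.  Pairs are
    stratified by (type, orientation, chromosome pair); within a stratum a
    pair joins a cluster when both anchors lie within the cluster window of a
    member's anchors (transitively).  Output is deterministically ordered by
    (chromA, startA, chromB, startB); ties inside a cluster are broken by
    lowest pair_id.
    """
    config = config or ClusterConfig()
    window = config.window(model)
    disc = classified[classified["category"] != "concordant"]
    calls = []
    if len(disc) == 0:
        return calls
    samples = disc["sample_id"].unique()
    if len(samples) != 1:
        raise ValueError("cluster_events expects pairs from one sample")
    sample = samples[0]

    disc = disc.assign(
        orientation=[
            _orientation(t, s1, s2)
            for t, s1, s2 in zip(disc["category"], disc["strand1"], disc["strand2"])
        ]
    )
    for (type_, orient, c1, c2), group in disc.groupby(
        ["category", "orientation", "chrom1", "chrom2"], sort=False
    ):
        group = group.sort_values(["pos1", "pos2", "pair_id"], kind="mergesort")
        p1 = group["pos1"].to_numpy(float)
        p2 = group["pos2"].to_numpy(float)
        ids = group["pair_id"].astype(str).to_numpy()
        for comp in _single_linkage(p1, p2, window):
            comp = sorted(comp)
            face_a, face_b = _FACING[(type_, orient)]
            region_a = _bracket(face_a, p1[comp], read_length, model.median, c1)
            region_b = _bracket(face_b, p2[comp], read_length, model.median, c2)
            members = sorted(ids[comp])
            calls.append(
                SVCall(
                    call_id="",
                    sample_id=sample,
                    type=type_,
                    region_a=region_a,
                    region_b=region_b,
                    orientation=orient,
                    support=len(members),
                    members=members,
                )
            )
    calls.sort(
        key=lambda c: (
            chrom_sort_key(c.region_a[0]), c.region_a[1],
            chrom_sort_key(c.region_b[0]), c.region_b[1], c.type,
        )
    )
    for i, c in enumerate(calls):
        c.call_id = f"{sample}_{c.type[:3]}_{i:04d}"
    return calls


def call_sample(records, model: InsertSizeModel,
                config: ClusterConfig | None = None,
                read_length: int = 50) -> list:
    """Classify + cluster convenience wrapper; accepts records or a frame."""
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = records_to_frame(records)
    classified = classify_frame(frame, model, read_length=read_length)
    return cluster_events(classified, model, config, read_length=read_length)
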