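"""Regenerate the synthetic gene and census fixtures under src/matepairsv/data/.

The exon structures are SYNTHETIC: real RefSeq transcript models are not
shipped with the package.  Each gene is laid out deterministically so that
every printed breakpoint in the somatic-SV fixture lands in the printed
exon or intron, with exon numbering following transcript orientation.
Run from the repository root:  python scripts/build_gene_fixture.py
"""

from __future__ import annotations

import sys
from collections import defaultdict

sys.path.insert(0, "src")

from matepairsv.annotate_select import _label_region  # noqa: E402
from matepairsv.core_io import GeneModel, write_genes  # noqa: E402
from matepairsv.datasets import load_table2, parse_gene_labels  # noqa: E402

EXON_W = 1000
GAP_MIN = 5000
PAD = 500

MINUS_STRAND = {"SKA3", "RORA", "H2AFY", "KIAA1217", "EPHA5"}

REAL_CENSUS_HITS = ["CHN1", "CLTC", "DDX10", "MECOM"]
CENSUS_SIZE = 487


def parse_label(label: str):
    if label.startswith("exon "):
        return "exon", int(label.split()[1])
    body = label[len("intron "):]
    k = int(body.split("–")[0])
    return "intron", k  # between transcript exons k and k+1


def build_gene(symbol, chrom, strand, constraints):
    """constraints: [(pos0, kind, k)] with k in transcript numbering."""
    n = max((k + 1) if kind == "intron" else k for _p, kind, k in constraints) + 1
    exon_contains = defaultdict(list)
    gap_contains = defaultdict(list)  # gap j: between genomic exons j, j+1
    for pos, kind, k in constraints:
        if kind == "exon":
            g = k if strand == "+" else n - k + 1
            exon_contains[g].append(pos)
        else:
            j = k if strand == "+" else n - k
            gap_contains[j].append(pos)
    all_pos = [p for p, _k, _n in constraints]
    cursor = max(0, min(all_pos) - n * (EXON_W + GAP_MIN) - 1000)
    exons = []
    for g in range(1, n + 1):
        if g in exon_contains:
            lo = min(exon_contains[g]) - PAD
            hi = max(exon_contains[g]) + PAD
            if lo < cursor:
                raise ValueError(f"{symbol}: infeasible layout at exon {g}")
            exons.append((lo, hi))
        else:
            exons.append((cursor, cursor + EXON_W))
        end = exons[-1][1]
        cursor = end + GAP_MIN
        if g in gap_contains:
            ps = gap_contains[g]
            if end > min(ps) - 100:
                raise ValueError(f"{symbol}: exon {g} overruns its intron constraint")
            cursor = max(cursor, max(ps) + PAD)
    return GeneModel(symbol, chrom, strand, exons)


def main():
    table2 = load_table2()
    constraints = defaultdict(list)  # symbol -> (chrom, [(pos0, kind, k)])
    chrom_of = {}
    for row in table2.itertuples(index=False):
        for chrom, pos, cell in ((row.chrom1, row.pos1, row.genes1),
                                 (row.chrom2, row.pos2, row.genes2)):
            for sym, label in parse_gene_labels(cell):
                kind, k = parse_label(label)
                constraints[sym].append((int(pos) - 1, kind, k))
                if sym in chrom_of and chrom_of[sym] != chrom:
                    raise ValueError(f"{sym} on two chromosomes")
                chrom_of[sym] = chrom

    genes = []
    for sym in sorted(constraints):
        strand = "-" if sym in MINUS_STRAND else "+"
        genes.append(build_gene(sym, chrom_of[sym], strand, constraints[sym]))

    # verify: every constraint position annotates to its printed label
    by_symbol = {g.symbol: g for g in genes}
    for sym, cons in constraints.items():
        g = by_symbol[sym]
        for pos, kind, k in cons:
            got = _label_region(g, pos, pos + 1)
            want = f"exon {k}" if kind == "exon" else f"intron {k}–{k + 1}"
            assert got == want, f"{sym}@{pos}: got {got!r}, want {want!r}"
    # verify: no gene accidentally spans an unannotated breakpoint
    for row in table2.itertuples(index=False):
        for chrom, pos, cell in ((row.chrom1, row.pos1, row.genes1),
                                 (row.chrom2, row.pos2, row.genes2)):
            annotated = {sym for sym, _l in parse_gene_labels(cell)}
            for g in genes:
                if g.chrom == chrom and g.start <= int(pos) - 1 < g.end:
                    assert g.symbol in annotated, (
                        f"{g.symbol} unexpectedly spans {chrom}:{pos}")

    write_genes(genes, "src/matepairsv/data/table2_genes.synthetic.bed")
    print(f"wrote {len(genes)} synthetic gene models")

    census = list(REAL_CENSUS_HITS) + [
        f"CGCSYN{i:04d}" for i in range(CENSUS_SIZE - len(REAL_CENSUS_HITS))
    ]
    with open("src/matepairsv/data/cancer_gene_census.synthetic.txt", "w") as fh:
        fh.write("\n".join(census) + "\n")
    print(f"wrote synthetic census of {len(census)} symbols")


if __name__ == "__main__":
    main()
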