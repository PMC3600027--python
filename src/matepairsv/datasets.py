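"""Packaged fixture tables and their loaders.

Fixtures: the cohort validation-summary table (per-sample attempted /
non-validated / constitutional / somatic counts for deletions, inversions
and translocations), the somatic-SV table with printed breakpoints and
disrupted-gene labels, a synthetic exon-structure fixture reproducing those
labels at the printed hg19 coordinates (real RefSeq structures are not
redistributable here; the file is marked synthetic), a synthetic
cancer-gene-census list, and hg19 chromosome sizes.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .core_io import GenomeModel, read_chrom_sizes, read_genes


def _data_path(name: str):
    return resources.files("matepairsv").joinpath("data", name)


def load_table1() -> pd.DataFrame:
    """Per-sample validation counts (schema of enrichment_stats
    summarize_validation)."""
    with resources.as_file(_data_path("table1_validation.csv")) as p:
        return pd.read_csv(p)


def load_table2() -> pd.DataFrame:
    """Somatic-SV table: type, sample, the two 1-based breakpoints, and the
    disrupted-gene labels assigned per breakpoint ("SYMBOL|label", ';'
    separated; empty when the breakpoint disrupts no gene)."""
    with resources.as_file(_data_path("table2_somatic_svs.tsv")) as p:
        df = pd.read_csv(
            p, sep="\t",
            names=["type", "sample", "chrom1", "pos1", "chrom2", "pos2",
                   "genes1", "genes2"],
            header=0, dtype={"chrom1": str, "chrom2": str},
        )
    df["genes1"] = df["genes1"].fillna("")
    df["genes2"] = df["genes2"].fillna("")
    return df


def parse_gene_labels(cell: str) -> list:
    """'SYM|exon 7;SYM2|intron 1–2' -> [(symbol, label), ...]."""
    if not cell:
        return []
    out = []
    for item in cell.split(";"):
        sym, label = item.split("|")
        out.append((sym, label))
    return out


def distinct_disrupted_genes(table2: pd.DataFrame) -> set:
    symbols = set()
    for col in ("genes1", "genes2"):
        for cell in table2[col]:
            symbols.update(sym for sym, _label in parse_gene_labels(cell))
    return symbols


def translocation_breakpoints(table2: pd.DataFrame) -> list:
    """All breakpoints of the translocation rows, both ends, as 0-based
    (chrom, pos)."""
    rows = table2[table2["type"] == "translocation"]
    bps = []
    for row in rows.itertuples(index=False):
        bps.append((row.chrom1, int(row.pos1) - 1))
        bps.append((row.chrom2, int(row.pos2) - 1))
    return bps


def load_table2_genes() -> list:
    """Synthetic exon structures reproducing the somatic-SV table's
    disrupted-gene labels at the printed coordinates."""
    with resources.as_file(_data_path("table2_genes.synthetic.bed")) as p:
        return read_genes(p)


def load_cancer_census() -> set:
    """Synthetic census stand-in: the 4 real census members among the
    29 disrupted genes plus placeholder symbols up to a census of 487."""
    with resources.as_file(_data_path("cancer_gene_census.synthetic.txt")) as p:
        with open(p) as fh:
            return {line.strip() for line in fh if line.strip()}


def load_hg19_genome(effective_length: float = 3.0e9) -> GenomeModel:
    with resources.as_file(_data_path("hg19.chrom.sizes.tsv")) as p:
        sizes = read_chrom_sizes(p)
    return GenomeModel(chromosomes=sizes, effective_length=effective_length)
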