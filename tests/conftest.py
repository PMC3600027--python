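import pytest

from matepairsv.core_io import Anchor, GenomeModel, InsertSizeModel, MatePairRecord


@pytest.fixture
def model():
    """The default 2.5 kb library model: sigma floored at 125, 3-sigma window."""
    return InsertSizeModel(median=2500.0, sigma=125.0, lo=2125.0, hi=2875.0)


@pytest.fixture
def genome():
    return GenomeModel(
        chromosomes={"chr1": 10_000_000, "chr2": 10_000_000},
        excluded=[
            ("chr1", 0, 50_000, "telomere"),
            ("chr1", 4_950_000, 5_050_000, "centromere"),
            ("chr1", 9_950_000, 10_000_000, "telomere"),
            ("chr2", 0, 50_000, "telomere"),
            ("chr2", 4_950_000, 5_050_000, "centromere"),
            ("chr2", 9_950_000, 10_000_000, "telomere"),
        ],
    )


def make_pair(pos1, pos2, chrom1="chr1", chrom2=None, strand1="+", strand2="+",
              sample="s1", pair_id="p0", read_length=50):
    return MatePairRecord(
        sample, pair_id,
        Anchor(chrom1, pos1, strand1),
        Anchor(chrom2 or chrom1, pos2, strand2),
        read_length=read_length,
    ).canonicalized()
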