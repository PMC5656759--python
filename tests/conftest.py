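"""Shared fixtures: a full-size genome, compact fast specs, the packaged table."""

import pytest

from polycipi import seqio
from polycipi.synthetic import GenomeSpec, Orf2bSpec, generate_genome

#: Compact architecture for fast sweeps: same five-ORF shape, ~4.3 kb,
#: with the long ORF still covering more than half of the genome.
COMPACT_LENS = {"ORF1": 300, "ORF2": 450, "ORF3": 300, "ORF4": 450, "ORF5": 2400}


def compact_spec(seed: int, genus: str = "Sopolycivirus", **kw) -> GenomeSpec:
    base = dict(
        utr5_len=100,
        utr3_len=100,
        igr_len=250,
        orf_lens=dict(COMPACT_LENS),
        seed=seed,
    )
    if genus == "Sopolycivirus":
        base["orf2b"] = Orf2bSpec(offset=4, length=210)
    elif genus == "Hupolycivirus":
        base["orf2b"] = None
    elif genus == "Chipolycivirus":
        base["orf2b"] = None
        base["motif6_variant"] = "ADD"
    else:
        raise ValueError(genus)
    base.update(kw)
    return GenomeSpec(**base)


@pytest.fixture(scope="session")
def sinv2_like():
    """One full-size (~11.3 kb) genome with ground truth, SINV-2-shaped."""
    return generate_genome(GenomeSpec(seed=7))


@pytest.fixture(scope="session")
def table_rows():
    return seqio.read_layout_table()
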