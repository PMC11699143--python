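import numpy as np
import pandas as pd
import pytest

from wrapseq import FragmentSet, GenomeLayout


@pytest.fixture
def toy_layout():
    """Two small chromosomes with 1 kb bins; chr1 ends in a partial bin."""
    return GenomeLayout([("chr1", 5500), ("chr2", 3000)], 1000)


@pytest.fixture
def make_frags(toy_layout):
    """Build a FragmentSet from (chrom, start, end) tuples on the toy layout."""

    def _make(intervals, layout=None):
        df = pd.DataFrame(intervals, columns=["chrom", "start", "end"])
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        return FragmentSet(df, layout or toy_layout, provenance="test")

    return _make


def frags_from_lengths(layout, chrom, lengths, start=0, gap=300):
    """Non-overlapping fragments of the given lengths laid end to end."""
    rows, pos = [], start
    for L in lengths:
        rows.append((chrom, pos, pos + L))
        pos += L + gap
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return FragmentSet(df, layout, provenance="lengths")
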