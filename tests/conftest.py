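import numpy as np
import pytest

from methaplo.io import MethylationHaplotype


def haps_from_strings(calls_list, positions=None, chrom="chr1", **kw):
    """Build haplotypes at shared positions from bare call strings."""
    if positions is None:
        length = max(len(s) for s in calls_list)
        positions = tuple(10 * (i + 1) for i in range(length))
    out = []
    for i, calls in enumerate(calls_list):
        out.append(
            MethylationHaplotype(
                chrom, tuple(positions[: len(calls)]), calls, read_id=f"r{i}", **kw
            )
        )
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
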