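import numpy as np
import pytest

from paleomito import simulate
from paleomito.alignment import AlignedFragment
from paleomito._seq import complement, decode, encode


@pytest.fixture(scope="session")
def ref_small():
    """Short circular reference for fast unit tests."""
    return simulate.simulate_reference(2000, gc=0.44, seed=42)


@pytest.fixture(scope="session")
def ref_mt():
    """rCRS-length circular reference."""
    return simulate.simulate_reference(16569, gc=0.44, seed=7)


def make_fragment(
    ref,
    start: int,
    length: int,
    strand: str = "+",
    mapq: int = 60,
    frag_id: str = "f",
    substitutions: dict[int, str] | None = None,
):
    """Build a fragment matching the reference except at ``substitutions``
    (read-orientation position -> read-orientation base)."""
    L = len(ref.sequence)
    idx = (start + np.arange(length)) % L
    template = ref.encoded[idx]
    read = complement(template)[::-1] if strand == "-" else template.copy()
    if substitutions:
        read = read.copy()
        for pos, base in substitutions.items():
            read[pos] = encode(base)[0]
    if strand == "+":
        obs_base = read
        obs_read = np.arange(length)
    else:
        obs_base = complement(read)[::-1]
        obs_read = np.arange(length - 1, -1, -1)
    return AlignedFragment(
        id=frag_id,
        ref_start=start,
        strand=strand,
        mapq=mapq,
        read_length=length,
        obs_ref_pos=idx,
        obs_read_pos=obs_read,
        obs_base=obs_base,
        ref_span=length,
        read_seq=decode(read),
    )
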