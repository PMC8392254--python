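import numpy as np
import pytest

from mitotxscape.annotation import GeneFeature, GenomeRef
from mitotxscape.coverage import StrandedDepth


@pytest.fixture
def small_ref():
    return GenomeRef("mt", 1000)


@pytest.fixture
def uniform_depth(small_ref):
    """Depth 5 on both strands everywhere."""
    return StrandedDepth(small_ref,
                         np.full(small_ref.length, 5, dtype=np.int64),
                         np.full(small_ref.length, 5, dtype=np.int64))


@pytest.fixture
def two_exon_gene():
    return GeneFeature(gene_id="gX", strand="+", exons=[(100, 200), (300, 450)])


def random_depth(rng, length=400, max_depth=6, masked=()):
    ref = GenomeRef("rnd", length, masked_intervals=list(masked))
    return StrandedDepth(ref,
                         rng.integers(0, max_depth, size=length),
                         rng.integers(0, max_depth, size=length))
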