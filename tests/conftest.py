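import numpy as np
import pytest

from transcensus.io_formats import Contig


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def random_contigs(rng):
    """Thirty random 600-bp contigs (no planted structure)."""
    bases = np.array(list("ACGT"))
    return [
        Contig(id=f"c{i}", sequence="".join(bases[rng.integers(0, 4, 600)]))
        for i in range(30)
    ]
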