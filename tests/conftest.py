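import numpy as np
import pytest

from pseudodrift import consensus
from pseudodrift.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def similipal_callsets():
    """The packaged noninvasive call table and its individual grouping."""
    return consensus.read_callsets(consensus.similipal_calls_path())


@pytest.fixture()
def toy_matrix():
    """Two populations x four individuals at two loci, fully called."""
    codes = np.array(
        [[0, 1], [1, 1], [0, 0], [1, 2], [2, 1], [2, 2], [1, 2], [2, 1]], dtype=float
    )
    return GenotypeMatrix(
        [f"s{i}" for i in range(8)],
        ["l1", "l2"],
        codes,
        np.array(["A"] * 4 + ["B"] * 4, dtype=object),
    )
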