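import numpy as np
import pandas as pd
import pytest

from genocurate.geno_io import MISSING, GenotypeMatrix, SITE_COLUMNS


def make_matrix(calls, ids=None, chrom="1A", start_pos=100, step=50):
    """GenotypeMatrix from a nested list / array of calls."""
    calls = np.asarray(calls, dtype=np.int8)
    n, l = calls.shape
    ids = ids or [f"ACC{i + 1:03d}" for i in range(n)]
    refalt = [("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")]
    rows = [(chrom, start_pos + j * step, *refalt[j % 4], f"S{j + 1}")
            for j in range(l)]
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    return GenotypeMatrix(ids, sites, calls)


@pytest.fixture
def toy_matrix():
    """3 accessions x 4 sites with one het and one missing call."""
    return make_matrix([
        [0, 1, 2, 0],
        [0, 2, 2, MISSING],
        [2, 2, 0, 0],
    ])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
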