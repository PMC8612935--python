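import numpy as np
import pandas as pd
import pytest

import gamforge as gf
from gamforge.io_formats import SegregationTable, make_windows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_segregation(rng, n_windows=50, n_samples=40, p=0.3, chrom="chr1", bin_size=50_000):
    windows = make_windows({chrom: n_windows * bin_size}, bin_size)
    detection = rng.random((n_windows, n_samples)) < p
    samples = [f"S{j}" for j in range(n_samples)]
    return SegregationTable(windows, samples, detection, bin_size)


@pytest.fixture
def tiny_seg():
    windows = pd.DataFrame(
        dict(chrom=["chr1", "chr1", "chr1"], start=[0, 50_000, 100_000],
             stop=[50_000, 100_000, 150_000])
    )
    detection = np.array([[1, 0], [1, 1], [0, 1]], dtype=bool)
    return SegregationTable(windows, ["A", "B"], detection, 50_000)


@pytest.fixture(scope="session")
def sliced_run():
    """One simulated GAM run at study conditions (no compartments), reused
    by I/O, QC and topology tests."""
    ens = gf.generate_ensemble(gf.study_config(with_compartments=False), 300, seed=1)
    seg = gf.slice_sample(ens, gf.SliceSpec(n_samples=500, seed=2))
    return ens, seg


@pytest.fixture(scope="session")
def compartment_run():
    """A simulated run with planted compartments and its GC track."""
    ens = gf.generate_ensemble(gf.study_config(), 300, seed=3)
    seg = gf.slice_sample(ens, gf.SliceSpec(n_samples=500, seed=4))
    return ens, seg
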