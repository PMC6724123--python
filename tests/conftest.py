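import numpy as np
import pandas as pd
import pytest

from coldcascade.io_formats import CountMatrix, SampleDesign


@pytest.fixture(scope="session")
def design() -> SampleDesign:
    return SampleDesign.canonical()


@pytest.fixture()
def small_counts(design) -> CountMatrix:
    """10 genes x 24 samples of moderate Poisson-ish counts."""
    rng = np.random.default_rng(0)
    values = rng.poisson(50, size=(10, design.n_samples))
    genes = [f"g{i}" for i in range(10)]
    return CountMatrix(pd.DataFrame(values, index=genes, columns=design.sample_ids))
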