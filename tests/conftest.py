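import numpy as np
import pandas as pd
import pytest

from heterosis.io import CountMatrix, SampleDesign


@pytest.fixture
def small_counts() -> CountMatrix:
    """12 samples, 3 groups x 4 replicates, deterministic small counts."""
    rng = np.random.default_rng(123)
    genes = [f"g{i}" for i in range(1, 31)]
    samples = [f"{g}_r{i}" for g in ("TJ", "LC", "LT") for i in range(1, 5)]
    data = rng.poisson(50, size=(len(genes), len(samples)))
    return CountMatrix(pd.DataFrame(data, index=genes, columns=samples))


@pytest.fixture
def small_design() -> SampleDesign:
    rows = [
        {"sample": f"{g}_r{i}", "group": g, "role": role}
        for g, role in (("TJ", "parent1"), ("LC", "parent2"), ("LT", "hybrid"))
        for i in range(1, 5)
    ]
    return SampleDesign(pd.DataFrame.from_records(rows))


def make_counts(array, genes=None, samples=None) -> CountMatrix:
    array = np.asarray(array)
    genes = genes or [f"g{i}" for i in range(1, array.shape[0] + 1)]
    samples = samples or [f"s{i}" for i in range(1, array.shape[1] + 1)]
    return CountMatrix(pd.DataFrame(array, index=genes, columns=samples))
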