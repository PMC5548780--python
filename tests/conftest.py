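import warnings

import numpy as np
import pandas as pd
import pytest

from snucseq.io import ExpressionMatrix, SampleTable
from snucseq.simulate import SimConfig, simulate_nuclei

warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def default_sim():
    """One default simulated experiment shared across tests."""
    return simulate_nuclei(SimConfig(seed=11))


@pytest.fixture()
def toy_matrix():
    """Tiny deterministic FPKM matrix with a count layer."""
    fpkm = pd.DataFrame(
        [[10.0, 5.0, 0.0, 8.0],
         [4.0, 4.0, 4.0, 4.0],
         [0.5, 1.0, 2.0, 3.999],
         [100.0, 90.0, 80.0, 70.0]],
        index=["g1", "g2", "g3", "g4"],
        columns=["s1", "s2", "s3", "s4"])
    counts = (fpkm * 10).round().astype(int)
    return ExpressionMatrix(fpkm, counts=counts)


@pytest.fixture()
def toy_samples():
    return SampleTable(pd.DataFrame({
        "sample_id": ["s1", "s2", "s3", "s4"],
        "condition": ["Sham", "Sham", "TAC", "TAC"],
        "batch": ["batch1", "batch1", "batch1", "batch1"],
        "assay_level": ["single_nucleus"] * 4,
    }))
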