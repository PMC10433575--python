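import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes `oracles` importable

from bactipred import LabeledDataset, ProteinRecord, SyntheticSpec, generate
from bactipred.sequence_io import AMINO_ACIDS


@pytest.fixture(scope="session")
def random_sequences():
    """100 seeded random sequences (length 15-80) for oracle-equivalence checks."""
    rng = np.random.default_rng(20231)
    aa = np.array(list(AMINO_ACIDS))
    seqs = []
    for i in range(100):
        L = int(rng.integers(15, 81))
        seqs.append(ProteinRecord(f"r{i:03d}", "".join(rng.choice(aa, L))))
    return seqs


@pytest.fixture(scope="session")
def small_dataset():
    """Separable two-class dataset, 30 sequences per class."""
    return generate(SyntheticSpec(n_per_class=30, delta=0.6, seed=11))


@pytest.fixture(scope="session")
def gaussian_features():
    """120 x 100 matrix: 5 informative (2-SD class shift) + 95 noise features."""
    import pandas as pd

    rng = np.random.default_rng(5150)
    n_per = 60
    y = np.array([1] * n_per + [-1] * n_per)
    X = rng.standard_normal((2 * n_per, 100))
    X[: n_per, :5] += 2.0
    cols = [f"inf_{i}" for i in range(5)] + [f"noise_{i}" for i in range(95)]
    return pd.DataFrame(X, columns=cols), y
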