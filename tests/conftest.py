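import numpy as np
import pandas as pd
import pytest

from refstab import CtMatrix, SampleSheet


@pytest.fixture
def toy_ct() -> CtMatrix:
    """3-gene toy: A and B differ by a constant, C wobbles around A."""
    df = pd.DataFrame(
        {
            "s1": [20.0, 25.0, 20.0],
            "s2": [21.0, 26.0, 22.0],
            "s3": [22.0, 27.0, 21.0],
            "s4": [23.0, 28.0, 24.0],
        },
        index=["A", "B", "C"],
    )
    return CtMatrix(df)


@pytest.fixture
def two_group_sheet() -> SampleSheet:
    return SampleSheet(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3", "s4"],
                "group": ["control", "control", "treat", "treat"],
                "is_control": [True, True, False, False],
            }
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_ct(rng: np.random.Generator, n_genes: int, n_samples: int) -> CtMatrix:
    """Random complete Ct matrix in a plausible cycle range."""
    base = rng.uniform(18, 30, size=(n_genes, 1))
    vals = base + rng.normal(0, 1.0, size=(n_genes, n_samples))
    vals = np.clip(vals, 1.0, 44.0)
    genes = [f"G{i}" for i in range(n_genes)]
    samples = [f"S{j}" for j in range(n_samples)]
    return CtMatrix(pd.DataFrame(vals, index=genes, columns=samples))
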