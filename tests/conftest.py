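import numpy as np
import pandas as pd
import pytest

from orchardkin.io import MarkerMatrix, SSRProfile
from orchardkin.simulate import SimConfig, simulate_collection


@pytest.fixture
def small_matrix() -> MarkerMatrix:
    """3 accessions x 4 markers with one missing call."""
    calls = pd.DataFrame(
        [[1.0, 0.0, 1.0, 1.0],
         [1.0, np.nan, 0.0, 1.0],
         [0.0, 1.0, 1.0, 0.0]],
        index=["A1", "A2", "A3"],
        columns=["M1", "M2", "M3", "M4"],
    )
    return MarkerMatrix(calls)


@pytest.fixture
def random_matrix() -> MarkerMatrix:
    """20 accessions x 50 markers, ~5% missing, fixed seed."""
    rng = np.random.default_rng(42)
    calls = rng.integers(0, 2, size=(20, 50)).astype(float)
    calls[rng.random((20, 50)) < 0.05] = np.nan
    return MarkerMatrix(pd.DataFrame(
        calls,
        index=[f"A{i:02d}" for i in range(20)],
        columns=[f"M{j:02d}" for j in range(50)],
    ))


@pytest.fixture(scope="session")
def default_collection():
    """The default planted study design, rendered once per session."""
    return simulate_collection(SimConfig(seed=7))


def ssr(acc: str, ploidy: int | None = 2, **loci) -> SSRProfile:
    """Shorthand SSR profile: ssr('P', L1=(118, 120), L2=(100,))."""
    return SSRProfile(
        accession_id=acc,
        genotype={k: tuple(sorted(v)) for k, v in loci.items()},
        ploidy=ploidy,
    )
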