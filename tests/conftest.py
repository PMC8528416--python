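import numpy as np
import pytest

from secircuit import PipelineConfig, SyntheticDesign, generate
from secircuit.pipeline import run_synthetic_study


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def chrom_sizes():
    return {"chr1": 100_000, "chr2": 80_000}


@pytest.fixture(scope="session")
def exact_dataset():
    """Noiseless (exact-mean) default study: planted truth must be recovered
    exactly by every stage."""
    return generate(SyntheticDesign(noise="exact"), seed=5)


@pytest.fixture(scope="session")
def default_study():
    """One full pipeline run on the default stochastic design."""
    dataset, result = run_synthetic_study(seed=11)
    return dataset, result
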