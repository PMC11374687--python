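import numpy as np
import pandas as pd
import pytest

from crcmetrics.simulate import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared read-only across tests."""
    return generate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for structural tests."""
    return generate_cohort(
        SimConfig(
            n_samples=40,
            n_genes=80,
            n_signature_genes=12,
            n_controls=6,
            baseline_log_mu=float(np.log(60.0)),
            genome_size_mb=12.0,
            seed=7,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240807)


@pytest.fixture()
def tiny_segments():
    return pd.DataFrame(
        {
            "sample_id": ["s1"] * 3,
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [1, 10_000_001, 1],
            "end": [10_000_000, 50_000_000, 50_000_000],
            "tcn": [4, 2, 1],
            "lcn": [1, 1, 0],
            "log2_ratio": [1.0, 0.0, -1.0],
        }
    )
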