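import numpy as np
import pandas as pd
import pytest

from soilcue.simulate import default_design, simulate_study


@pytest.fixture(scope="session")
def noise_free_study():
    """Default 150-sample study at zero measurement noise (exact round trips)."""
    return simulate_study(default_design(noise_cv=0.0), seed=42)


@pytest.fixture(scope="session")
def noisy_study():
    """Default study at the study-condition noise level (cv = 0.15)."""
    return simulate_study(default_design(noise_cv=0.15), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def planted_counts(
    n_taxa: int,
    n_samples: int,
    depth: int,
    pairs: list[tuple[int, int, float]],
    seed: int,
    log_sd: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Multinomial counts over a log-normal basis with planted pair correlations.

    Returns (counts taxa x samples, true correlation matrix). Shared by the
    SparCC unit and acceptance tests.
    """
    from soilcue.simulate import BasisCorrelationSpec, planted_pairs_correlation, simulate_otu_table

    corr = planted_pairs_correlation(n_taxa, pairs)
    gen = np.random.default_rng(seed)
    spec = BasisCorrelationSpec(
        n_taxa=n_taxa,
        correlation_matrix=corr,
        log_mean_abundances=gen.normal(0.0, 1.0, n_taxa),
        log_sd=np.full(n_taxa, log_sd),
        sequencing_depth=depth,
    )
    table = simulate_otu_table(spec, n_samples, seed=seed + 1)
    return table.counts.values, corr
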