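import pytest

import rre


@pytest.fixture(scope="session")
def noiseless_long_table():
    """Longitudinal cohort with no measurement artifacts (onset shifts only)."""
    design = rre.longitudinal_benchmark_design(
        seed=7, noise_sigma=0.0, covariate_effects=rre.CovariateEffects.zero()
    )
    return rre.generate_longitudinal(design)


@pytest.fixture(scope="session")
def noisy_long_table():
    """Benchmark longitudinal cohort at the default 5% log-normal noise."""
    return rre.generate_longitudinal(rre.longitudinal_benchmark_design(seed=7))


@pytest.fixture(scope="session")
def cross_table():
    """Benchmark cross-sectional cohort (10 regions, early-phase severity)."""
    return rre.generate_cross_sectional(rre.cross_sectional_benchmark_design(seed=11))
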