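import numpy as np
import pytest

from rlpupil.synth import (
    CohortGroundTruth,
    GroupHyperParameters,
    generate_cohort_behaviour,
)
from rlpupil.inference import SamplerConfig, build_model, sample_posterior

# hyperparameters producing a large beta drug effect in the gain condition:
# placebo beta ~ Phi(-0.6)*10 = 2.7, atomoxetine ~ Phi(1.1)*10 = 8.6
EFFECT_TRUTH = CohortGroundTruth(
    gain=GroupHyperParameters(
        mu_alpha=-1.2, mu_beta=-0.6, mu_delta_beta=1.7,
        sigma_alpha=0.4, sigma_beta=0.4,
    )
)

NULL_TRUTH = CohortGroundTruth(
    gain=GroupHyperParameters(
        mu_alpha=-1.2, mu_beta=0.0, sigma_alpha=0.4, sigma_beta=0.4,
    )
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """12-participant crossover cohort with a strong beta drug effect."""
    return generate_cohort_behaviour(EFFECT_TRUTH, 12, rng_seed=77)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    """Reduced-sampling crossover fit of the small cohort's gain condition."""
    model = build_model(small_cohort.data, "gain", "crossover")
    return sample_posterior(
        model, SamplerConfig(chains=4, iterations=1000, warmup=500), rng_seed=99
    )
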