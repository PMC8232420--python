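import numpy as np
import pytest

from dilitree.synth import AmwDist, GeneratorSpec, MlogpDist, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (652 drugs, 432:220)."""
    return generate_cohort(GeneratorSpec(seed=20210625))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def amw_only_spec(seed: int, n_per_class: int = 2500, sep: float = 0.9) -> GeneratorSpec:
    """Cohort where AMW is the single informative feature: normal AMW
    families with equal sd and class sizes, identical lipophilicity
    distributions, plus noise features."""
    return GeneratorSpec(
        n_dili=n_per_class,
        n_nodili=n_per_class,
        amw_dili=AmwDist(family="normal", mean=7.09 + sep, sd=0.5),
        amw_nodili=AmwDist(family="normal", mean=7.09, sd=0.5),
        mlogp_dili=MlogpDist(1.5, 1.5),
        mlogp_nodili=MlogpDist(1.5, 1.5),
        n_noise_features=3,
        seed=seed,
    )
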