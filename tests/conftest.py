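import numpy as np
import pytest

from gxeherit.simulate import TraitSpec, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """Shared desk-scale study: ~250 individuals, 600 SNPs, default traits."""
    return simulate_study(n_families=25, n_snps=600, seed=7)


@pytest.fixture(scope="session")
def gxe_study():
    """Study with one strong planted GxE trait for power-style checks."""
    return simulate_study(
        n_families=40,
        n_snps=1000,
        seed=19,
        traits={"t": TraitSpec(0.20, 0.30, "carbohydrate", {"age": 0.01, "sex": 0.2})},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def covariate_design(study, cols=("age", "sex", "center_b")):
    return study.covariates[list(cols)].to_numpy(dtype=float)
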