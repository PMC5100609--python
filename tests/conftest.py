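"""Shared fixtures: small simulated worlds reused across test modules."""
import numpy as np
import pytest

from bonemr import make_scenario, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A modest combined-scenario cohort for interface-level tests."""
    return simulate_cohort(make_scenario("combined_C", n_individuals=1500, seed=42))


@pytest.fixture(scope="session")
def confounded_world():
    """Fat -> LL-BMD = 0.6 with confounding inducing ~ +0.1 OLS bias.

    Built from the null preset with a single causal edge and symmetric
    confounder loadings (0.1^0.5 each), so the latent OLS slope has the
    closed-form value 0.6 + 0.1 = 0.7.
    """
    c = np.sqrt(0.1)
    def build(n, seed):
        return make_scenario(
            "null", n_individuals=n, seed=seed,
            overrides={
                "causal_fat_to_bmd": {"LL": 0.6},
                "confounder_effects": {"fat": c, "LL": c},
            })
    return build


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
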